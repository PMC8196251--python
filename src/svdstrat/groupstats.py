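"""Group-level statistics for the subject table: nonparametric omnibus and
post-hoc rank tests, categorical tests with automatic exact fallback, and
covariate-adjusted linear models under two group codings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as stats
import statsmodels.api as sm

from .classification import GROUP_ORDER

__all__ = [
    "GroupCoding",
    "ModelResult",
    "kruskal_wallis",
    "posthoc_pairwise",
    "categorical_test",
    "fit_adjusted_model",
    "group_summary",
]

#: linear codes: control=1 .. type4=5
LINEAR_CODES = {g.value: i + 1 for i, g in enumerate(GROUP_ORDER)}


@dataclass(frozen=True)
class GroupCoding:
    """How the SVD group enters a regression design.

    ``linear`` maps the ordered groups to consecutive integers
    (control=1, type1=2, ...); ``class`` uses one indicator per non-reference
    group with control as the reference level.
    """

    scheme: str = "linear"
    groups: tuple[str, ...] = tuple(g.value for g in GROUP_ORDER)
    reference: str = "control"

    def __post_init__(self) -> None:
        if self.scheme not in ("linear", "class"):
            raise ValueError(f"unknown coding scheme {self.scheme!r}")
        if self.scheme == "class" and self.reference not in self.groups:
            raise ValueError("reference group must be among coded groups")

    def design_columns(self, labels: Sequence[str]) -> pd.DataFrame:
        labels = pd.Series(list(labels), dtype=object)
        unknown = sorted(set(labels) - set(self.groups))
        if unknown:
            raise ValueError(f"labels outside coding: {unknown}")
        if self.scheme == "linear":
            codes = {g: i + 1 for i, g in enumerate(self.groups)}
            return pd.DataFrame({"svd_linear": labels.map(codes).astype(float)})
        cols = {
            f"svd_{g}": (labels == g).astype(float)
            for g in self.groups
            if g != self.reference
        }
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ModelResult:
    """Per-term OLS estimates: coefficient, 95% CI bounds and p-value."""

    terms: tuple[str, ...]
    coef: Mapping[str, float]
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]
    pvalues: Mapping[str, float]
    stderr: Mapping[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "B": [self.coef[t] for t in self.terms],
                "ci_low": [self.ci_low[t] for t in self.terms],
                "ci_high": [self.ci_high[t] for t in self.terms],
                "p": [self.pvalues[t] for t in self.terms],
                "se": [self.stderr[t] for t in self.terms],
            }
        )


def _group_arrays(values, groups) -> dict[object, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out = {}
    for g in pd.unique(groups):
        arr = values[groups == g]
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        out[g] = arr
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and its chi-square p-value.

    Degenerate all-equal data yields (0, 1) rather than an error.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    arrays = list(by_group.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def posthoc_pairwise(
    values,
    groups,
    reference: object,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-sum comparisons of each group against a reference.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T/(12(N-1))) *
    (1/n_i + 1/n_j)) with T = sum(t^3 - t) over tie groups; two-sided normal
    p-values, Bonferroni-adjusted across the comparisons by default. The
    adjustment used is recorded in the output.
    """
    by_group = _group_arrays(values, groups)
    if reference not in by_group:
        raise ValueError(f"reference group {reference!r} not present")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n_total = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))

    others = [g for g in by_group if g != reference]
    m = len(others)
    rows = []
    ref_mask = groups == reference
    for g in others:
        mask = groups == g
        mean_diff = ranks[mask].mean() - ranks[ref_mask].mean()
        se = np.sqrt(base_var * (1.0 / mask.sum() + 1.0 / ref_mask.sum()))
        z = mean_diff / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append(
            {
                "group": g,
                "reference": reference,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "adjustment": adjust,
            }
        )
    return pd.DataFrame(rows)


def categorical_test(table: np.ndarray | Sequence[Sequence[int]],
                     n_resamples: int = 9999,
                     seed: int | None = 0) -> tuple[float, float, str]:
    """Independence test for an r x c count table.

    Pearson chi-square when every expected count is >= 5; otherwise Fisher's
    exact test for 2x2 tables, or a Monte-Carlo chi-square p (fixed margins)
    for larger sparse tables. Returns (statistic, p, test name).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(row_sums, col_sums) / counts.sum()

    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        return float(chi2), float(p), "chi-square"
    if counts.shape == (2, 2):
        odds, p = stats.fisher_exact(counts.astype(int))
        return float(odds), float(p), "fisher-exact"
    # sparse r x c: Monte-Carlo chi-square under fixed margins
    chi2_obs, _, _, _ = stats.chi2_contingency(counts, correction=False)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_sums.astype(int), col_sums.astype(int))
    draws = sampler.rvs(n_resamples, random_state=rng)
    exceed = 0
    for t in draws:
        chi2_t, _, _, _ = stats.chi2_contingency(t + 0.0, correction=False)
        if chi2_t >= chi2_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_resamples + 1)
    return float(chi2_obs), float(p), "chi-square-montecarlo"


def fit_adjusted_model(
    outcome,
    labels,
    covariates: pd.DataFrame,
    coding: GroupCoding = GroupCoding(),
) -> ModelResult:
    """OLS of an outcome on the coded SVD group plus nuisance covariates.

    Classical (non-robust) standard errors and 95% CIs, matching standard
    multivariate-linear-regression output.
    """
    y = np.asarray(outcome, dtype=float)
    group_cols = coding.design_columns(labels)
    X = pd.concat(
        [group_cols.reset_index(drop=True), covariates.reset_index(drop=True)],
        axis=1,
    )
    X = sm.add_constant(X, prepend=True)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(X.to_numpy(), rowvar=False)
        corr = np.nan_to_num(corr)
        np.fill_diagonal(corr, 0.0)
        bad = [
            X.columns[j]
            for j in range(p)
            if np.any(np.abs(corr[j]) > 1 - 1e-10)
        ]
        raise ValueError(f"design is rank deficient; suspect columns: {bad}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = tuple(X.columns)
    return ModelResult(
        terms=terms,
        coef=dict(fit.params),
        ci_low=dict(ci[0]),
        ci_high=dict(ci[1]),
        pvalues=dict(fit.pvalues),
        stderr=dict(fit.bse),
        n=n,
    )


def group_summary(
    table: pd.DataFrame,
    group_col: str = "svd_class",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
) -> pd.DataFrame:
    """Table-1-style summary: mean (SD) per group for continuous variables,
    n (%) for binary ones, plus the omnibus p-value for each row."""
    groups_present = [
        g.value for g in GROUP_ORDER if g.value in set(table[group_col])
    ]
    rows = []
    for var in continuous:
        row = {"variable": var, "kind": "continuous"}
        for g in groups_present:
            vals = table.loc[table[group_col] == g, var].astype(float)
            row[g] = f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})"
        _, p = kruskal_wallis(table[var].astype(float), table[group_col])
        row["p"] = p
        rows.append(row)
    for var in binary:
        row = {"variable": var, "kind": "binary"}
        counts = []
        for g in groups_present:
            vals = table.loc[table[group_col] == g, var].astype(int)
            n_pos = int(vals.sum())
            counts.append([n_pos, len(vals) - n_pos])
            row[g] = f"{n_pos} ({100.0 * n_pos / len(vals):.1f}%)"
        counts_arr = np.asarray(counts).T
        try:
            _, p, test = categorical_test(counts_arr)
        except ValueError:
            p, test = np.nan, "degenerate"
        row["p"] = p
        row["test"] = test
        rows.append(row)
    return pd.DataFrame(rows)
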