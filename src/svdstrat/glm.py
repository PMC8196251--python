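"""Permutation-based voxel-wise ANCOVA on 3D scalar maps.

Per-voxel OLS with nuisance covariates, cluster-forming thresholding,
cluster-level family-wise-error correction from the permutation
distribution of the maximum cluster statistic (Freedman-Lane scheme),
post-hoc group contrasts and ordered linear trend contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as stats

__all__ = [
    "DesignMatrix",
    "Contrast",
    "StatMap",
    "PermutationConfig",
    "make_group_design",
    "fit_glm",
    "label_clusters",
    "permutation_cluster_inference",
    "trend_inference",
    "ASCENDING_WEIGHTS",
    "DESCENDING_WEIGHTS",
]

ASCENDING_WEIGHTS = (-3.0, -1.0, 1.0, 3.0)
DESCENDING_WEIGHTS = (3.0, 1.0, -1.0, -3.0)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class DesignMatrix:
    """Subject-by-predictor design with columns tagged interest or nuisance.

    Group membership enters as cell-means indicator columns (one per group,
    no explicit intercept — the intercept lies in their span); nuisance
    covariates are continuous columns. The nuisance-only model used for
    residualization always includes an intercept.
    """

    frame: pd.DataFrame
    interest: tuple[str, ...]
    nuisance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cols = set(self.frame.columns)
        for name in (*self.interest, *self.nuisance):
            if name not in cols:
                raise ValueError(f"design has no column {name!r}")
        if not self.interest:
            raise ValueError("at least one interest column is required")
        X = self.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame[list(self.interest) + list(self.nuisance)].to_numpy(float)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def nuisance_matrix(self) -> np.ndarray:
        """Intercept plus nuisance columns (the reduced model)."""
        Z = [np.ones((len(self.frame), 1))]
        if self.nuisance:
            Z.append(self.frame[list(self.nuisance)].to_numpy(float))
        return np.hstack(Z)


@dataclass(frozen=True)
class Contrast:
    """Contrast over the interest columns of a design.

    ``kind='t'`` or ``'trend'``: ``weights`` is one weight per interest
    column (trend weights must sum to zero). ``kind='F'``: the joint test of
    all interest columns against the nuisance-only model (weights ignored).
    """

    kind: str
    weights: tuple[float, ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("t", "F", "trend"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.kind in ("t", "trend"):
            if self.weights is None:
                raise ValueError(f"{self.kind} contrast requires weights")
            w = np.asarray(self.weights, float)
            if not np.any(w != 0):
                raise ValueError("contrast weights must not all be zero")
            if self.kind == "trend" and abs(w.sum()) > 1e-12:
                raise ValueError("trend weights must sum to zero")


@dataclass
class StatMap:
    """Voxel-wise statistic image: finite inside the mask, NaN outside.

    ``n_degenerate`` counts in-mask voxels with zero residual variance;
    those are NaN in ``data`` and excluded from clustering.
    """

    data: np.ndarray
    mask: np.ndarray
    kind: str
    df: tuple[float, ...]
    contrast_name: str = ""
    n_degenerate: int = 0

    def in_mask_values(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for permutation cluster inference.

    ``cluster_forming_t`` is a t-scale threshold; for F contrasts it is
    mapped to the F value with the same upper-tail probability at the model's
    error degrees of freedom. ``cluster_stat`` chooses extent (voxel count,
    default) or mass (sum of suprathreshold excess) as the cluster summary.
    """

    n_permutations: int = 10_000
    cluster_forming_t: float = 3.1
    alpha: float = 0.05
    connectivity: int = 26
    seed: int | None = None
    cluster_stat: str = "extent"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.cluster_forming_t > 0:
            raise ValueError("cluster_forming_t must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.cluster_stat not in ("extent", "mass"):
            raise ValueError("cluster_stat must be 'extent' or 'mass'")


def make_group_design(
    labels: Sequence[str],
    covariates: pd.DataFrame | None = None,
    group_order: Sequence[str] | None = None,
) -> DesignMatrix:
    """Cell-means design: one indicator column per group plus nuisance
    covariates. ``group_order`` fixes the interest-column order (required
    for trend contrasts)."""
    labels = pd.Series(list(labels), dtype=object)
    if group_order is None:
        group_order = list(pd.unique(labels))
    missing = sorted(set(labels) - set(group_order))
    if missing:
        raise ValueError(f"labels outside group_order: {missing}")
    cols = {f"g_{g}": (labels == g).astype(float) for g in group_order}
    frame = pd.DataFrame(cols)
    nuisance: tuple[str, ...] = ()
    if covariates is not None:
        frame = pd.concat([frame, covariates.reset_index(drop=True)], axis=1)
        nuisance = tuple(covariates.columns)
    return DesignMatrix(frame=frame, interest=tuple(cols), nuisance=nuisance)


def _stack_images(images, mask: np.ndarray) -> np.ndarray:
    """(n_subjects, n_in_mask_voxels) data matrix from 3D maps."""
    if isinstance(images, np.ndarray) and images.ndim == 4:
        stack = images
    else:
        stack = np.stack(list(images), axis=0)
    if stack.shape[1:] != mask.shape:
        raise ValueError(
            f"image grid {stack.shape[1:]} does not match mask grid {mask.shape}"
        )
    return stack[:, mask].astype(float)


class _VoxelGLM:
    """Precomputed operators for repeated per-voxel OLS refits."""

    def __init__(self, design: DesignMatrix, contrast: Contrast):
        X = design.matrix
        self.X = X
        self.n, self.p = X.shape
        self.rank = np.linalg.matrix_rank(X)
        self.dof = self.n - self.rank
        if self.dof <= 0:
            raise ValueError("no error degrees of freedom")
        self.pinvX = np.linalg.pinv(X)
        self.contrast = contrast
        self.kind = contrast.kind
        if self.kind in ("t", "trend"):
            w = np.asarray(contrast.weights, float)
            if w.size != len(design.interest):
                raise ValueError(
                    f"contrast has {w.size} weights for "
                    f"{len(design.interest)} interest columns"
                )
            c = np.concatenate([w, np.zeros(len(design.nuisance))])
            self.c = c
            xtx_inv = np.linalg.pinv(X.T @ X)
            self.cvc = float(c @ xtx_inv @ c)
            self.df: tuple[float, ...] = (self.dof,)
        else:
            Z0 = design.nuisance_matrix()
            self.pinvZ0 = np.linalg.pinv(Z0)
            self.Z0 = Z0
            self.q = self.rank - np.linalg.matrix_rank(Z0)
            if self.q < 1:
                raise ValueError("interest columns add no rank beyond nuisance")
            self.df = (float(self.q), float(self.dof))

    def stats(self, Y: np.ndarray) -> np.ndarray:
        """Per-voxel statistic values; NaN where residual variance vanishes
        (exactly or to within floating rounding of the data's scale)."""
        beta = self.pinvX @ Y
        resid = Y - self.X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        scale = np.einsum("ij,ij->j", Y, Y)
        rss = np.where(rss <= scale * 1e-24, 0.0, rss)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.kind in ("t", "trend"):
                se = np.sqrt(self.cvc * rss / self.dof)
                out = (self.c @ beta) / se
            else:
                resid0 = Y - self.Z0 @ (self.pinvZ0 @ Y)
                rss0 = np.einsum("ij,ij->j", resid0, resid0)
                out = ((rss0 - rss) / self.q) / (rss / self.dof)
        out[~np.isfinite(out)] = np.nan
        return out

    def forming_threshold(self, t_threshold: float) -> float:
        """Map the t-scale cluster-forming threshold to this statistic."""
        if self.kind in ("t", "trend"):
            return t_threshold
        tail = stats.t.sf(t_threshold, self.dof)
        return float(stats.f.isf(tail, self.q, self.dof))


def fit_glm(images, mask: np.ndarray, design: DesignMatrix,
            contrast: Contrast) -> StatMap:
    """Per-voxel OLS statistic map for one contrast.

    t = c'beta / SE(c'beta); F is the partitioned-model statistic of the
    interest columns over the nuisance-plus-intercept reduced model.
    """
    mask = np.asarray(mask, bool)
    Y = _stack_images(images, mask)
    if Y.shape[0] != design.n_subjects:
        raise ValueError(
            f"{Y.shape[0]} images but design has {design.n_subjects} rows"
        )
    engine = _VoxelGLM(design, contrast)
    values = engine.stats(Y)
    data = np.full(mask.shape, np.nan)
    data[mask] = values
    return StatMap(
        data=data,
        mask=mask,
        kind=contrast.kind,
        df=engine.df,
        contrast_name=contrast.name,
        n_degenerate=int(np.isnan(values).sum()),
    )


def label_clusters(binary: np.ndarray, connectivity: int = 26):
    """Connected components of a 3D binary map.

    Returns (labels, extents) where labels is an int array with background 0
    and extents[k] is the voxel count of cluster k+1. Deterministic labels in
    array scan order.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndi.label(np.asarray(binary, bool), structure=structure)
    extents = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, extents


def _cluster_stats(stat_values: np.ndarray, labels: np.ndarray, n_clusters: int,
                   threshold: float, how: str) -> np.ndarray:
    """Extent or suprathreshold mass per cluster label (1..n)."""
    if n_clusters == 0:
        return np.zeros(0)
    if how == "extent":
        return np.bincount(labels.ravel(), minlength=n_clusters + 1)[1:].astype(float)
    excess = np.where(np.isfinite(stat_values), stat_values - threshold, 0.0)
    return ndi.sum_labels(excess, labels, index=np.arange(1, n_clusters + 1))


def _permutation_orders(n: int, config: PermutationConfig):
    """Row orders for the permutation loop.

    When n! <= n_permutations the space is enumerated exactly (identity
    included, p = count/n!); otherwise n_permutations random orders are
    sampled and p = (b+1)/(P+1).
    """
    n_fact = math.factorial(n)
    if n_fact <= config.n_permutations:
        return [np.asarray(p) for p in _all_permutations(range(n))], True
    rng = np.random.default_rng(config.seed)
    return [rng.permutation(n) for _ in range(config.n_permutations)], False


def permutation_cluster_inference(
    images,
    mask: np.ndarray,
    design: DesignMatrix,
    contrast: Contrast,
    config: PermutationConfig = PermutationConfig(),
):
    """Cluster-level FWE inference via the Freedman-Lane permutation scheme.

    The nuisance-only model (intercept + nuisance covariates) is fitted
    once; its residuals are permuted, added back to the nuisance fit, and
    the full model is refitted per permutation. The maximum suprathreshold
    cluster statistic per permutation forms the null; each observed
    cluster's FWE p is the (add-one-corrected) fraction of permutation
    maxima at least as large.

    Returns (cluster_table, stat_map, metadata).
    """
    mask = np.asarray(mask, bool)
    Y = _stack_images(images, mask)
    n = Y.shape[0]
    if n != design.n_subjects:
        raise ValueError(f"{n} images but design has {design.n_subjects} rows")
    if config.n_permutations < 1.0 / config.alpha:
        warnings.warn(
            f"n_permutations={config.n_permutations} cannot resolve "
            f"p-values below alpha={config.alpha}",
            stacklevel=2,
        )

    engine = _VoxelGLM(design, contrast)
    threshold = engine.forming_threshold(config.cluster_forming_t)

    observed = engine.stats(Y)
    stat3d = np.full(mask.shape, np.nan)
    stat3d[mask] = observed
    binary = np.zeros(mask.shape, bool)
    binary[mask] = np.nan_to_num(observed, nan=-np.inf) > threshold
    labels, _ = label_clusters(binary, config.connectivity)
    n_clusters = labels.max()
    obs_stats = _cluster_stats(stat3d, labels, n_clusters, threshold,
                               config.cluster_stat)

    # Freedman-Lane: permute residuals of the nuisance-only model
    Z = design.nuisance_matrix()
    fitted = Z @ (np.linalg.pinv(Z) @ Y)
    resid = Y - fitted

    orders, exact = _permutation_orders(n, config)
    perm_max = np.empty(len(orders))
    scratch_binary = np.zeros(mask.shape, bool)
    for i, order in enumerate(orders):
        perm_values = engine.stats(fitted + resid[order])
        scratch_binary[mask] = np.nan_to_num(perm_values, nan=-np.inf) > threshold
        plabels, _ = label_clusters(scratch_binary, config.connectivity)
        k = plabels.max()
        if k == 0:
            perm_max[i] = 0.0
            continue
        svals = np.full(mask.shape, np.nan)
        svals[mask] = perm_values
        perm_max[i] = _cluster_stats(svals, plabels, k, threshold,
                                     config.cluster_stat).max()

    denom = len(orders) if exact else len(orders) + 1
    rows = []
    for k in range(n_clusters):
        cluster_mask = labels == k + 1
        stat_in = np.where(cluster_mask, stat3d, -np.inf)
        peak_flat = int(np.argmax(stat_in))
        peak = np.unravel_index(peak_flat, mask.shape)
        exceed = int((perm_max >= obs_stats[k] - 1e-12).sum())
        p = (exceed if exact else exceed + 1) / denom
        rows.append(
            {
                "cluster_id": k + 1,
                "extent": int(cluster_mask.sum()),
                "cluster_stat": float(obs_stats[k]),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_stat": float(stat3d[peak]),
                "p_fwe": float(p),
                "significant": bool(p < config.alpha),
            }
        )
    cluster_table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "extent", "cluster_stat", "peak_x", "peak_y",
            "peak_z", "peak_stat", "p_fwe", "significant",
        ],
    )
    if len(cluster_table):
        cluster_table = cluster_table.sort_values(
            "cluster_stat", ascending=False
        ).reset_index(drop=True)

    stat_map = StatMap(
        data=stat3d,
        mask=mask,
        kind=contrast.kind,
        df=engine.df,
        contrast_name=contrast.name,
        n_degenerate=int(np.isnan(observed).sum()),
    )
    meta = {
        "n_permutations": len(orders),
        "exact_enumeration": exact,
        "forming_threshold": float(threshold),
        "forming_threshold_t_scale": config.cluster_forming_t,
        "cluster_stat": config.cluster_stat,
        "connectivity": config.connectivity,
        "alpha": config.alpha,
        "seed": config.seed,
        "cluster_labels": labels,
    }
    return cluster_table, stat_map, meta


def trend_inference(
    images,
    mask: np.ndarray,
    design: DesignMatrix,
    direction: str,
    config: PermutationConfig = PermutationConfig(),
):
    """Linear-trend contrast over four ordered groups, then the same
    cluster-level permutation inference as any t contrast."""
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    weights = ASCENDING_WEIGHTS if direction == "ascending" else DESCENDING_WEIGHTS
    if len(design.interest) != len(weights):
        raise ValueError(
            f"trend contrast needs {len(weights)} ordered groups, design "
            f"has {len(design.interest)} interest columns"
        )
    contrast = Contrast(kind="trend", weights=weights, name=f"trend_{direction}")
    return permutation_cluster_inference(images, mask, design, contrast, config)
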