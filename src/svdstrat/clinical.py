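"""Composite clinical scoring: the 5-component physical-frailty score and
the education-dependent global-cognitive-impairment flag."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalMeasures",
    "FrailtyCutoffs",
    "ChsResult",
    "score_chs",
    "flag_global_cognitive_impairment",
    "derive_percentile_cutoffs",
    "score_cohort",
]

CHS_COMPONENTS = ("weight_loss", "exhaustion", "weakness", "slowness", "low_activity")


@dataclass(frozen=True)
class ClinicalMeasures:
    """Raw clinical inputs for one subject. Any field may be None (missing)."""

    sex: str  # "male" | "female"
    weight_loss_pct: float | None = None
    exhaustion: bool | None = None
    grip_strength: float | None = None  # kg
    gait_speed: float | None = None  # m/s
    ipaq_score: float | None = None  # activity units
    mmse: float | None = None
    education_years: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must lie in [0, 30], got {self.mmse!r}")
        if self.gait_speed is not None and not self.gait_speed > 0:
            raise ValueError(f"gait_speed must be > 0, got {self.gait_speed!r}")


@dataclass(frozen=True)
class FrailtyCutoffs:
    """Sex-specific cutoffs for the weakness/slowness/low-activity components.

    Defaults are the fixed published cutoffs; ``mode='cohort_percentile_20'``
    marks cutoffs derived as the sex-specific lowest 20% of a cohort.
    """

    ipaq_male: float = 7497.0
    ipaq_female: float = 6930.0
    speed_male: float = 1.20
    speed_female: float = 1.10
    grip_male: float = 28.00
    grip_female: float = 17.00
    mode: str = "fixed"

    def __post_init__(self) -> None:
        for name in ("ipaq_male", "ipaq_female", "speed_male", "speed_female",
                     "grip_male", "grip_female"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.mode not in ("fixed", "cohort_percentile_20"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")

    def for_sex(self, sex: str) -> tuple[float, float, float]:
        """(ipaq, speed, grip) cutoffs for the given sex."""
        if sex == "male":
            return self.ipaq_male, self.speed_male, self.grip_male
        return self.ipaq_female, self.speed_female, self.grip_female


@dataclass(frozen=True)
class ChsResult:
    """Frailty scoring outcome: total score, frail flag, per-component flags,
    and the names of any components that could not be evaluated."""

    score: int | None
    frail: bool | None
    components: Mapping[str, bool | None]
    missing: tuple[str, ...]


def score_chs(
    measures: ClinicalMeasures,
    cutoffs: FrailtyCutoffs = FrailtyCutoffs(),
) -> ChsResult:
    """Score the 5 frailty components (0-5); frail means score >= 3.

    Weight loss is positive for loss strictly greater than 5% in the last
    year; weakness, slowness and low activity are positive when the measure
    is <= the sex-specific cutoff. Missing inputs yield an explicit
    missing-data result (score None), never a silent 0.
    """
    ipaq_cut, speed_cut, grip_cut = cutoffs.for_sex(measures.sex)
    components: dict[str, bool | None] = {
        "weight_loss": None if measures.weight_loss_pct is None
        else measures.weight_loss_pct > 5.0,
        "exhaustion": None if measures.exhaustion is None
        else bool(measures.exhaustion),
        "weakness": None if measures.grip_strength is None
        else measures.grip_strength <= grip_cut,
        "slowness": None if measures.gait_speed is None
        else measures.gait_speed <= speed_cut,
        "low_activity": None if measures.ipaq_score is None
        else measures.ipaq_score <= ipaq_cut,
    }
    missing = tuple(k for k, v in components.items() if v is None)
    if missing:
        return ChsResult(score=None, frail=None, components=components, missing=missing)
    score = sum(bool(v) for v in components.values())
    return ChsResult(score=score, frail=score >= 3, components=components, missing=())


def flag_global_cognitive_impairment(mmse: float, education_years: float) -> bool:
    """True iff MMSE < 24 with >= 6 education years, or MMSE < 14 with < 6."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"mmse must lie in [0, 30], got {mmse!r}")
    if education_years < 0:
        raise ValueError(f"education_years must be >= 0, got {education_years!r}")
    if education_years >= 6:
        return mmse < 24
    return mmse < 14


def derive_percentile_cutoffs(table: pd.DataFrame) -> FrailtyCutoffs:
    """Sex-specific 20th-percentile cutoffs for activity, speed and grip,
    computed from a cohort table with ``sex``, ``ipaq_score``,
    ``gait_speed_m_s`` and ``grip_strength_kg`` columns."""
    values: dict[str, float] = {}
    for sex in ("male", "female"):
        sub = table[table["sex"] == sex]
        if len(sub) < 5:
            raise ValueError(
                f"need >= 5 subjects per sex to derive cutoffs, got {len(sub)} {sex}"
            )
        values[f"ipaq_{sex}"] = float(np.percentile(sub["ipaq_score"], 20))
        values[f"speed_{sex}"] = float(np.percentile(sub["gait_speed_m_s"], 20))
        values[f"grip_{sex}"] = float(np.percentile(sub["grip_strength_kg"], 20))
    return FrailtyCutoffs(mode="cohort_percentile_20", **values)


def score_cohort(
    table: pd.DataFrame,
    cutoffs: FrailtyCutoffs | None = None,
) -> pd.DataFrame:
    """Append ``chs_score``, ``frail`` and ``cognitive_impairment`` columns.

    With ``cutoffs=None`` the sex-specific 20th-percentile cutoffs are
    derived from this table first.
    """
    if cutoffs is None:
        cutoffs = derive_percentile_cutoffs(table)
    out = table.copy()
    scores: list[float] = []
    frail: list[bool] = []
    impaired: list[bool] = []
    for _, row in out.iterrows():
        m = ClinicalMeasures(
            sex=str(row["sex"]),
            weight_loss_pct=float(row["weight_loss_pct"]),
            exhaustion=bool(row["exhaustion"]),
            grip_strength=float(row["grip_strength_kg"]),
            gait_speed=float(row["gait_speed_m_s"]),
            ipaq_score=float(row["ipaq_score"]),
        )
        res = score_chs(m, cutoffs)
        scores.append(res.score)
        frail.append(res.frail)
        impaired.append(
            flag_global_cognitive_impairment(
                float(row["mmse"]), float(row["education_years"])
            )
        )
    out["chs_score"] = scores
    out["frail"] = frail
    out["cognitive_impairment"] = impaired
    return out
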