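"""Rule-based stratification of subjects into SVD subtypes from MRI markers.

The scheme proceeds in three ordered steps: (i) presence of cerebral
microbleeds (CMB); (ii) presence of severe white-matter hyperintensity
(WMH) burden, defined against a WMH/TIV-ratio threshold; (iii) for
bleeders, the CMB topography (mixed vs strictly lobar); for non-bleeders
with severe WMH, the presence of lacunes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CmbTopography",
    "SvdLabel",
    "SVDClass",
    "MarkerProfile",
    "ThresholdPolicy",
    "classify_cmb_topography",
    "wmh_ratio",
    "severe_wmh_threshold",
    "stratify",
    "stratify_cohort",
]


class CmbTopography(str, Enum):
    NONE = "none"
    STRICTLY_LOBAR = "strictly_lobar"
    MIXED = "mixed"


class SvdLabel(str, Enum):
    CONTROL = "control"
    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE3 = "type3"
    TYPE4 = "type4"
    UNCLASSIFIED = "unclassified"


#: canonical group ordering used by downstream statistics
GROUP_ORDER = (
    SvdLabel.CONTROL,
    SvdLabel.TYPE1,
    SvdLabel.TYPE2,
    SvdLabel.TYPE3,
    SvdLabel.TYPE4,
)


@dataclass(frozen=True)
class SVDClass:
    """Stratification outcome for one subject: a label plus the rule that fired."""

    label: SvdLabel
    rationale: str


@dataclass(frozen=True)
class MarkerProfile:
    """Per-subject MRI SVD markers.

    Parameters
    ----------
    wmh_volume : float
        Total WMH lesion volume in mm^3.
    tiv : float
        Total intracranial volume in mm^3 (must be positive).
    lacune_count : int
        Number of lacunes (small CSF-filled cavities).
    cmb_lobar, cmb_deep, cmb_infratentorial : int
        Microbleed counts by anatomical category.
    """

    wmh_volume: float
    tiv: float
    lacune_count: int
    cmb_lobar: int
    cmb_deep: int
    cmb_infratentorial: int

    def __post_init__(self) -> None:
        if not self.tiv > 0:
            raise ValueError(f"tiv must be > 0, got {self.tiv!r}")
        if self.wmh_volume < 0:
            raise ValueError(f"wmh_volume must be >= 0, got {self.wmh_volume!r}")
        for name in ("lacune_count", "cmb_lobar", "cmb_deep", "cmb_infratentorial"):
            value = getattr(self, name)
            if value < 0 or int(value) != value:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the severe-WMH threshold on the WMH/TIV ratio is obtained.

    ``cohort_percentile`` computes the stated percentile of the cohort's
    ratios (linear-interpolation convention); ``fixed`` uses
    ``fixed_ratio`` directly (default 0.0007, i.e. 0.07%).
    """

    mode: str = "cohort_percentile"
    percentile: float = 50.0
    fixed_ratio: float = 7e-4

    def __post_init__(self) -> None:
        if self.mode not in ("cohort_percentile", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if not self.fixed_ratio > 0:
            raise ValueError("fixed_ratio must be > 0")


def classify_cmb_topography(profile: MarkerProfile) -> CmbTopography:
    """Assign the three-way CMB topography class.

    ``none`` when all counts are zero; ``strictly_lobar`` when microbleeds
    occur exclusively in lobar regions; ``mixed`` whenever any deep or
    infratentorial microbleed is present, with or without lobar ones.
    """
    if profile.cmb_deep + profile.cmb_infratentorial > 0:
        return CmbTopography.MIXED
    if profile.cmb_lobar > 0:
        return CmbTopography.STRICTLY_LOBAR
    return CmbTopography.NONE


def wmh_ratio(profile: MarkerProfile, subject_id: object | None = None) -> float:
    """WMH volume normalized by total intracranial volume (dimensionless)."""
    if not profile.tiv > 0:
        who = f" for subject {subject_id!r}" if subject_id is not None else ""
        raise ValueError(f"tiv must be > 0{who}, got {profile.tiv!r}")
    return profile.wmh_volume / profile.tiv


def severe_wmh_threshold(
    ratios: Sequence[float] | Iterable[float],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> float:
    """Severe-WMH cutoff on the WMH/TIV ratio under the given policy."""
    if policy.mode == "fixed":
        return policy.fixed_ratio
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size < 2:
        raise ValueError(
            "cohort_percentile mode requires at least 2 ratios, got "
            f"{arr.size}"
        )
    return float(np.percentile(arr, policy.percentile))


def stratify(profile: MarkerProfile, threshold: float) -> SVDClass:
    """Apply the three-step stratification to one marker profile.

    Severity comparison is strict: ratio > threshold counts as severe.
    A subject with lacune(s) but neither CMB nor severe WMH falls outside
    the scheme and is labelled ``unclassified`` rather than control.
    """
    topography = classify_cmb_topography(profile)
    if topography is CmbTopography.MIXED:
        return SVDClass(SvdLabel.TYPE3, "CMB present with mixed topography")
    if topography is CmbTopography.STRICTLY_LOBAR:
        return SVDClass(SvdLabel.TYPE4, "CMB present, strictly lobar")

    severe = wmh_ratio(profile) > threshold
    has_lacune = profile.lacune_count >= 1
    if severe:
        if has_lacune:
            return SVDClass(SvdLabel.TYPE2, "no CMB, severe WMH with lacune")
        return SVDClass(SvdLabel.TYPE1, "no CMB, severe WMH without lacune")
    if has_lacune:
        return SVDClass(
            SvdLabel.UNCLASSIFIED,
            "lacune without CMB or severe WMH falls outside the scheme",
        )
    return SVDClass(SvdLabel.CONTROL, "no CMB, no severe WMH, no lacune")


MARKER_COLUMNS = (
    "wmh_volume_mm3",
    "tiv_mm3",
    "lacune_count",
    "cmb_lobar",
    "cmb_deep",
    "cmb_infratentorial",
)


def profile_from_row(row: pd.Series) -> MarkerProfile:
    return MarkerProfile(
        wmh_volume=float(row["wmh_volume_mm3"]),
        tiv=float(row["tiv_mm3"]),
        lacune_count=int(row["lacune_count"]),
        cmb_lobar=int(row["cmb_lobar"]),
        cmb_deep=int(row["cmb_deep"]),
        cmb_infratentorial=int(row["cmb_infratentorial"]),
    )


def stratify_cohort(
    table: pd.DataFrame,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify every subject in a marker table.

    Returns the table with ``wmh_ratio``, ``cmb_topography``, ``svd_class``
    and ``svd_rationale`` columns appended, plus a per-group count summary.
    The percentile threshold (if requested) is computed on this table's
    ratios.
    """
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"marker table is missing columns: {missing}")

    profiles: list[MarkerProfile] = []
    errors: list[str] = []
    for idx, row in table.iterrows():
        try:
            profiles.append(profile_from_row(row))
        except ValueError as exc:  # collect with subject identity
            sid = row.get("subject_id", idx)
            errors.append(f"subject {sid!r}: {exc}")
    if errors:
        raise ValueError("invalid marker rows:\n" + "\n".join(errors))

    ratios = [wmh_ratio(p) for p in profiles]
    threshold = severe_wmh_threshold(ratios, policy)
    results = [stratify(p, threshold) for p in profiles]

    out = table.copy()
    out["wmh_ratio"] = ratios
    out["cmb_topography"] = [classify_cmb_topography(p).value for p in profiles]
    out["svd_class"] = [r.label.value for r in results]
    out["svd_rationale"] = [r.rationale for r in results]

    n_unclassified = int((out["svd_class"] == SvdLabel.UNCLASSIFIED.value).sum())
    if n_unclassified:
        warnings.warn(
            f"{n_unclassified} subject(s) with lacune but neither CMB nor "
            "severe WMH were labelled 'unclassified'",
            stacklevel=2,
        )

    order = [g.value for g in GROUP_ORDER] + [SvdLabel.UNCLASSIFIED.value]
    counts = out["svd_class"].value_counts()
    summary = pd.DataFrame(
        {
            "svd_class": order,
            "n": [int(counts.get(g, 0)) for g in order],
        }
    )
    summary["threshold"] = threshold
    return out, summary
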