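"""Synthetic cohort and image generation.

Produces subject tables and 3D scalar maps with the statistical structure
the downstream analysis assumes: group-dependent marker prevalences,
age/sex/TIV covariate effects, and localized group effects in the images.
Default group parameters echo the published cohort summary (five groups,
N = 312/230/40/54/34).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupParams",
    "CohortSpec",
    "ImageEffectSpec",
    "generate_cohort",
    "generate_images",
    "marker_table_from_counts",
    "DEFAULT_GROUPS",
]

SEVERE_WMH_RATIO = 7e-4  # generator-side severity threshold on WMH/TIV

SUBJECT_COLUMNS = (
    "subject_id", "group_true", "age", "sex", "education_years",
    "hypertension", "tiv_mm3", "wmh_volume_mm3", "lacune_count",
    "cmb_lobar", "cmb_deep", "cmb_infratentorial", "weight_loss_pct",
    "exhaustion", "grip_strength_kg", "gait_speed_m_s", "ipaq_score",
    "mmse", "cvvlt_recall", "taylor_score", "clock_score",
)


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one intended group."""

    n: int
    age_mean: float
    age_sd: float
    sex_male: float
    lacune_rate: float
    severe_wmh_rate: float
    cmb_topography: str  # "none" | "mixed" | "strictly_lobar"
    wmh_lognorm_mu: float  # log of the median ratio excess above threshold
    wmh_lognorm_sigma: float
    education_mean: float
    education_sd: float
    hypertension_rate: float
    mmse_mean: float
    mmse_sd: float
    cvvlt_mean: float
    cvvlt_sd: float
    taylor_mean: float
    taylor_sd: float
    clock_mean: float
    clock_sd: float
    frailty_shift: float  # SD units subtracted from grip/gait/ipaq
    exhaustion_rate: float
    weight_loss_rate: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("sex_male", "lacune_rate", "severe_wmh_rate",
                     "hypertension_rate", "exhaustion_rate", "weight_loss_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.cmb_topography not in ("none", "mixed", "strictly_lobar"):
            raise ValueError(
                f"cmb_topography must be none/mixed/strictly_lobar, "
                f"got {self.cmb_topography!r}"
            )


def _group(n, age, age_sd, male, lac, sev, topo, wmh_mu, edu, edu_sd, htn,
           mmse, mmse_sd, cvvlt, cvvlt_sd, taylor, taylor_sd, clock, clock_sd,
           shift, exh, wl) -> GroupParams:
    return GroupParams(
        n=n, age_mean=age, age_sd=age_sd, sex_male=male, lacune_rate=lac,
        severe_wmh_rate=sev, cmb_topography=topo, wmh_lognorm_mu=wmh_mu,
        wmh_lognorm_sigma=0.8, education_mean=edu, education_sd=edu_sd,
        hypertension_rate=htn, mmse_mean=mmse, mmse_sd=mmse_sd,
        cvvlt_mean=cvvlt, cvvlt_sd=cvvlt_sd, taylor_mean=taylor,
        taylor_sd=taylor_sd, clock_mean=clock, clock_sd=clock_sd,
        frailty_shift=shift, exhaustion_rate=exh, weight_loss_rate=wl,
    )


# Defaults echo the published per-group means/SDs and marker prevalences.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "control": _group(312, 57.9, 5.9, 0.404, 0.0, 0.0, "none", np.log(2e-4),
                      8.7, 4.6, 0.231, 27.4, 2.6, 7.1, 1.6, 32.8, 4.2,
                      8.5, 1.8, 0.0, 0.05, 0.03),
    "type1": _group(230, 65.6, 8.1, 0.483, 0.0, 1.0, "none", np.log(1.3e-3),
                    5.7, 5.2, 0.426, 25.6, 3.3, 6.2, 2.1, 29.5, 7.0,
                    7.5, 2.4, 0.35, 0.08, 0.05),
    "type2": _group(40, 67.8, 9.2, 0.500, 1.0, 1.0, "none", np.log(2.5e-3),
                    4.9, 4.3, 0.525, 24.6, 5.1, 5.8, 2.4, 28.5, 8.7,
                    7.0, 3.0, 0.9, 0.15, 0.10),
    "type3": _group(54, 67.1, 10.3, 0.481, 0.426, 0.815, "mixed",
                    np.log(2.8e-3), 5.6, 5.4, 0.407, 25.0, 4.7, 5.7, 2.2,
                    28.9, 9.1, 7.2, 2.6, 0.95, 0.15, 0.10),
    "type4": _group(34, 64.3, 9.0, 0.412, 0.118, 0.559, "strictly_lobar",
                    np.log(1.5e-3), 7.4, 5.9, 0.235, 25.6, 3.9, 6.0, 2.0,
                    29.3, 7.0, 7.2, 2.7, 0.35, 0.08, 0.05),
}


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification: per-group parameters plus the seed."""

    groups: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    seed: int = 0

    def with_sizes(self, n_per_group: Mapping[str, int] | int) -> "CohortSpec":
        """Copy of the spec with group sizes replaced (int = same size for all)."""
        if isinstance(n_per_group, int):
            n_per_group = {g: n_per_group for g in self.groups}
        groups = {
            g: replace(p, n=int(n_per_group.get(g, p.n)))
            for g, p in self.groups.items()
        }
        return replace(self, groups=groups)


# sex-specific physical baselines: (mean, sd) for grip kg, gait m/s, IPAQ
_PHYS_BASE = {
    "male": {"grip": (35.0, 7.0), "gait": (1.45, 0.22), "ipaq": (12000.0, 4000.0)},
    "female": {"grip": (23.0, 5.0), "gait": (1.35, 0.22), "ipaq": (11000.0, 3500.0)},
}


def _truncnorm(rng, mean, sd, low, high, size):
    """Group-shifted Gaussian clipped to the instrument range."""
    return np.clip(rng.normal(mean, sd, size), low, high)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject, marker fields consistent with the intended
    group, reproducible under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for name in spec.groups:
        p = spec.groups[name]
        n = p.n
        male = rng.random(n) < p.sex_male
        sex = np.where(male, "male", "female")
        age = _truncnorm(rng, p.age_mean, p.age_sd, 50.0, 95.0, n)
        education = _truncnorm(rng, p.education_mean, p.education_sd, 0.0, 20.0, n)
        hypertension = (rng.random(n) < p.hypertension_rate).astype(int)
        tiv = np.clip(
            rng.normal(1_400_000 + 100_000 * male, 120_000, n), 900_000, None
        )

        severe = rng.random(n) < p.severe_wmh_rate
        excess = rng.lognormal(p.wmh_lognorm_mu, p.wmh_lognorm_sigma, n)
        below = rng.uniform(0.05, 0.95, n) * SEVERE_WMH_RATIO
        ratio = np.where(severe, SEVERE_WMH_RATIO + excess, below)
        wmh_volume = ratio * tiv

        has_lacune = rng.random(n) < p.lacune_rate
        lacunes = np.where(has_lacune, 1 + rng.poisson(0.7, n), 0)

        lobar = np.zeros(n, int)
        deep = np.zeros(n, int)
        infra = np.zeros(n, int)
        if p.cmb_topography == "strictly_lobar":
            lobar = 1 + rng.poisson(1.0, n)
        elif p.cmb_topography == "mixed":
            deep = np.where(rng.random(n) < 0.9, 1 + rng.poisson(1.0, n), 0)
            infra = np.where(rng.random(n) < 0.3, 1 + rng.poisson(0.5, n), 0)
            none = (deep + infra) == 0
            deep = np.where(none, 1, deep)  # mixed topography guaranteed
            lobar = np.where(rng.random(n) < 0.5, 1 + rng.poisson(1.0, n), 0)

        grip = np.empty(n)
        gait = np.empty(n)
        ipaq = np.empty(n)
        for s in ("male", "female"):
            idx = sex == s
            base = _PHYS_BASE[s]
            grip[idx] = _truncnorm(
                rng, base["grip"][0] - p.frailty_shift * base["grip"][1],
                base["grip"][1], 2.0, None, int(idx.sum()))
            gait[idx] = _truncnorm(
                rng, base["gait"][0] - p.frailty_shift * base["gait"][1],
                base["gait"][1], 0.2, None, int(idx.sum()))
            ipaq[idx] = _truncnorm(
                rng, base["ipaq"][0] - p.frailty_shift * base["ipaq"][1],
                base["ipaq"][1], 100.0, None, int(idx.sum()))

        exhaustion = (rng.random(n) < p.exhaustion_rate).astype(int)
        lost_weight = rng.random(n) < p.weight_loss_rate
        weight_loss = np.where(
            lost_weight, rng.uniform(5.5, 12.0, n), rng.uniform(0.0, 4.5, n)
        )

        mmse = _truncnorm(rng, p.mmse_mean, p.mmse_sd, 0.0, 30.0, n)
        cvvlt = _truncnorm(rng, p.cvvlt_mean, p.cvvlt_sd, 0.0, 9.0, n)
        taylor = _truncnorm(rng, p.taylor_mean, p.taylor_sd, 0.0, 36.0, n)
        clock = _truncnorm(rng, p.clock_mean, p.clock_sd, 0.0, 10.0, n)

        frames.append(pd.DataFrame({
            "subject_id": [f"S{offset + i:04d}" for i in range(n)],
            "group_true": name,
            "age": np.round(age, 1),
            "sex": sex,
            "education_years": np.round(education, 1),
            "hypertension": hypertension,
            "tiv_mm3": np.round(tiv, 1),
            "wmh_volume_mm3": np.round(wmh_volume, 2),
            "lacune_count": lacunes.astype(int),
            "cmb_lobar": lobar.astype(int),
            "cmb_deep": deep.astype(int),
            "cmb_infratentorial": infra.astype(int),
            "weight_loss_pct": np.round(weight_loss, 2),
            "exhaustion": exhaustion,
            "grip_strength_kg": np.round(grip, 2),
            "gait_speed_m_s": np.round(gait, 3),
            "ipaq_score": np.round(ipaq, 1),
            "mmse": np.round(mmse).astype(int),
            "cvvlt_recall": np.round(cvvlt).astype(int),
            "taylor_score": np.round(taylor, 1),
            "clock_score": np.round(clock).astype(int),
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)[list(SUBJECT_COLUMNS)]


def marker_table_from_counts(
    group_counts: Mapping[str, Mapping[str, int]],
    tiv: float = 1_400_000.0,
) -> pd.DataFrame:
    """Deterministic marker table reproducing exact per-group marker counts.

    ``group_counts`` maps an intended group to ``{"n": ..., "n_lacune": ...,
    "n_severe": ...}``. Within each group the first ``n_severe`` subjects get
    a WMH/TIV ratio above the fixed severity threshold (and the first
    ``n_lacune`` get one lacune); CMB topography follows the intended group.
    Useful for reconstructing published count tables as classifier input.
    """
    rows = []
    sid = 0
    for group, c in group_counts.items():
        n = int(c["n"])
        n_lacune = int(c.get("n_lacune", 0))
        n_severe = int(c.get("n_severe", 0))
        if not 0 <= n_lacune <= n or not 0 <= n_severe <= n:
            raise ValueError(f"group {group!r}: counts exceed n")
        for i in range(n):
            severe = i < n_severe
            lacune = 1 if i < n_lacune else 0
            if group == "type3":
                lobar, deep, infra = 1, 1, 0
            elif group == "type4":
                lobar, deep, infra = 2, 0, 0
            else:
                lobar = deep = infra = 0
            ratio = 2.0 * SEVERE_WMH_RATIO if severe else 0.5 * SEVERE_WMH_RATIO
            rows.append({
                "subject_id": f"S{sid:04d}",
                "group_true": group,
                "tiv_mm3": tiv,
                "wmh_volume_mm3": ratio * tiv,
                "lacune_count": lacune,
                "cmb_lobar": lobar,
                "cmb_deep": deep,
                "cmb_infratentorial": infra,
            })
            sid += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImageEffectSpec:
    """Geometry and effect structure of the synthetic 3D maps.

    Each blob is a sphere given as (center, radius, atlas_label);
    ``effect_sizes`` maps a group to one mean shift per blob;
    ``covariate_betas`` are slopes on z-scored age and TIV and on the male
    indicator. Subject map = baseline + group blob effects + covariate
    effects + iid Gaussian noise.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    blobs: tuple[tuple[tuple[int, int, int], float, int], ...] = (
        ((7, 8, 12), 3.0, 1),
        ((16, 15, 9), 4.0, 4),
        ((12, 18, 16), 3.0, 7),
    )
    effect_sizes: Mapping[str, Sequence[float]] = field(default_factory=dict)
    covariate_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)  # age, sex, tiv
    noise_sd: float = 1.0
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid dimensions must be >= 4")
        for center, radius, label in self.blobs:
            if radius <= 0:
                raise ValueError("blob radius must be > 0")
            if not 1 <= label <= 7:
                raise ValueError("atlas labels must lie in 1..7")
            for c, dim in zip(center, self.grid_shape):
                if not radius <= c <= dim - 1 - radius:
                    raise ValueError(
                        f"grid {self.grid_shape} too small to host blob at "
                        f"{center} with radius {radius}"
                    )

    def blob_masks(self) -> list[np.ndarray]:
        grids = np.indices(self.grid_shape)
        masks = []
        for center, radius, _ in self.blobs:
            dist2 = sum(
                (g - c) ** 2 for g, c in zip(grids, center)
            )
            masks.append(dist2 <= radius**2)
        return masks


def generate_images(
    cohort: pd.DataFrame,
    spec: ImageEffectSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject maps plus the shared analysis mask and 7-label atlas.

    Returns (images, mask, atlas): images is (n_subjects, *grid_shape);
    the mask excludes a one-voxel border; the atlas partitions the mask
    into 7 slabs along x, overwritten by each blob's assigned label.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    n = len(cohort)

    mask = np.zeros(shape, bool)
    mask[1:-1, 1:-1, 1:-1] = True

    atlas = np.zeros(shape, int)
    x_edges = np.linspace(1, shape[0] - 1, 8).astype(int)
    for label in range(1, 8):
        atlas[x_edges[label - 1]:x_edges[label], :, :] = label
    blob_masks = spec.blob_masks()
    for (_, _, label), bmask in zip(spec.blobs, blob_masks):
        atlas[bmask] = label
    atlas[~mask] = 0

    age = cohort["age"].to_numpy(float)
    male = (cohort["sex"] == "male").to_numpy(float)
    tiv = cohort["tiv_mm3"].to_numpy(float)
    z_age = (age - age.mean()) / (age.std() or 1.0)
    z_tiv = (tiv - tiv.mean()) / (tiv.std() or 1.0)
    b_age, b_sex, b_tiv = spec.covariate_betas
    subject_offset = b_age * z_age + b_sex * male + b_tiv * z_tiv

    images = rng.normal(0.0, spec.noise_sd, (n, *shape))
    images += spec.baseline + subject_offset[:, None, None, None]
    groups = cohort["group_true"].to_numpy()
    for g, effects in spec.effect_sizes.items():
        effects = np.asarray(effects, float)
        if effects.size != len(blob_masks):
            raise ValueError(
                f"group {g!r}: {effects.size} effect sizes for "
                f"{len(blob_masks)} blobs"
            )
        idx = np.flatnonzero(groups == g)
        for e, bmask in zip(effects, blob_masks):
            if e != 0.0 and idx.size:
                images[idx] += np.where(bmask, e, 0.0)
    return images, mask, atlas
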