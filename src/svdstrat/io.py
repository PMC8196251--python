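"""File formats and run configuration: CSV subject tables with row-level
validation, NIfTI-1 maps with grid-consistency checks, YAML run configs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .classification import ThresholdPolicy
from .glm import PermutationConfig

__all__ = [
    "MANDATORY_COLUMNS",
    "TableValidationError",
    "read_subject_table",
    "write_subject_table",
    "save_map",
    "load_map",
    "load_map_stack",
    "RunConfig",
]

MANDATORY_COLUMNS = (
    "subject_id",
    "wmh_volume_mm3",
    "tiv_mm3",
    "lacune_count",
    "cmb_lobar",
    "cmb_deep",
    "cmb_infratentorial",
)

_NUMERIC_COLUMNS = MANDATORY_COLUMNS[1:]


class TableValidationError(ValueError):
    """Raised with one message per offending row/column."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "subject table failed validation:\n" + "\n".join(self.problems)
        )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject CSV.

    Mandatory columns are the subject id and the six marker fields; rows
    with non-numeric markers, non-positive TIV or negative counts are
    reported by line number (header = line 1).
    """
    table = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError([f"missing mandatory column(s): {missing}"])
    for col in _NUMERIC_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[numeric.isna()]:
            problems.append(
                f"line {idx + 2}: column {col!r} is not numeric "
                f"({table.at[idx, col]!r})"
            )
        table[col] = numeric
    if not problems:
        for idx in table.index[table["tiv_mm3"] <= 0]:
            problems.append(f"line {idx + 2}: tiv_mm3 must be > 0")
        for col in ("lacune_count", "cmb_lobar", "cmb_deep",
                    "cmb_infratentorial", "wmh_volume_mm3"):
            for idx in table.index[table[col] < 0]:
                problems.append(f"line {idx + 2}: {col} must be >= 0")
    if problems:
        raise TableValidationError(problems)
    return table


def write_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def save_map(data: np.ndarray, path: str | Path,
             affine: np.ndarray | None = None) -> None:
    """Write a 3D (or 4D) array as NIfTI-1; float data stored losslessly
    as float64, integer data as int16/int32."""
    if affine is None:
        affine = np.eye(4)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        dtype = np.int32 if data.max(initial=0) > 32767 else np.int16
        data = data.astype(dtype)
    elif data.dtype == bool:
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def load_map_stack(
    paths: Sequence[str | Path],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Load per-subject 3D maps into an (n, x, y, z) stack.

    Enforces a shared grid and orientation across the set and finiteness
    of in-mask voxels.
    """
    if not paths:
        raise ValueError("no map paths given")
    arrays = []
    ref_shape = ref_affine = None
    for p in paths:
        data, affine = load_map(p)
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, affine
        elif data.shape != ref_shape or not np.allclose(affine, ref_affine):
            raise ValueError(
                f"map {p} grid/orientation differs from the first map "
                f"({data.shape} vs {ref_shape})"
            )
        arrays.append(np.asarray(data, float))
    stack = np.stack(arrays)
    if mask is not None:
        if mask.shape != ref_shape:
            raise ValueError(
                f"mask grid {mask.shape} does not match map grid {ref_shape}"
            )
        if not np.all(np.isfinite(stack[:, np.asarray(mask, bool)])):
            raise ValueError("non-finite values inside the analysis mask")
    return stack


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths, policies, seed)."""

    out_dir: str
    table_path: str | None = None
    image_paths: tuple[str, ...] = ()
    mask_path: str | None = None
    atlas_path: str | None = None
    threshold_mode: str = "cohort_percentile"
    threshold_percentile: float = 50.0
    fixed_ratio: float = 7e-4
    cutoff_mode: str = "fixed"
    coding_scheme: str = "linear"
    n_permutations: int = 1000
    cluster_forming_t: float = 3.1
    alpha: float = 0.05
    connectivity: int = 26
    seed: int = 0
    simulate: bool = False
    n_per_group: int | None = None

    def threshold_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            mode=self.threshold_mode,
            percentile=self.threshold_percentile,
            fixed_ratio=self.fixed_ratio,
        )

    def permutation_config(self) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            cluster_forming_t=self.cluster_forming_t,
            alpha=self.alpha,
            connectivity=self.connectivity,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "image_paths" in raw:
            raw["image_paths"] = tuple(raw["image_paths"])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.simulate:
            for name in ("table_path", "mask_path", "atlas_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p!r}")
            for p in self.image_paths:
                if not Path(p).exists():
                    raise ValueError(f"image path does not exist: {p!r}")
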