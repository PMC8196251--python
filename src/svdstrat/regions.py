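"""Regional distribution of significant voxels over a 7-label parcellation."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REGION_NAMES", "regional_distribution"]

REGION_NAMES = {
    1: "frontal",
    2: "parietal",
    3: "limbic",
    4: "subcortical",
    5: "temporal",
    6: "occipital",
    7: "cerebellum",
}


def regional_distribution(
    significance_mask: np.ndarray,
    atlas: np.ndarray,
    region_names: dict[int, str] = REGION_NAMES,
) -> pd.DataFrame:
    """Count significant voxels per atlas label.

    For each region the output reports the raw count, its share of all
    significant in-atlas voxels (sums to 100% when any exist), and the
    fraction of that region's voxels that are significant. Voxels with
    atlas label 0 (unassigned) are reported in a separate row. An empty
    significance mask yields zero counts with shares flagged NaN.
    """
    sig = np.asarray(significance_mask, bool)
    atlas = np.asarray(atlas)
    if sig.shape != atlas.shape:
        raise ValueError(
            f"significance grid {sig.shape} does not match atlas grid {atlas.shape}"
        )
    known = set(region_names) | {0}
    present = set(np.unique(atlas).tolist())
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"atlas contains labels outside the dictionary: {unknown}")

    total_in_atlas = int((sig & (atlas > 0)).sum())
    rows = []
    for label in sorted(region_names):
        region_voxels = int((atlas == label).sum())
        n_sig = int((sig & (atlas == label)).sum())
        share = 100.0 * n_sig / total_in_atlas if total_in_atlas else np.nan
        within = 100.0 * n_sig / region_voxels if region_voxels else np.nan
        rows.append(
            {
                "label": label,
                "region": region_names[label],
                "n_significant": n_sig,
                "region_voxels": region_voxels,
                "share_pct": share,
                "within_region_pct": within,
            }
        )
    n_unassigned = int((sig & (atlas == 0)).sum())
    rows.append(
        {
            "label": 0,
            "region": "unassigned",
            "n_significant": n_unassigned,
            "region_voxels": int((atlas == 0).sum()),
            "share_pct": np.nan,
            "within_region_pct": np.nan,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["total_significant_in_atlas"] = total_in_atlas
    out.attrs["empty"] = total_in_atlas == 0 and n_unassigned == 0
    return out
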