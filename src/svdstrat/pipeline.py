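"""End-to-end orchestration: stratify, score, compare, run voxelwise
inference and the downstream pattern/region summaries, and write a
machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import GROUP_ORDER, stratify_cohort
from .clinical import FrailtyCutoffs, score_cohort
from .glm import (
    Contrast,
    make_group_design,
    permutation_cluster_inference,
    trend_inference,
)
from .groupstats import GroupCoding, fit_adjusted_model, group_summary
from .io import RunConfig, read_subject_table, save_map, load_map, load_map_stack
from .patterns import select_k_calinski, vectorize_statmaps
from .regions import regional_distribution
from .synthetic import CohortSpec, ImageEffectSpec, generate_cohort, generate_images

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the manifest dictionary.

    Stages: classify -> clinical scoring -> group statistics -> omnibus F
    map -> post-hoc t maps (each SVD type vs control) -> ascending and
    descending trend maps -> pattern clustering of the post-hoc maps ->
    regional distribution of trend-significant voxels. All outputs land
    under ``config.out_dir``; the manifest records the seed, thresholds and
    a checksum per artifact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit_csv(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        artifacts[name] = _sha256(path)

    def emit_map(data: np.ndarray, name: str) -> None:
        path = out / name
        save_map(data, path)
        artifacts[name] = _sha256(path)

    stage = "load_inputs"
    try:
        if config.simulate:
            spec = CohortSpec(seed=config.seed)
            if config.n_per_group:
                spec = spec.with_sizes(config.n_per_group)
            table = generate_cohort(spec)
            effect_spec = ImageEffectSpec(
                effect_sizes={
                    "type1": (-0.6, -0.4, 0.0),
                    "type2": (-0.9, -0.7, 0.0),
                    "type3": (-1.2, -0.9, 0.0),
                    "type4": (0.0, 0.0, -0.8),
                },
                covariate_betas=(-0.2, 0.1, 0.3),
            )
            images, mask, atlas = generate_images(
                table, effect_spec, seed=config.seed
            )
        else:
            table = read_subject_table(config.table_path)
            mask_data, _ = load_map(config.mask_path)
            mask = mask_data.astype(bool)
            atlas_data, _ = load_map(config.atlas_path)
            atlas = atlas_data.astype(int)
            images = load_map_stack(config.image_paths, mask)
            if len(config.image_paths) != len(table):
                raise ValueError(
                    f"{len(config.image_paths)} images for {len(table)} subjects"
                )

        stage = "classify"
        classified, counts = stratify_cohort(table, config.threshold_policy())
        emit_csv(classified, "subjects_classified.csv")
        emit_csv(counts, "group_counts.csv")

        stage = "clinical_scoring"
        cutoffs = FrailtyCutoffs() if config.cutoff_mode == "fixed" else None
        scored = score_cohort(classified, cutoffs)
        emit_csv(scored, "subjects_scored.csv")

        stage = "group_statistics"
        named = scored[
            scored["svd_class"].isin([g.value for g in GROUP_ORDER])
        ].reset_index(drop=True)
        summary = group_summary(
            named,
            continuous=("age", "education_years", "chs_score", "mmse"),
            binary=("hypertension", "frail", "cognitive_impairment"),
        )
        emit_csv(summary, "table1_summary.csv")
        frailty_groups = [g.value for g in GROUP_ORDER[:4]]
        frail_rows = named[named["svd_class"].isin(frailty_groups)]
        models = []
        for coding in (GroupCoding("linear", tuple(frailty_groups)),
                       GroupCoding("class", tuple(frailty_groups))):
            res = fit_adjusted_model(
                frail_rows["chs_score"], frail_rows["svd_class"],
                frail_rows[["age"]].assign(
                    sex=(frail_rows["sex"] == "male").astype(float)
                ),
                coding,
            )
            frame = res.to_frame()
            frame.insert(0, "outcome", "chs_score")
            frame.insert(1, "coding", coding.scheme)
            models.append(frame)
        all_groups = tuple(g.value for g in GROUP_ORDER)
        for coding in (GroupCoding("linear", all_groups),
                       GroupCoding("class", all_groups)):
            res = fit_adjusted_model(
                named["mmse"], named["svd_class"],
                named[["age", "education_years"]].assign(
                    sex=(named["sex"] == "male").astype(float)
                ),
                coding,
            )
            frame = res.to_frame()
            frame.insert(0, "outcome", "mmse")
            frame.insert(1, "coding", coding.scheme)
            models.append(frame)
        emit_csv(pd.concat(models, ignore_index=True), "table2_models.csv")

        stage = "voxelwise_omnibus"
        groups_present = [
            g.value for g in GROUP_ORDER
            if (classified["svd_class"] == g.value).sum() >= 2
        ]
        keep = classified["svd_class"].isin(groups_present).to_numpy()
        sub = classified.loc[keep].reset_index(drop=True)
        sub_images = images[keep]
        covariates = pd.DataFrame({
            "age": sub["age"].astype(float),
            "sex": (sub["sex"] == "male").astype(float),
            "tiv": sub["tiv_mm3"].astype(float),
        })
        design = make_group_design(
            sub["svd_class"], covariates, group_order=groups_present
        )
        perm = config.permutation_config()
        f_clusters, f_map, f_meta = permutation_cluster_inference(
            sub_images, mask, design, Contrast(kind="F", name="group_F"), perm
        )
        emit_map(f_map.data, "stat_F_group.nii")
        emit_csv(f_clusters, "clusters_F_group.csv")

        stage = "voxelwise_posthoc"
        posthoc_maps = {}
        for g in groups_present:
            if g == "control":
                continue
            weights = tuple(
                1.0 if col == "g_control" else (-1.0 if col == f"g_{g}" else 0.0)
                for col in design.interest
            )
            contrast = Contrast(kind="t", weights=weights,
                                name=f"control_gt_{g}")
            clusters, stat_map, _ = permutation_cluster_inference(
                sub_images, mask, design, contrast, perm
            )
            emit_map(stat_map.data, f"stat_t_{contrast.name}.nii")
            emit_csv(clusters, f"clusters_t_{contrast.name}.csv")
            posthoc_maps[g] = stat_map.data

        stage = "voxelwise_trend"
        trend_sig = np.zeros(mask.shape, bool)
        trend_groups = ["control", "type1", "type2", "type3"]
        trend_meta = {}
        if all(g in groups_present for g in trend_groups):
            tkeep = classified["svd_class"].isin(trend_groups).to_numpy()
            tsub = classified.loc[tkeep].reset_index(drop=True)
            tcov = pd.DataFrame({
                "age": tsub["age"].astype(float),
                "sex": (tsub["sex"] == "male").astype(float),
                "tiv": tsub["tiv_mm3"].astype(float),
            })
            tdesign = make_group_design(
                tsub["svd_class"], tcov, group_order=trend_groups
            )
            for direction in ("ascending", "descending"):
                clusters, stat_map, meta = trend_inference(
                    images[tkeep], mask, tdesign, direction, perm
                )
                emit_map(stat_map.data, f"stat_t_trend_{direction}.nii")
                emit_csv(clusters, f"clusters_trend_{direction}.csv")
                labels = meta["cluster_labels"]
                for _, row in clusters[clusters["significant"]].iterrows():
                    trend_sig |= labels == row["cluster_id"]
                trend_meta[direction] = {
                    "n_significant_clusters": int(clusters["significant"].sum()),
                    "forming_threshold": meta["forming_threshold"],
                }
            emit_map(trend_sig.astype(np.int16), "trend_significant_mask.nii")

        stage = "pattern_clustering"
        pattern_report: dict = {"skipped": len(posthoc_maps) < 3}
        if len(posthoc_maps) >= 3:
            vectors = vectorize_statmaps(sorted(posthoc_maps.items()), mask)
            solution = select_k_calinski(vectors)
            dist = pd.DataFrame(
                solution.distances, index=solution.labels,
                columns=solution.labels,
            )
            path = out / "pattern_distance.csv"
            dist.to_csv(path)
            artifacts["pattern_distance.csv"] = _sha256(path)
            pattern_report = {
                "selected_k": solution.selected_k,
                "degenerate": solution.degenerate,
                "ch_by_k": {str(k): v for k, v in solution.ch_by_k.items()},
                "membership": solution.membership,
                "linkage": solution.linkage.tolist(),
            }
            path = out / "pattern_clustering.json"
            path.write_text(json.dumps(pattern_report, indent=2))
            artifacts["pattern_clustering.json"] = _sha256(path)

        stage = "regional_summary"
        regions = regional_distribution(trend_sig, atlas)
        emit_csv(regions, "trend_regional_distribution.csv")

    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    manifest = {
        "svdstrat_version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "cluster_forming_t": config.cluster_forming_t,
        "alpha": config.alpha,
        "threshold_mode": config.threshold_mode,
        "groups_analyzed": groups_present,
        "trend": trend_meta,
        "pattern_clustering": {
            k: v for k, v in pattern_report.items() if k != "linkage"
        },
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
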