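# svdstrat

Rule-based stratification of cerebral small-vessel-disease (SVD) subtypes
from MRI-marker tables, with the downstream statistics to characterize the
resulting groups: composite clinical scoring, nonparametric group
comparisons, permutation-based voxel-wise ANCOVA with cluster-level FWE
correction (including ordered linear trend contrasts), hierarchical
clustering of statistic-map spatial patterns, and regional distribution
summaries over a 7-label parcellation. A synthetic-cohort module generates
subject tables and 3D NIfTI maps with the statistical structure the
analysis assumes, so the whole pipeline is testable offline.

## The stratification scheme

Three ordered steps on a subject's markers (WMH volume/TIV ratio, lacune
count, microbleed counts by anatomical category):

1. microbleeds present? mixed topography (any deep/infratentorial) → type 3;
   strictly lobar → type 4;
2. otherwise, severe WMH (ratio above the cohort 50th percentile, or a fixed
   0.0007 cutoff)? without lacune → type 1; with lacune → type 2;
3. otherwise → control. A lacune with neither microbleeds nor severe WMH
   falls outside the scheme and is flagged `unclassified` with a warning.

## Command line

Everything is reachable through the `svdstrat` entry point:

```bash
svdstrat simulate --out demo --seed 1 --n-per-group 20
svdstrat classify --table demo/subjects.csv --mode fixed --out demo/classified.csv
svdstrat clinstats score-chs --table demo/classified.csv --out demo/scored.csv
svdstrat clinstats compare --table demo/scored.csv --continuous age --binary frail
svdstrat clinstats model --table demo/scored.csv --outcome chs_score \
    --coding linear --covariate age --covariate sex
svdstrat trend --design design.csv --mask demo/mask.nii --direction ascending \
    --perms 1000 --seed 1 --out demo/out
svdstrat cluster-patterns --maps a.nii --maps b.nii --maps c.nii --maps d.nii \
    --mask demo/mask.nii --out demo/patterns
svdstrat report regions --significance sig.nii --atlas demo/atlas.nii \
    --out regions.csv --pie pie.png
svdstrat run-all --out demo/full --simulate --n-per-group 12 --perms 500 --seed 1
```

`voxelwise` expects a design CSV with `svd_class`, `age`, `sex`, `tiv_mm3`
and `image_path` columns; `run-all` accepts a YAML config (see
`svdstrat.io.RunConfig` for the keys) and writes a manifest with per-artifact
checksums so reruns with the same seed are verifiably identical.

## Library layout

| module | contents |
| --- | --- |
| `svdstrat.classification` | marker profiles, threshold policy, the stratification rules |
| `svdstrat.clinical` | 5-component frailty score (CHS), cognitive-impairment flag, percentile cutoffs |
| `svdstrat.groupstats` | Kruskal–Wallis, Dunn post-hoc, chi-square/Fisher with exact fallback, adjusted OLS under linear/class group codings |
| `svdstrat.glm` | per-voxel OLS t/F maps, connected components, Freedman–Lane permutation cluster-FWE inference, trend contrasts |
| `svdstrat.patterns` | 1−r distances, average-linkage trees, Calinski–Harabasz cluster-count selection |
| `svdstrat.regions` | significant-voxel distribution over the 7-region atlas |
| `svdstrat.synthetic` | cohort and image generators, exact-count marker tables |
| `svdstrat.io` / `svdstrat.pipeline` | CSV/NIfTI/YAML formats, validation, end-to-end orchestration |

Statistical conventions worth knowing: permutation p-values use the
add-one convention (b+1)/(P+1), switching to exact full enumeration when
n! does not exceed the requested permutation count; the cluster-forming
threshold is given on the t scale and mapped to the matching F quantile for
F contrasts; cluster summary is extent by default with mass as an option;
connectivity defaults to 26 neighbors.

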