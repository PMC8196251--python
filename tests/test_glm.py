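import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from svdstrat.glm import (
    ASCENDING_WEIGHTS,
    Contrast,
    DesignMatrix,
    PermutationConfig,
    fit_glm,
    label_clusters,
    make_group_design,
    permutation_cluster_inference,
    trend_inference,
)


def two_group_design(n_per_group=10, covariate=None):
    labels = ["a"] * n_per_group + ["b"] * n_per_group
    cov = None
    if covariate is not None:
        cov = pd.DataFrame({"cov": covariate})
    return make_group_design(labels, cov, group_order=["a", "b"])


def flood_fill_oracle(binary, connectivity):
    """Brute-force BFS connected-component labelling."""
    offsets = [
        o for o in itertools.product([-1, 0, 1], repeat=3)
        if o != (0, 0, 0) and sum(abs(v) for v in o) <= {6: 1, 18: 2, 26: 3}[connectivity]
    ]
    labels = np.zeros(binary.shape, int)
    current = 0
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if labels[idx]:
            continue
        current += 1
        queue = [idx]
        labels[idx] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(nb, binary.shape)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = current
                        queue.append(nb)
    return labels


class TestDesignAndContrast:
    def test_rank_deficient_design_rejected(self):
        frame = pd.DataFrame({"g_a": [1.0, 1, 0, 0], "g_b": [0.0, 0, 1, 1],
                              "dup": [1.0, 1, 0, 0]})
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(frame=frame, interest=("g_a", "g_b"), nuisance=("dup",))

    def test_trend_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to zero"):
            Contrast(kind="trend", weights=(1.0, 1.0, 1.0, 1.0))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all be zero"):
            Contrast(kind="t", weights=(0.0, 0.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_permutations=0)
        with pytest.raises(ValueError):
            PermutationConfig(connectivity=4)
        with pytest.raises(ValueError):
            PermutationConfig(cluster_forming_t=-1.0)


class TestFitGlm:
    def test_f_equals_t_squared_two_groups(self, rng):
        n = 12
        images = rng.normal(size=(2 * n, 6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(n)
        tmap = fit_glm(images, mask, design,
                       Contrast(kind="t", weights=(1.0, -1.0)))
        fmap = fit_glm(images, mask, design, Contrast(kind="F"))
        np.testing.assert_allclose(fmap.data[mask], tmap.data[mask] ** 2,
                                   rtol=1e-9)

    def test_null_t_mean_near_zero(self, rng):
        images = rng.normal(size=(40, 8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        design = two_group_design(20)
        tmap = fit_glm(images, mask, design,
                       Contrast(kind="t", weights=(1.0, -1.0)))
        assert abs(np.nanmean(tmap.data[mask])) < 0.1

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 16
        images = rng.normal(size=(n, 4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        cov = rng.normal(size=n)
        design = two_group_design(8, covariate=cov)
        tmap = fit_glm(images, mask, design,
                       Contrast(kind="t", weights=(1.0, -1.0)))
        X = design.matrix
        for flat_idx, voxel in zip(np.flatnonzero(mask.ravel())[:5],
                                   images.reshape(n, -1).T[mask.ravel()][:5]):
            fit = sm.OLS(voxel, X).fit()
            t_ref = fit.t_test([1.0, -1.0, 0.0]).tvalue.item()
            assert tmap.data.ravel()[flat_idx] == pytest.approx(t_ref, rel=1e-8)

    def test_noncentrality_recovery(self, rng):
        # planted effect 1, noise 1, 20 vs 20: ncp = 1/sqrt(2/20)
        n = 20
        effect = 1.0
        images = rng.normal(size=(2 * n, 10, 10, 4))
        images[n:, 2:8, 2:8, :] += effect
        mask = np.ones((10, 10, 4), bool)
        design = two_group_design(n)
        tmap = fit_glm(images, mask, design,
                       Contrast(kind="t", weights=(-1.0, 1.0)))
        ncp = effect / np.sqrt(2.0 / n)
        blob = np.zeros_like(mask)
        blob[2:8, 2:8, :] = True
        observed = tmap.data[blob].mean()
        # voxel t values are iid across the blob; allow 2 SE of the mean
        se = tmap.data[blob].std(ddof=1) / np.sqrt(blob.sum())
        assert abs(observed - ncp) < max(2 * se, 0.15) + 0.05 * ncp

    def test_zero_variance_voxels_flagged(self):
        images = np.full((10, 5, 5, 5), 3.0)
        images[5:] += 1.0  # deterministic effect, zero residual variance
        mask = np.ones((5, 5, 5), bool)
        design = two_group_design(5)
        tmap = fit_glm(images, mask, design,
                       Contrast(kind="t", weights=(1.0, -1.0)))
        assert tmap.n_degenerate == mask.sum()
        assert np.isnan(tmap.data[mask]).all()

    def test_grid_mismatch_rejected(self, rng):
        images = rng.normal(size=(4, 5, 5, 5))
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(2)
        with pytest.raises(ValueError, match="mask grid"):
            fit_glm(images, mask, design, Contrast(kind="F"))


class TestLabelClusters:
    def test_single_voxel(self):
        binary = np.zeros((5, 5, 5), bool)
        binary[2, 2, 2] = True
        labels, extents = label_clusters(binary)
        assert labels.max() == 1 and list(extents) == [1]

    def test_corner_touch_connectivity(self):
        binary = np.zeros((4, 4, 4), bool)
        binary[1, 1, 1] = True
        binary[2, 2, 2] = True  # touch only at a corner
        _, extents26 = label_clusters(binary, 26)
        _, extents6 = label_clusters(binary, 6)
        assert len(extents26) == 1
        assert len(extents6) == 2

    def test_edge_touch(self):
        binary = np.zeros((4, 4, 4), bool)
        binary[1, 1, 1] = True
        binary[1, 2, 2] = True  # share an edge
        assert len(label_clusters(binary, 26)[1]) == 1
        assert len(label_clusters(binary, 18)[1]) == 1
        assert len(label_clusters(binary, 6)[1]) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(5):
            shape = tuple(rng.integers(4, 12, size=3))
            binary = rng.random(shape) < 0.3
            labels, extents = label_clusters(binary, connectivity)
            oracle = flood_fill_oracle(binary, connectivity)
            assert labels.max() == oracle.max()
            # same partition: one-to-one label correspondence
            for k in range(1, oracle.max() + 1):
                ours = labels[oracle == k]
                assert len(np.unique(ours)) == 1 and ours[0] > 0
            assert sorted(extents) == sorted(
                np.bincount(oracle.ravel())[1:].tolist()
            )


def brute_force_permutation_p(Y, X, Z, c, threshold, connectivity, shape, mask):
    """Independent exhaustive Freedman-Lane cluster test (own OLS + BFS)."""
    n = Y.shape[0]

    def tmap(data):
        beta, *_ = np.linalg.lstsq(X, data, rcond=None)
        resid = data - X @ beta
        dof = n - np.linalg.matrix_rank(X)
        sigma2 = (resid**2).sum(axis=0) / dof
        cov = c @ np.linalg.pinv(X.T @ X) @ c
        with np.errstate(divide="ignore", invalid="ignore"):
            return (c @ beta) / np.sqrt(cov * sigma2)

    def max_extent(tvals):
        binary = np.zeros(shape, bool)
        binary[mask] = np.nan_to_num(tvals, nan=-np.inf) > threshold
        labels = flood_fill_oracle(binary, connectivity)
        if labels.max() == 0:
            return 0, labels
        return np.bincount(labels.ravel())[1:].max(), labels

    gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ gamma
    resid = Y - fitted
    obs_t = tmap(Y)
    obs_max, obs_labels = max_extent(obs_t)
    extents = np.bincount(obs_labels.ravel())[1:]
    maxima = []
    for order in itertools.permutations(range(n)):
        maxima.append(max_extent(tmap(fitted + resid[list(order)]))[0])
    maxima = np.asarray(maxima)
    return {
        "extents": sorted(extents.tolist()),
        "pvals": sorted(
            float((maxima >= e).sum()) / len(maxima) for e in extents
        ),
    }


class TestPermutationInference:
    def test_vacuous_threshold_empty_table(self, rng):
        images = rng.normal(size=(20, 6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(10)
        clusters, _, _ = permutation_cluster_inference(
            images, mask, design, Contrast(kind="t", weights=(1.0, -1.0)),
            PermutationConfig(n_permutations=50, cluster_forming_t=1e6, seed=0),
        )
        assert len(clusters) == 0

    def test_seed_determinism(self, rng):
        images = rng.normal(size=(20, 6, 6, 6))
        images[10:, 2:4, 2:4, 2:4] += 2.0
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(10)
        contrast = Contrast(kind="t", weights=(-1.0, 1.0))
        cfg = PermutationConfig(n_permutations=100, seed=7)
        a, _, _ = permutation_cluster_inference(images, mask, design, contrast, cfg)
        b, _, _ = permutation_cluster_inference(images, mask, design, contrast, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_in_valid_range(self, rng):
        images = rng.normal(size=(16, 6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(8)
        clusters, _, meta = permutation_cluster_inference(
            images, mask, design, Contrast(kind="t", weights=(1.0, -1.0)),
            PermutationConfig(n_permutations=99, cluster_forming_t=1.5, seed=1),
        )
        if len(clusters):
            assert (clusters["p_fwe"] >= 1.0 / (meta["n_permutations"] + 1)).all()
            assert (clusters["p_fwe"] <= 1.0).all()

    def test_fwe_monotonicity(self, rng):
        images = rng.normal(size=(20, 8, 8, 8))
        images[10:, 1:4, 1:4, 1:4] += 1.5
        mask = np.ones((8, 8, 8), bool)
        design = two_group_design(10)
        clusters, _, _ = permutation_cluster_inference(
            images, mask, design, Contrast(kind="t", weights=(-1.0, 1.0)),
            PermutationConfig(n_permutations=200, cluster_forming_t=1.5, seed=3),
        )
        if len(clusters) > 1:
            ordered = clusters.sort_values("cluster_stat", ascending=False)
            assert ordered["p_fwe"].is_monotonic_increasing

    def test_exact_enumeration_small_n(self, rng):
        images = rng.normal(size=(5, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        design = make_group_design(["a", "a", "a", "b", "b"],
                                   group_order=["a", "b"])
        clusters, _, meta = permutation_cluster_inference(
            images, mask, design, Contrast(kind="t", weights=(1.0, -1.0)),
            PermutationConfig(n_permutations=500, cluster_forming_t=1.0, seed=0),
        )
        assert meta["exact_enumeration"] is True
        assert meta["n_permutations"] == math.factorial(5)
        if len(clusters):
            steps = clusters["p_fwe"] * math.factorial(5)
            np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_matches_bruteforce_enumeration_oracle(self, rng):
        # full independent reimplementation on a tiny instance
        n = 6
        shape = (4, 4, 3)
        images = rng.normal(size=(n, *shape))
        images[3:, 1:3, 1:3, :] += 1.6
        mask = np.ones(shape, bool)
        cov = rng.normal(size=n)
        design = make_group_design(
            ["a"] * 3 + ["b"] * 3, pd.DataFrame({"cov": cov}),
            group_order=["a", "b"],
        )
        contrast = Contrast(kind="t", weights=(-1.0, 1.0))
        cfg = PermutationConfig(n_permutations=10_000, cluster_forming_t=1.2,
                                connectivity=26, seed=0)
        clusters, _, meta = permutation_cluster_inference(
            images, mask, design, contrast, cfg
        )
        assert meta["exact_enumeration"]
        X = design.matrix
        Z = design.nuisance_matrix()
        c = np.array([-1.0, 1.0, 0.0])
        oracle = brute_force_permutation_p(
            images.reshape(n, -1), X, Z, c, 1.2, 26, shape, mask
        )
        assert sorted(clusters["extent"].tolist()) == oracle["extents"]
        np.testing.assert_allclose(
            sorted(clusters["p_fwe"].tolist()), oracle["pvals"], atol=1e-12
        )

    def test_low_perm_warning(self, rng):
        images = rng.normal(size=(12, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        design = two_group_design(6)
        with pytest.warns(UserWarning, match="cannot resolve"):
            permutation_cluster_inference(
                images, mask, design, Contrast(kind="t", weights=(1.0, -1.0)),
                PermutationConfig(n_permutations=10, seed=0),
            )

    def test_cluster_mass_option(self, rng):
        images = rng.normal(size=(20, 6, 6, 6))
        images[10:, 1:4, 1:4, 1:4] += 2.0
        mask = np.ones((6, 6, 6), bool)
        design = two_group_design(10)
        clusters, _, meta = permutation_cluster_inference(
            images, mask, design, Contrast(kind="t", weights=(-1.0, 1.0)),
            PermutationConfig(n_permutations=100, seed=2, cluster_stat="mass"),
        )
        assert meta["cluster_stat"] == "mass"
        if len(clusters):
            assert (clusters["cluster_stat"] > 0).all()


class TestTrend:
    @staticmethod
    def _ordered_images(rng, means, n_per=8, noise=1.0, shape=(6, 6, 6)):
        groups = []
        images = []
        for g, m in zip(("c", "t1", "t2", "t3"), means):
            groups += [g] * n_per
            images.append(rng.normal(m, noise, size=(n_per, *shape)))
        design = make_group_design(groups, group_order=["c", "t1", "t2", "t3"])
        return np.concatenate(images), design

    def test_perfect_trend_all_suprathreshold(self, rng):
        images, design = self._ordered_images(
            rng, means=[-3.0, -1.0, 1.0, 3.0], noise=1e-6
        )
        mask = np.ones((6, 6, 6), bool)
        _, stat_map, meta = trend_inference(
            images, mask, design, "ascending",
            PermutationConfig(n_permutations=50, seed=0),
        )
        assert (stat_map.data[mask] > meta["forming_threshold"]).all()

    def test_descending_blind_to_increase(self, rng):
        images, design = self._ordered_images(
            rng, means=[0.0, 1.0, 2.0, 3.0], noise=1.0
        )
        mask = np.ones((6, 6, 6), bool)
        clusters, _, _ = trend_inference(
            images, mask, design, "descending",
            PermutationConfig(n_permutations=100, seed=1),
        )
        assert not clusters["significant"].any() if len(clusters) else True

    def test_group_count_mismatch(self, rng):
        design = make_group_design(["a"] * 4 + ["b"] * 4,
                                   group_order=["a", "b"])
        images = rng.normal(size=(8, 4, 4, 4))
        with pytest.raises(ValueError, match="4 ordered groups"):
            trend_inference(images, np.ones((4, 4, 4), bool), design,
                            "ascending", PermutationConfig(n_permutations=10))

    def test_weights(self):
        assert ASCENDING_WEIGHTS == (-3.0, -1.0, 1.0, 3.0)
        assert sum(ASCENDING_WEIGHTS) == 0
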