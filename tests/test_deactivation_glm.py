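import numpy as np
import pytest
from scipy import stats

from dmnclass.study_design import (
    REST,
    AcquisitionParams,
    Block,
    SessionDesign,
)
from dmnclass.deactivation_glm import (
    build_design_matrix,
    cluster_extent_threshold,
    connectivity_structure,
    double_gamma_hrf,
    extract_clusters,
    fdr_threshold,
    fit_glm,
    group_ttest,
    StatMap,
)


def _design(task_dur=24.0, n_cycles=6, rest_dur=24.0, tr=1.0):
    blocks, t = [], 0.0
    for _ in range(n_cycles):
        blocks.append(Block(REST, t, rest_dur))
        t += rest_dur
        blocks.append(Block("task", t, task_dur))
        t += task_dur
    blocks.append(Block(REST, t, rest_dur))
    t += rest_dur
    return SessionDesign(
        study_id="sim", blocks=tuple(blocks),
        acquisition=AcquisitionParams(tr=tr, n_volumes=int(t / tr)),
    )


class TestHrfAndDesign:
    def test_hrf_impulse_peak_5_to_8s(self):
        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t)
        peak = t[np.argmax(h)]
        assert 4.0 <= peak <= 8.0

    def test_event_regressor_peak_lag(self):
        # a brief (1 s) boxcar behaves like an impulse: response peak
        # 5-8 s after onset
        design = SessionDesign(
            study_id="evt",
            blocks=(Block(REST, 0, 20), Block("task", 20, 1.0),
                    Block(REST, 21, 39)),
            acquisition=AcquisitionParams(tr=1.0, n_volumes=60),
        )
        X = build_design_matrix(design)
        col = X.matrix[:, X.column_names.index("task")]
        lag = np.argmax(col) - 20
        assert 5 <= lag <= 8

    def test_column_integral_matches_block_seconds(self):
        # the HRF kernel is unit-integral, so a convolved boxcar integrates
        # to the number of task seconds
        design = _design(task_dur=24.0, n_cycles=1)
        X = build_design_matrix(design)
        col = X.matrix[:, X.column_names.index("task")]
        assert col.sum() * design.acquisition.tr == pytest.approx(24.0, rel=0.01)

    def test_rest_only_design_has_no_task_columns(self):
        design = SessionDesign(
            study_id="rest_only",
            blocks=(Block(REST, 0, 60),),
            acquisition=AcquisitionParams(tr=1.0, n_volumes=60),
        )
        X = build_design_matrix(design, include_rest_regressor=False)
        assert X.column_names == ("intercept",)

    def test_unknown_hrf_error(self, designs):
        with pytest.raises(ValueError, match="HRF"):
            build_design_matrix(designs[0], hrf="triple_gamma")

    def test_condition_grouping_collapses_columns(self, designs):
        X = build_design_matrix(designs[0])  # pun + literal -> language
        assert "language" in X.condition_names
        assert "pun" not in X.condition_names


class TestFitGlm:
    def test_planted_deactivation_recovered(self):
        design = _design()
        X = build_design_matrix(design)
        rng = np.random.default_rng(0)
        T = design.acquisition.n_volumes
        task = X.matrix[:, X.column_names.index("task")]
        data = np.vstack([
            -1.0 * task + rng.standard_normal(T),  # deactivating node
            rng.standard_normal(T),                # null node
        ])
        stat = fit_glm(data, X, {"rest": 1.0, "task": -1.0})
        assert stat.values[0] > 3.0          # rest > task
        assert abs(stat.values[1]) < 3.0

    def test_zero_contrast_gives_zero_t(self):
        design = _design(n_cycles=2)
        X = build_design_matrix(design)
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, design.acquisition.n_volumes))
        stat = fit_glm(data, X, np.zeros(X.matrix.shape[1]))
        np.testing.assert_allclose(stat.values, 0.0, atol=1e-12)

    def test_null_calibration(self):
        # pure noise: two-sided p<0.001 exceedance rate ~0.002 within +-50%
        design = _design(n_cycles=3)
        X = build_design_matrix(design)
        rng = np.random.default_rng(2)
        n_vox = 10_000
        data = rng.standard_normal((n_vox, design.acquisition.n_volumes))
        stat = fit_glm(data, X, {"rest": 1.0, "task": -1.0})
        thr = stats.t.isf(0.001, stat.df)
        rate = np.mean(np.abs(stat.values) > thr)
        assert 0.001 <= rate <= 0.003

    def test_df(self):
        design = _design(n_cycles=2)
        X = build_design_matrix(design)
        data = np.random.default_rng(3).standard_normal(
            (2, design.acquisition.n_volumes))
        stat = fit_glm(data, X, {"task": 1.0})
        assert stat.df == design.acquisition.n_volumes - np.linalg.matrix_rank(X.matrix)

    def test_volume_mismatch_error(self):
        design = _design(n_cycles=2)
        X = build_design_matrix(design)
        with pytest.raises(ValueError, match="volumes"):
            fit_glm(np.zeros((2, 10)), X, {"task": 1.0})


class TestGroupTtest:
    def test_identical_groups_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 20))
        stat = group_ttest(a, a.copy())
        np.testing.assert_allclose(stat.values, 0.0, atol=1e-12)

    def test_matches_closed_form_pooled_t(self):
        # groups of constants a, b with per-subject jitter, n1=13, n2=14
        rng = np.random.default_rng(1)
        A = 2.0 + 0.5 * rng.standard_normal((13, 8))
        B = 1.0 + 0.5 * rng.standard_normal((14, 8))
        stat = group_ttest(A, B)
        n1, n2 = 13, 14
        sp2 = ((n1 - 1) * A.var(0, ddof=1) + (n2 - 1) * B.var(0, ddof=1)) / (n1 + n2 - 2)
        expected = (A.mean(0) - B.mean(0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        np.testing.assert_allclose(stat.values, expected, rtol=1e-12)
        assert stat.df == 25

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((13, 50))
        B = rng.standard_normal((14, 50)) + 0.3
        stat = group_ttest(A, B)
        oracle = stats.ttest_ind(A, B, axis=0, equal_var=True)
        np.testing.assert_allclose(stat.values, oracle.statistic, rtol=1e-10)

    def test_one_sample(self):
        rng = np.random.default_rng(3)
        A = 1.0 + rng.standard_normal((10, 30))
        stat = group_ttest(A)
        oracle = stats.ttest_1samp(A, 0.0, axis=0)
        np.testing.assert_allclose(stat.values, oracle.statistic, rtol=1e-10)
        assert stat.df == 9

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            group_ttest(np.zeros((1, 5)), np.zeros((5, 5)))

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((13, 100))
        B = rng.standard_normal((14, 100))
        B[:, :10] += 2.0
        stat = group_ttest(B, A)
        thr = stats.t.isf(0.001, stat.df)
        assert np.all(stat.values[:10] > thr)
        assert np.mean(np.abs(stat.values[10:]) > thr) < 0.05


def _bh_bruteforce(p, q):
    """Independent step-up oracle: check every k explicitly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


class TestFdr:
    def test_hand_computed_case(self):
        # thresholds {0.0167, 0.0333, 0.05}: 0.02 <= 0.0333 so both of the
        # two smallest p-values are rejected
        reject = fdr_threshold(np.array([0.001, 0.02, 0.9]), q=0.05)
        np.testing.assert_array_equal(reject, [True, True, False])

    def test_all_ones_none_rejected(self):
        assert not fdr_threshold(np.ones(10), q=0.05).any()

    def test_empty_input(self):
        assert fdr_threshold(np.array([]), q=0.05).size == 0

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([0.5, 1.2]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 50))
        np.testing.assert_array_equal(
            fdr_threshold(p, q=0.05), _bh_bruteforce(p, 0.05)
        )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        p = rng.uniform(size=200) ** 2
        reject = fdr_threshold(p, q=0.05)
        sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(reject, sm_reject)


class TestClusterExtent:
    def test_alpha_ge_1_gives_kmin_1(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        null = cluster_extent_threshold(mask, alpha=1.0, n_sim=100)
        assert null.k_min == 1

    def test_independent_voxel_regime(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        null = cluster_extent_threshold(
            mask, smoothness_fwhm=0.0, voxel_p=0.001, n_sim=500,
            alpha=0.05, seed=0,
        )
        assert null.k_min in (1, 2)
        # P(any suprathreshold voxel) = 1 - 0.999^1000 ~ 0.632
        assert abs(null.fwe_rate(1) - 0.632) < 0.08

    def test_kmin_nondecreasing_in_fwhm(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        kmins = [
            cluster_extent_threshold(
                mask, smoothness_fwhm=fwhm, voxel_p=0.01, n_sim=2000,
                alpha=0.05, voxel_size=(3.0, 3.0, 3.0), seed=1,
            ).k_min
            for fwhm in (0.0, 6.0, 12.0)
        ]
        assert kmins == sorted(kmins)

    def test_small_nsim_warns(self):
        with pytest.warns(UserWarning):
            cluster_extent_threshold(np.ones((4, 4, 4), dtype=bool), n_sim=50)

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            cluster_extent_threshold(np.zeros((4, 4, 4), dtype=bool))

    def test_seeded_reproducible(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        a = cluster_extent_threshold(mask, n_sim=200, seed=7)
        b = cluster_extent_threshold(mask, n_sim=200, seed=7)
        np.testing.assert_array_equal(a.max_sizes, b.max_sizes)


class TestExtractClusters:
    def _map(self, values):
        return StatMap(values=values, df=10.0)

    def test_single_voxel_below_kmin(self):
        v = np.zeros((6, 6, 6))
        v[3, 3, 3] = 5.0
        table = extract_clusters(self._map(v), 3.0, k_min=2)
        assert len(table) == 0

    def test_two_touching_voxels_26_connectivity(self):
        v = np.zeros((6, 6, 6))
        v[3, 3, 3] = 5.0
        v[4, 4, 4] = 4.0  # corner-adjacent
        table = extract_clusters(self._map(v), 3.0, k_min=2, connectivity=26)
        assert len(table) == 1
        assert table.clusters[0].size == 2
        assert table.clusters[0].peak_stat == 5.0

    def test_corner_voxels_split_under_6_connectivity(self):
        v = np.zeros((6, 6, 6))
        v[3, 3, 3] = 5.0
        v[4, 4, 4] = 4.0
        table = extract_clusters(self._map(v), 3.0, k_min=1, connectivity=6)
        assert len(table) == 2

    def test_planted_blob_survives_110(self):
        v = np.zeros((12, 12, 12))
        v[3:8, 3:8, 3:8] = 4.0  # 125 contiguous voxels
        table = extract_clusters(self._map(v), 3.0, k_min=110)
        assert len(table) == 1
        assert table.clusters[0].size == 125

    def test_peak_mm_via_affine(self):
        v = np.zeros((6, 6, 6))
        v[2, 3, 4] = 5.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-9.0, -9.0, -9.0)
        table = extract_clusters(
            StatMap(values=v, df=10.0, affine=affine), 3.0, k_min=1
        )
        assert table.clusters[0].peak_mm == (-3.0, 0.0, 3.0)

    def test_flip_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((10, 10, 10))
        t1 = extract_clusters(self._map(v), 2.0, k_min=1)
        t2 = extract_clusters(self._map(np.flip(v, axis=0).copy()), 2.0, k_min=1)
        assert sorted(c.size for c in t1) == sorted(c.size for c in t2)

    def test_connectivity_structure_values(self):
        assert connectivity_structure(6).sum() == 7
        assert connectivity_structure(18).sum() == 19
        assert connectivity_structure(26).sum() == 27
        with pytest.raises(ValueError):
            connectivity_structure(10)


class TestResidualOrthogonality:
    def test_glm_residuals_orthogonal_to_design(self):
        design = _design(n_cycles=2)
        X = build_design_matrix(design)
        rng = np.random.default_rng(6)
        T = design.acquisition.n_volumes
        Y = rng.standard_normal((4, T))
        beta = np.linalg.pinv(X.matrix) @ Y.T
        resid = Y.T - X.matrix @ beta
        assert np.abs(X.matrix.T @ resid).max() < 1e-9
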