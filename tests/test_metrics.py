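import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from sklearn.covariance import LedoitWolf

from lamsim import glm, metrics as met
from lamsim.metrics import LaminarProfile


def brute_force_orthogonal_slope(x, y):
    """Independent oracle: minimize summed perpendicular squared distances.

    Parameterized by line angle; coarse grid scan followed by bounded Brent
    refinement around the best angle.
    """
    xc = x - x.mean()
    yc = y - y.mean()

    def sse(theta):
        b = np.tan(theta)
        return np.sum((yc - b * xc) ** 2) / (1 + b**2)

    thetas = np.linspace(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6, 20001)
    best = thetas[np.argmin([sse(t) for t in thetas])]
    width = thetas[1] - thetas[0]
    res = minimize_scalar(
        sse, bounds=(best - 2 * width, best + 2 * width), method="bounded",
        options={"xatol": 1e-14},
    )
    return np.tan(res.x)


def make_contrasts(dplus, dminus):
    return glm.ContrastEstimates(
        taskdplus=np.asarray(dplus, dtype=float),
        taskdminus=np.asarray(dminus, dtype=float),
    )


ONE_LAYER_EACH = np.array([0, 0, 1, 1, 2, 2])


class TestDemingSlope:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert met.deming_slope(x, 0.5 * x) == pytest.approx(0.5, abs=1e-12)

    def test_swap_gives_reciprocal(self, rng):
        x = rng.standard_normal(50)
        y = 0.7 * x + rng.normal(0, 0.3, 50)
        forward = met.deming_slope(x, y)
        backward = met.deming_slope(y, x)
        assert forward == pytest.approx(1.0 / backward, rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_perpendicular_sse_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(10)
        y = 0.8 * x + r.normal(0, 0.5, 10)
        assert met.deming_slope(x, y) == pytest.approx(
            brute_force_orthogonal_slope(x, y), abs=1e-6
        )

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(30)
        y = 1.3 * x + rng.normal(0, 0.2, 30)
        assert met.deming_slope(x + 17.0, y - 4.0) == pytest.approx(
            met.deming_slope(x, y), rel=1e-10
        )

    def test_zero_covariance_is_missing(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert np.isnan(met.deming_slope(x, y))


class TestVoxelRatio:
    def test_arithmetic(self):
        c = make_contrasts([2, 4, 0, 0, 0, 0], [3, 6, 1, 1, 1, 1])
        profile = met.metric_voxel_ratio(c, ONE_LAYER_EACH)
        assert profile.values[0] == pytest.approx(2 / 3)

    def test_heavy_tail_sensitivity(self):
        c = make_contrasts([1, 1, 0, 0, 0, 0], [1, 1e-6, 1, 1, 1, 1])
        profile = met.metric_voxel_ratio(c, ONE_LAYER_EACH)
        assert profile.values[0] == pytest.approx(5e5, rel=1e-6)

    def test_zero_denominators_excluded(self):
        c = make_contrasts([1, 1, 1, 1, 1, 1], [0, 2, 1, 1, 1, 1])
        profile = met.metric_voxel_ratio(c, ONE_LAYER_EACH)
        assert profile.values[0] == pytest.approx(0.5)
        assert profile.n_used[0] == 1

    def test_all_zero_denominators_missing(self):
        c = make_contrasts([1, 1, 1, 1, 1, 1], [0, 0, 1, 1, 1, 1])
        profile = met.metric_voxel_ratio(c, ONE_LAYER_EACH)
        assert np.isnan(profile.values[0])


class TestRoiRatio:
    def test_arithmetic(self):
        c = make_contrasts([2, 4, 1, 1, 1, 1], [3, 6, 1, 1, 1, 1])
        profile = met.metric_roi_ratio(c, ONE_LAYER_EACH)
        assert profile.values[0] == pytest.approx(2 / 3)

    def test_scale_invariance(self, rng):
        dplus, dminus = rng.standard_normal(6), rng.standard_normal(6) + 2
        base = met.metric_roi_ratio(make_contrasts(dplus, dminus), ONE_LAYER_EACH)
        scaled = met.metric_roi_ratio(
            make_contrasts(5 * dplus, 5 * dminus), ONE_LAYER_EACH
        )
        np.testing.assert_allclose(scaled.values, base.values)

    def test_zero_denominator_missing(self):
        c = make_contrasts([1, 1, 1, 1, 1, 1], [1, -1, 1, 1, 1, 1])
        assert np.isnan(met.metric_roi_ratio(c, ONE_LAYER_EACH).values[0])


class TestMetricDeming:
    def test_exact_line_per_layer(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        layer = np.array([0] * 4 + [1] * 4 + [2] * 4)
        c = make_contrasts(np.tile(0.5 * x, 3), np.tile(x, 3))
        profile = met.metric_deming(c, layer)
        np.testing.assert_allclose(profile.values, 0.5, atol=1e-12)

    def test_too_few_voxels_missing(self):
        c = make_contrasts([1, 2, 1, 2, 3, 4], [1, 2, 1, 2, 3, 4])
        profile = met.metric_deming(c, ONE_LAYER_EACH)
        assert np.all(np.isnan(profile.values))


@settings(max_examples=30, deadline=None)
@given(
    scale=st.floats(0.1, 100.0),
    seed=st.integers(0, 1000),
)
def test_ratio_family_layer_rescale_invariance(scale, seed):
    # the mechanism by which a multiplicative layer bias cancels
    r = np.random.default_rng(seed)
    n = 30
    layer = np.repeat([0, 1, 2], n // 3)
    dminus = r.standard_normal(n) + 3
    dplus = 0.6 * dminus + r.normal(0, 0.1, n)
    factors = np.array([1.0, scale, 1 / scale])[layer]
    base = make_contrasts(dplus, dminus)
    scaled = make_contrasts(dplus * factors, dminus * factors)
    for metric in (met.metric_voxel_ratio, met.metric_roi_ratio, met.metric_deming):
        np.testing.assert_allclose(
            metric(scaled, layer).values, metric(base, layer).values, rtol=1e-9
        )


class TestRawProfile:
    def test_zero_data(self):
        profile = met.raw_contrast_profile(make_contrasts(np.zeros(6), np.zeros(6)), ONE_LAYER_EACH)
        np.testing.assert_allclose(profile.values, 0)

    def test_layer_means(self):
        c = make_contrasts([1, 3, 5, 7, 9, 11], np.ones(6))
        profile = met.raw_contrast_profile(c, ONE_LAYER_EACH)
        np.testing.assert_allclose(profile.values, [2, 6, 10])


class TestL2Norm:
    def test_normalization_arithmetic(self):
        betas = np.array([[3.0, 4.0, 0.0, 0.0]])
        norm = np.linalg.norm(betas)
        np.testing.assert_allclose(betas / norm, [[0.6, 0.8, 0.0, 0.0]])

    def test_per_voxel_scale_invariance(self, rng):
        labels = ("F135", "F45", "H135", "H45") + glm.NUISANCE_LABELS
        cond = rng.standard_normal((6, 4)) + 1
        nuis = rng.standard_normal((6, 4))
        fit_a = glm.BetaEstimates(np.hstack([cond, nuis]), np.zeros((6, 10)), labels)
        fit_b = glm.BetaEstimates(
            np.hstack([cond * rng.uniform(0.5, 2, (6, 1)), nuis]), np.zeros((6, 10)), labels
        )
        a = met.metric_l2norm([fit_a], ONE_LAYER_EACH)
        b = met.metric_l2norm([fit_b], ONE_LAYER_EACH)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_zero_norm_voxel_excluded(self, rng):
        labels = ("F135", "F45", "H135", "H45") + glm.NUISANCE_LABELS
        cond = rng.standard_normal((6, 4)) + 1
        cond[0] = 0.0
        fit = glm.BetaEstimates(
            np.hstack([cond, rng.standard_normal((6, 4))]), np.zeros((6, 10)), labels
        )
        profile = met.metric_l2norm([fit], ONE_LAYER_EACH)
        assert profile.n_used[0] == 1


def _clustered_block_betas(rng, n_voxels=12, separation=10.0, n_runs=4, n_blocks=20):
    layer = np.repeat([0, 1, 2], n_voxels // 3)
    direction = rng.standard_normal(n_voxels)
    betas, labels = [], []
    for _ in range(n_runs):
        cats = np.array(["face", "house"] * (n_blocks // 2), dtype=object)
        signs = np.where(cats == "face", 1.0, -1.0)
        patterns = separation * np.outer(direction, signs)
        patterns += rng.standard_normal(patterns.shape)
        betas.append(patterns)
        labels.append(cats)
    return betas, labels, layer


class TestSVM:
    def test_separable_clusters_reach_perfect_accuracy(self, rng):
        betas, labels, layer = _clustered_block_betas(rng, separation=50.0)
        profile = met.metric_svm(betas, labels, layer)
        np.testing.assert_allclose(profile.values, 1.0)

    def test_accuracy_bounded(self, rng):
        betas, labels, layer = _clustered_block_betas(rng, separation=0.0)
        profile = met.metric_svm(betas, labels, layer)
        assert np.all(profile.values >= 0) and np.all(profile.values <= 1)

    def test_permuted_labels_give_chance(self):
        # Monte-Carlo oracle: permutation chance level is 0.5
        r = np.random.default_rng(0)
        accs = []
        for _ in range(60):
            betas, labels, layer = _clustered_block_betas(r, n_voxels=6, separation=0.0)
            shuffled = [r.permutation(l) for l in labels]
            accs.append(met.metric_svm(betas, shuffled, layer).values.mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_run_rejected(self, rng):
        betas, labels, layer = _clustered_block_betas(rng)
        labels[0][:] = "face"
        with pytest.raises(ValueError):
            met.metric_svm(betas, labels, layer)


class TestLedoitWolf:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn(self, seed):
        r = np.random.default_rng(seed)
        samples = r.standard_normal((40, 6)) @ r.standard_normal((6, 6))
        cov, shrinkage = met.ledoit_wolf_covariance(samples)
        ref = LedoitWolf(assume_centered=True).fit(samples)
        np.testing.assert_allclose(cov, ref.covariance_, rtol=1e-8)
        assert shrinkage == pytest.approx(ref.shrinkage_, rel=1e-8)


class TestLDC:
    def test_zero_test_contrast_gives_zero(self, rng):
        layer = np.repeat([0, 1, 2], 2)
        contrasts = [np.zeros(6)] * 4
        residuals = [rng.standard_normal((6, 40)) for _ in range(4)]
        profile = met.metric_ldc(contrasts, residuals, layer)
        np.testing.assert_allclose(profile.values, 0, atol=1e-12)

    def test_identity_covariance_reduction(self, rng):
        # residual samples engineered so the empirical covariance is exactly
        # the identity: LDC reduces to ||c||^2 / sqrt(n_voxels)
        p, n = 2, 40
        layer = np.repeat([0, 1, 2], p)
        c = rng.standard_normal(3 * p)
        residuals = []
        for _ in range(2):
            run_res = np.zeros((3 * p, n))
            for lay in range(3):
                q, _ = np.linalg.qr(rng.standard_normal((n, p)))
                run_res[lay * p : (lay + 1) * p] = (q * np.sqrt(n)).T
            residuals.append(run_res)
        profile = met.metric_ldc([c, c], residuals, layer)
        for lay in range(3):
            expected = np.sum(c[lay * p : (lay + 1) * p] ** 2) / np.sqrt(p)
            assert profile.values[lay] == pytest.approx(expected, rel=1e-9)

    def test_matches_dense_oracle(self):
        # 5 voxels per layer, 30 samples per run: direct computation with
        # sklearn's shrinkage and an explicit matrix inverse
        r = np.random.default_rng(42)
        p, n_runs = 5, 4
        layer = np.repeat([0, 1, 2], p)
        contrasts = [r.standard_normal(3 * p) for _ in range(n_runs)]
        residuals = [r.standard_normal((3 * p, 30)) for _ in range(n_runs)]
        profile = met.metric_ldc(contrasts, residuals, layer)

        for lay in range(3):
            mask = layer == lay
            stats = []
            for test in range(n_runs):
                train = [q for q in range(n_runs) if q != test]
                pooled = np.vstack([residuals[q][mask].T for q in train])
                cov = LedoitWolf(assume_centered=True).fit(pooled).covariance_
                c_train = np.mean([contrasts[q][mask] for q in train], axis=0)
                weights = c_train @ np.linalg.inv(cov)
                stats.append(weights @ contrasts[test][mask])
            expected = np.mean(stats) / np.sqrt(p)
            assert profile.values[lay] == pytest.approx(expected, rel=1e-8)

    def test_label_swap_flips_sign(self, rng):
        layer = np.repeat([0, 1, 2], 3)
        contrasts = [rng.standard_normal(9) for _ in range(4)]
        residuals = [rng.standard_normal((9, 40)) for _ in range(4)]
        base = met.metric_ldc(contrasts, residuals, layer)
        flipped = met.metric_ldc([-c for c in contrasts], residuals, layer)
        np.testing.assert_allclose(flipped.values, base.values, rtol=1e-10)


class TestContributionScores:
    def test_v_profile(self):
        bias, attention = met.contribution_scores(np.array([3.0, 2.0, 3.0]))
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert attention == pytest.approx(0.375, abs=1e-12)

    def test_linear_bias_profile(self):
        bias, attention = met.contribution_scores(np.array([3.0, 2.0, 1.0]))
        assert bias == pytest.approx(1.0, abs=1e-12)
        assert attention == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0.5, 1.0, -3.0])
    def test_flat_profile_scores_zero(self, k):
        bias, attention = met.contribution_scores(np.array([k, k, k]))
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert attention == pytest.approx(0.0, abs=1e-12)

    def test_near_zero_mean_is_missing(self):
        bias, attention = met.contribution_scores(np.array([1.0, 0.0, -1.0]))
        assert np.isnan(bias) and np.isnan(attention)

    def test_accepts_profile_object(self):
        profile = LaminarProfile("x", np.array([3.0, 2.0, 3.0]), np.ones(3))
        assert met.contribution_scores(profile)[1] == pytest.approx(0.375)
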