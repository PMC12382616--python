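"""Gamma HRF, PC1 nuisance, design-matrix assembly, and the voxel GLM."""

import numpy as np
import pytest

import rewardmap as rm
from rewardmap.exceptions import (
    DegenerateInputError,
    InvalidContrastError,
    InvalidInputError,
    InvalidParameterError,
)
from rewardmap.glm import (
    DEFAULT_ROLES,
    HRFParams,
    event_regressor,
    gamma_hrf,
)
from rewardmap.synthetic import simulate_motion


class TestGammaHRF:
    def test_causal_before_delay(self):
        t = np.linspace(-5, 30, 701)
        h = gamma_hrf(t, HRFParams(delay=2.5))
        assert np.all(h[t < 2.5] == 0)

    def test_analytic_peak_location(self):
        """The gamma kernel's mode is (shape_n - 1) * tau past the delay."""
        t = np.arange(0, 20, 0.1)
        h = gamma_hrf(t, HRFParams(shape_n=3, tau=1.25, delay=0.0))
        assert t[np.argmax(h)] == pytest.approx(2.5)

    def test_unit_peak_normalisation(self):
        t = np.arange(0, 40, 0.001)
        for params in [HRFParams(), HRFParams(shape_n=1, tau=2.0, delay=0.0),
                       HRFParams(shape_n=5, tau=0.9, delay=1.0)]:
            assert gamma_hrf(t, params).max() == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            HRFParams(tau=0.0)
        with pytest.raises(InvalidParameterError):
            HRFParams(shape_n=0)


def test_event_regressor_matches_direct_summation():
    """Single and multiple off-grid events against a per-event loop."""
    frame_times = np.arange(240) * 2.5
    params = HRFParams()
    onsets = [11.5, 100.0, 101.5, 300.25]
    reg = event_regressor(onsets, frame_times, params)
    oracle = np.zeros(240)
    for onset in onsets:
        for k, t in enumerate(frame_times):
            oracle[k] += gamma_hrf(np.array([t - onset]), params)[0]
    assert np.allclose(reg, oracle, atol=1e-12)
    assert np.all(event_regressor([], frame_times, params) == 0)


class TestPC1:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        n, v = 240, 50
        g = np.sin(np.linspace(0, 8 * np.pi, n))
        gains = rng.uniform(0.5, 2.0, v)
        data = 100.0 + gains[:, None] * g[None, :]
        pc1 = rm.compute_pc1(data)
        r = np.corrcoef(pc1, g)[0, 1]
        assert abs(r) > 0.999

    def test_white_noise_explained_variance_is_small(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(1000, 240))
        centered = data - data.mean(axis=1, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        evr = s[0] ** 2 / (s**2).sum()
        assert evr < 0.05
        # and the returned course is the corresponding singular vector
        pc1 = rm.compute_pc1(data)
        assert np.allclose(np.linalg.norm(pc1), 1.0)

    def test_two_identical_voxels(self):
        t = np.arange(20, dtype=float)
        course = np.sin(t)
        data = np.vstack([10 + course, 10 + course])
        pc1 = rm.compute_pc1(data)
        centered = course - course.mean()
        assert abs(abs(np.corrcoef(pc1, centered)[0, 1]) - 1.0) < 1e-12

    def test_sign_positively_correlates_with_global_mean(self):
        rng = np.random.default_rng(2)
        g = np.cos(np.linspace(0, 6 * np.pi, 100))
        data = 5 + np.outer(rng.uniform(0.5, 1.5, 30), g)
        data += rng.normal(0, 0.01, data.shape)
        pc1 = rm.compute_pc1(data)
        assert np.dot(pc1, data.mean(axis=0) - data.mean()) > 0

    def test_matches_sklearn_truncated_svd(self):
        """Independent solver check: the time-domain PC1 of the row-centred
        voxels x time matrix equals the top right singular vector."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        data = rng.normal(size=(40, 60)) + np.outer(
            rng.normal(size=40), np.sin(np.arange(60)))
        ours = rm.compute_pc1(data)
        centered = data - data.mean(axis=1, keepdims=True)
        svd = sklearn.TruncatedSVD(
            n_components=1, algorithm="arpack", random_state=0).fit(centered)
        theirs = svd.components_[0]
        assert min(np.linalg.norm(ours - theirs),
                   np.linalg.norm(ours + theirs)) < 1e-8

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            rm.compute_pc1(np.ones((10, 30)))
        with pytest.raises(InvalidInputError):
            rm.compute_pc1(np.ones((1, 30)))


class TestDesignMatrix:
    def test_eleven_columns_and_contrast(self, records):
        pc1 = np.sin(np.arange(240) / 10)
        motion = simulate_motion(240, np.random.default_rng(0))
        X = rm.build_design_matrix(records, motion, pc1)
        assert X.p == 11
        assert X.column_roles == DEFAULT_ROLES
        expected = np.zeros(11)
        expected[7], expected[8] = -1.0, 1.0  # loss, win feedback
        assert np.array_equal(X.contrast, expected)
        # missed trials contribute no events anywhere
        n_missed = sum(r.outcome == "missed" for r in records)
        assert n_missed > 0

    def test_two_task_layout(self, records):
        pc1 = np.sin(np.arange(240) / 10)
        motion = simulate_motion(240, np.random.default_rng(0))
        X = rm.build_design_matrix(records, motion, pc1, layout="two_task")
        assert X.p == 9
        assert X.contrast[-2:].tolist() == [-1.0, 1.0]

    def test_event_column_matches_convolution_oracle(self):
        recs = [rm.TrialRecord(1, 0.5, 50, "loss", -50, 25.0, 26.5)]
        pc1 = np.zeros(240)
        motion = np.zeros((240, 6))
        X = rm.build_design_matrix(recs, motion, pc1)
        col = X.column("loss_feedback")
        t = np.arange(240) * 2.5
        assert np.allclose(col, gamma_hrf(t - 26.5, HRFParams()))
        assert np.all(X.column("win_feedback") == 0)

    def test_zero_win_trials_flag_rank_deficient_contrast(self):
        rng = np.random.default_rng(4)
        recs = [rm.TrialRecord(i + 1, 0.5, 10, "loss", -10,
                               i * 2.5, i * 2.5 + 1.5) for i in range(240)]
        motion = simulate_motion(240, rng)
        pc1 = np.sin(np.arange(240) / 7)
        X = rm.build_design_matrix(recs, motion, pc1)
        assert np.all(X.column("win_feedback") == 0)
        y = rng.normal(size=(240, 5))
        res = rm.fit_glm(y, X)
        assert res.rank < X.p
        assert not res.contrast_estimable(X.contrast)
        with pytest.warns(UserWarning, match="not estimable"):
            res.tmap()

    def test_length_mismatch_raises(self, records):
        with pytest.raises(InvalidInputError):
            rm.build_design_matrix(records, np.zeros((100, 6)), np.zeros(240))


def _random_design(rng, n=240, p=11):
    X = rng.normal(size=(n, p))
    roles = tuple(f"col{i}" for i in range(p - 2)) + ("loss_feedback", "win_feedback")
    C = np.zeros(p)
    C[-2], C[-1] = -1.0, 1.0
    return rm.DesignMatrix(X, roles, C)


class TestFitGLM:
    def test_exact_fit_recovers_coefficients(self):
        rng = np.random.default_rng(5)
        X = _random_design(rng)
        b = rng.normal(size=(11, 20))
        y = X.values @ b
        res = rm.fit_glm(y, X, center=False)
        assert np.allclose(res.params, b, atol=1e-9)
        assert np.all(res.sigma2 < 1e-10 * y.var())

    def test_df_is_228_at_full_rank(self):
        rng = np.random.default_rng(6)
        X = _random_design(rng)
        res = rm.fit_glm(rng.normal(size=(240, 3)), X)
        assert res.rank == 11
        assert res.df == 228

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_lstsq(self, seed):
        rng = np.random.default_rng(seed)
        X = _random_design(rng, n=20, p=5)
        y = rng.normal(size=(20, 3))
        res = rm.fit_glm(y, X, center=False)
        ref, *_ = np.linalg.lstsq(X.values, y, rcond=None)
        assert np.linalg.norm(res.params - ref) <= 1e-8 * np.linalg.norm(ref)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(7)
        X = _random_design(rng)
        y = rng.normal(size=(240, 50))
        res = rm.fit_glm(y, X)
        Xc = X.values - X.values.mean(axis=0)
        assert np.abs(Xc.T @ res.resid).max() < 1e-8

    def test_sigma2_estimates_noise_variance(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = _random_design(rng, n=n, p=5)
        sigma = 1.7
        y = rng.normal(0, sigma, size=(n, 200))
        res = rm.fit_glm(y, X)
        assert res.sigma2.mean() == pytest.approx(sigma**2, rel=0.05)
        assert np.all(res.sigma2 >= 0)

    def test_degenerate_model_raises(self):
        rng = np.random.default_rng(9)
        X = _random_design(rng, n=6, p=5)
        with pytest.raises(Exception):
            rm.fit_glm(rng.normal(size=(6, 2)), X)


class TestContrastTMap:
    def test_zero_contrast_estimate_gives_zero_t(self):
        rng = np.random.default_rng(10)
        X = _random_design(rng)
        y = rng.normal(size=(240, 30))
        res = rm.fit_glm(y, X)
        C = np.zeros(11)
        with pytest.raises(InvalidContrastError):
            res.tmap(C)  # C'GC = 0 is rejected
        # a voxel whose contrast estimate vanishes has t exactly 0
        t = res.tmap().values
        est = res.contrast_estimate()
        assert np.allclose(t[est == 0], 0.0) if np.any(est == 0) else True

    def test_nuisance_rescaling_leaves_t_unchanged(self):
        rng = np.random.default_rng(11)
        X = _random_design(rng)
        y = rng.normal(size=(240, 40)) + 3.0
        t1 = rm.fit_glm(y, X).tmap().values
        scaled = X.values.copy()
        scaled[:, 0] *= 57.0
        X2 = rm.DesignMatrix(scaled, X.column_roles, X.contrast)
        t2 = rm.fit_glm(y, X2).tmap().values
        assert np.allclose(t1, t2, atol=1e-9)

    def test_constant_voxel_flagged_undefined(self):
        rng = np.random.default_rng(12)
        X = _random_design(rng)
        y = rng.normal(size=(240, 5))
        y[:, 2] = 42.0  # constant series: zero residual variance
        res = rm.fit_glm(y, X)
        tm = res.tmap()
        assert tm.undefined[2]
        assert np.isnan(tm.values[2])
        assert not tm.undefined[[0, 1, 3, 4]].any()

    def test_wrong_length_contrast_raises(self):
        rng = np.random.default_rng(13)
        X = _random_design(rng)
        res = rm.fit_glm(rng.normal(size=(240, 2)), X)
        with pytest.raises(InvalidContrastError):
            res.tmap(np.array([1.0, -1.0]))

    def test_summary_mentions_df_and_p(self):
        rng = np.random.default_rng(14)
        X = _random_design(rng)
        res = rm.fit_glm(rng.normal(size=(240, 2)), X)
        text = res.summary()
        assert "228" in text and "11" in text
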