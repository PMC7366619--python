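import numpy as np
import pytest

from phantomech import (
    StressStrainCurve,
    SyntheticSpec,
    estimate_moduli,
    fit_segmented,
    gen_replicate_set,
    r_squared,
)
from phantomech.errors import InsufficientDataError
from tests.conftest import piecewise_linear
from tests.oracles import grid_search_best, piecewise_sse


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_null_model(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # SS_res = 4 * 0.01 = 0.04, SS_tot = 5 -> R^2 = 1 - 0.008 = 0.992
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        fit = np.array([0.1, 0.9, 2.1, 2.9])
        assert r_squared(obs, fit) == pytest.approx(0.992)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.ones(5), np.zeros(5))


class TestFitSegmented:
    def test_noiseless_exact_recovery(self, four_segment_data):
        x, y, psi_true, slopes_true = four_segment_data
        fit = fit_segmented((x, y), seed=1)
        np.testing.assert_allclose(fit.psi, psi_true, rtol=1e-6)
        np.testing.assert_allclose(fit.slopes, slopes_true, rtol=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.converged

    def test_noiseless_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0.0, 0.7, 40))
        x[0], x[-1] = 0.0, 0.7
        y = piecewise_linear(x, [20.0, 150.0, 500.0, 800.0],
                             [0.20, 0.35, 0.60])
        fit = fit_segmented((x, y), seed=0)
        grid_sse, _, _ = grid_search_best(x, y)
        assert fit.sse <= grid_sse + 1e-9

    def test_noiseless_se_near_zero(self, four_segment_data):
        x, y, _, _ = four_segment_data
        fit = fit_segmented((x, y), seed=3)
        assert np.all(fit.psi_se < 1e-6)

    def test_straight_line_degenerate(self):
        x = np.linspace(0.0, 0.7, 100)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_segmented((x, 100.0 * x), seed=0)
        np.testing.assert_allclose(fit.slopes, np.full(4, 100.0), atol=1e-8)
        assert fit.degenerate

    def test_noisy_bilinear_recovery_within_10pct(self, linear_heel_truth):
        spec = SyntheticSpec(kind="bilinear", truth=linear_heel_truth,
                             noise_rel=0.02, noise_abs=0.05, truth_jitter=0.0,
                             n_replicates=1, seed=1)
        rset, _ = gen_replicate_set(spec)
        fit = fit_segmented((rset.curves[0].strain, rset.curves[0].stress),
                            seed=1)
        assert fit.e1 == pytest.approx(20.0, rel=0.10)
        assert fit.e2 == pytest.approx(500.0, rel=0.10)

    def test_nesting_beats_single_line(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.0, 0.7, 80)
        y = piecewise_linear(x, [20.0, 150.0, 500.0, 800.0],
                             [0.20, 0.35, 0.60]) + rng.normal(0, 1.0, 80)
        fit = fit_segmented((x, y), seed=0)
        X1 = np.column_stack([np.ones_like(x), x])
        coef, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
        sse_line = float(np.sum((y - X1 @ coef) ** 2))
        assert fit.sse <= sse_line + 1e-9

    def test_requires_enough_points(self):
        with pytest.raises(InsufficientDataError):
            fit_segmented((np.linspace(0, 0.7, 6), np.ones(6)), seed=0)

    def test_psi0_must_be_inside_data(self, four_segment_data):
        x, y, _, _ = four_segment_data
        with pytest.raises(ValueError, match="span"):
            fit_segmented((x, y), psi0=(0.3, 0.5, 0.9), seed=0)

    def test_psi0_ordering_enforced(self, four_segment_data):
        x, y, _, _ = four_segment_data
        with pytest.raises(ValueError, match="increasing"):
            fit_segmented((x, y), psi0=(0.4, 0.3, 0.6), seed=0)

    def test_accepts_curve_object(self):
        x = np.linspace(0.0, 0.7, 50)
        y = piecewise_linear(x, [20.0, 150.0, 500.0, 800.0],
                             [0.20, 0.35, 0.60])
        curve = StressStrainCurve(strain=x, stress=y, material="M",
                                  dilution_pct=0.0, replicate_id="r1")
        fit = fit_segmented(curve, seed=0)
        assert fit.e1 == pytest.approx(20.0, rel=1e-6)

    def test_se_shrinks_with_point_count(self, linear_heel_truth):
        ses = []
        for n in (60, 400):
            spec = SyntheticSpec(kind="bilinear", truth=linear_heel_truth,
                                 noise_rel=0.02, noise_abs=0.05,
                                 truth_jitter=0.0, n_points=n,
                                 n_replicates=1, seed=11)
            rset, _ = gen_replicate_set(spec)
            c = rset.curves[0]
            ses.append(np.median(
                fit_segmented((c.strain, c.stress), seed=2).psi_se))
        assert ses[1] < ses[0]


class TestEstimateModuli:
    def test_noiseless_all_runs_identical(self, bilinear_spec):
        rset, _ = gen_replicate_set(bilinear_spec)
        est = estimate_moduli(rset, base_seed=0, n_runs=10)
        e1s = [f.e1 for f in est.fits]
        assert len(est.fits) == 10
        assert np.ptp(e1s) == pytest.approx(0.0, abs=1e-9)
        assert est.E1 == pytest.approx(20.0, rel=1e-6)
        assert est.E2 == pytest.approx(500.0, rel=1e-6)

    def test_e1_is_mean_of_run_slopes(self, linear_heel_truth):
        spec = SyntheticSpec(kind="bilinear", truth=linear_heel_truth,
                             noise_rel=0.02, noise_abs=0.05, truth_jitter=0.0,
                             n_replicates=3, seed=4)
        rset, _ = gen_replicate_set(spec)
        est = estimate_moduli(rset, base_seed=100, n_runs=10)
        assert [f.seed for f in est.fits] == list(range(100, 110))
        assert est.E1 == pytest.approx(np.mean([f.e1 for f in est.fits]))
        assert est.E2 == pytest.approx(np.mean([f.e2 for f in est.fits]))

    def test_pooling_before_fit(self, bilinear_spec):
        # pooled estimate uses all replicate points: psi SEs at noiseless
        # determinism must still be ~0 and estimates exact
        rset, _ = gen_replicate_set(bilinear_spec)
        est = estimate_moduli(rset, base_seed=0, n_runs=3)
        assert np.all(est.psi_se < 1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)
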