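import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomech import (
    BlatzFit,
    BlatzParams,
    SyntheticSpec,
    blatz_stress,
    fit_blatz,
    gen_blatz_curve,
    summarize_blatz,
)
from phantomech.errors import SingularParameterError
from tests.oracles import blatz_stress_reference

alphas = st.floats(-20.0, 20.0).filter(lambda a: abs(a + 1.0) > 1e-3)
gammas = st.floats(0.1, 1000.0)


class TestBlatzStress:
    def test_zero_at_unit_stretch(self):
        assert blatz_stress(1.0, BlatzParams(2.09, 12.32)) == 0.0

    def test_alpha_zero_limit(self):
        # sigma -> gamma * (lam - lam^-2): 10 * (0.9 - 1/0.81) = -3.345679...
        val = blatz_stress(0.9, BlatzParams(0.0, 10.0))
        assert val == pytest.approx(10.0 * (0.9 - 1.0 / 0.81), rel=1e-12)

    def test_matches_reference_transcription(self):
        lam = np.linspace(0.3, 1.0, 50)
        for a, g in [(2.09, 12.32), (-14.27, 6.15), (1.05, 144.5)]:
            np.testing.assert_allclose(
                blatz_stress(lam, BlatzParams(a, g)),
                blatz_stress_reference(lam, a, g),
                rtol=1e-12,
            )

    def test_negative_in_compression(self):
        lam = np.linspace(0.4, 0.99, 20)
        assert np.all(blatz_stress(lam, BlatzParams(2.0, 10.0)) < 0)

    def test_alpha_minus_one_singular(self):
        with pytest.raises(SingularParameterError):
            BlatzParams(-1.0, 10.0)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            blatz_stress(0.0, BlatzParams(1.0, 1.0))

    def test_overflow_reported(self):
        with pytest.raises(OverflowError, match="lambda"):
            blatz_stress(1e-3, BlatzParams(49.0, 1.0))

    @given(alpha=alphas, gamma=gammas)
    @settings(max_examples=200)
    def test_identity_at_unit_stretch_property(self, alpha, gamma):
        assert blatz_stress(1.0, BlatzParams(alpha, gamma)) == 0.0

    @given(alpha=alphas, gamma=gammas, c=st.floats(0.1, 10.0),
           lam=st.floats(0.5, 1.0))
    @settings(max_examples=100)
    def test_scale_equivariance_in_gamma(self, alpha, gamma, c, lam):
        a = blatz_stress(lam, BlatzParams(alpha, c * gamma))
        b = c * blatz_stress(lam, BlatzParams(alpha, gamma))
        assert a == pytest.approx(b, rel=1e-10, abs=1e-12)

    @given(alpha=alphas, gamma=gammas)
    @settings(max_examples=100)
    def test_small_strain_tangent_is_3gamma(self, alpha, gamma):
        p = BlatzParams(alpha, gamma)
        h = 1e-6
        tangent = (blatz_stress(1 + h, p) - blatz_stress(1 - h, p)) / (2 * h)
        assert tangent == pytest.approx(3.0 * gamma, rel=1e-5)


def _noiseless_curve(alpha, gamma, seed=0, n_points=200):
    spec = SyntheticSpec(kind="blatz", truth=BlatzParams(alpha, gamma),
                         noise_rel=0.0, noise_abs=0.0, truth_jitter=0.0,
                         n_replicates=1, seed=seed, n_points=n_points)
    return gen_blatz_curve(spec)


class TestFitBlatz:
    @pytest.mark.parametrize("alpha,gamma", [(2.09, 12.32), (1.05, 144.50)])
    def test_noiseless_recovery(self, alpha, gamma):
        fit = fit_blatz(_noiseless_curve(alpha, gamma))
        assert fit.params.alpha == pytest.approx(alpha, rel=1e-4)
        assert fit.params.gamma == pytest.approx(gamma, rel=1e-4)
        assert fit.converged

    def test_alpha_zero_effective_model(self):
        strain = np.linspace(0.0, 0.7, 150)
        lam = 1.0 - strain
        stress = np.abs(10.0 * (lam - lam**-2))
        from phantomech import StressStrainCurve
        curve = StressStrainCurve(strain=strain, stress=stress, material="M",
                                  dilution_pct=0.0, replicate_id="r1")
        fit = fit_blatz(curve)
        assert abs(fit.params.alpha) < 1e-3
        assert fit.params.gamma == pytest.approx(10.0, rel=1e-4)

    def test_all_zero_stress_flat_objective(self):
        from phantomech import StressStrainCurve
        curve = StressStrainCurve(strain=np.linspace(0, 0.5, 20),
                                  stress=np.zeros(20), material="M",
                                  dilution_pct=0.0, replicate_id="r1")
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_blatz(curve)
        assert fit.params.gamma == pytest.approx(0.0, abs=1e-6)

    def test_negative_alpha_recovery(self):
        fit = fit_blatz(_noiseless_curve(-14.27, 6.15))
        assert fit.params.alpha == pytest.approx(-14.27, rel=1e-3)
        assert fit.params.gamma == pytest.approx(6.15, rel=1e-3)

    def test_sse_nonnegative_contract(self):
        with pytest.raises(ValueError):
            BlatzFit(params=BlatzParams(1.0, 1.0), sse=-1.0)


class TestSummarizeBlatz:
    def test_hand_computed_mean_sd(self):
        fits = [BlatzFit(params=BlatzParams(2.0, 10.0), sse=0.0),
                BlatzFit(params=BlatzParams(2.2, 12.0), sse=0.0)]
        s = summarize_blatz(fits)
        assert s.alpha_mean == pytest.approx(2.1)
        assert s.alpha_sd == pytest.approx(np.sqrt(0.02), rel=1e-6)
        assert s.gamma_mean == pytest.approx(11.0)

    def test_single_fit(self):
        s = summarize_blatz([BlatzFit(params=BlatzParams(1.5, 7.0), sse=0.0)])
        assert s.alpha_sd == 0.0
        assert all(v == pytest.approx(1.5) for v in s.alpha_quantiles.values())

    def test_mean_within_min_max(self):
        rng = np.random.default_rng(0)
        fits = [BlatzFit(params=BlatzParams(a, g), sse=0.0)
                for a, g in zip(rng.normal(1.6, 0.2, 9),
                                rng.normal(20, 3, 9))]
        s = summarize_blatz(fits)
        gammas = [f.params.gamma for f in fits]
        assert min(gammas) <= s.gamma_mean <= max(gammas)

    def test_quantiles_nondecreasing(self):
        rng = np.random.default_rng(1)
        fits = [BlatzFit(params=BlatzParams(a, g), sse=0.0)
                for a, g in zip(rng.normal(2, 0.5, 11),
                                rng.normal(15, 4, 11))]
        s = summarize_blatz(fits)
        for qs in (s.alpha_quantiles, s.gamma_quantiles):
            vals = [qs[q] for q in sorted(qs)]
            assert vals == sorted(vals)

    def test_unconverged_excluded(self):
        fits = [BlatzFit(params=BlatzParams(2.0, 10.0), sse=0.0),
                BlatzFit(params=BlatzParams(9.9, 99.0), sse=0.0,
                         converged=False)]
        s = summarize_blatz(fits)
        assert s.n_replicates == 1
        assert s.alpha_mean == pytest.approx(2.0)

    def test_no_converged_fits_rejected(self):
        with pytest.raises(ValueError):
            summarize_blatz([BlatzFit(params=BlatzParams(1, 1), sse=0.0,
                                      converged=False)])
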