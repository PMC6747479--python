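import math

import numpy as np
import pytest

from micellenmr.core_physics import ValidationError
from micellenmr.cpmg_exchange import (
    DispersionCurve,
    ExchangeParams,
    bm_r2eff,
    canonicalize_exchange,
    cr_r2eff,
    detect_exchange,
    exchange_invariants,
    fit_dispersion,
    params_from_invariants,
)
from micellenmr.synthetic_data import CPMG_PRESETS, NoiseSpec, gen_dispersion

TAUS_17 = CPMG_PRESETS["cpmg_tm4_17"]
TAUS_10 = CPMG_PRESETS["cpmg_empty_10"]


def flat_params(r2=5.0):
    return ExchangeParams(p_a=1.0, p_b=0.0, k_ex=0.0, delta_omega=0.0,
                          r2_a=r2, r2_b=r2)


class TestCarverRichards:
    def test_no_minor_state_gives_intrinsic_rate(self, micelle_exchange):
        p = ExchangeParams(1.0, 0.0, micelle_exchange.k_ex,
                           micelle_exchange.delta_omega, 31.25, 5.26)
        for tau in (5e-5, 5e-4, 2e-3):
            assert cr_r2eff(p, tau) == pytest.approx(31.25)

    def test_identical_states_give_common_rate(self):
        p = ExchangeParams(0.9, 0.1, 500.0, 0.0, 12.0, 12.0)
        assert cr_r2eff(p, 1e-3) == pytest.approx(12.0)

    def test_dispersion_shape_flattens_under_fast_pulsing(self,
                                                          micelle_exchange):
        """R2eff rises with pulse spacing, up to the small coherent
        oscillations (cos eta- term) that slow exchange superimposes on
        the plateau; the Bloch-McConnell propagation shows the same
        ripple, so only dips beyond a few percent of the dispersion
        amplitude would indicate an error."""
        taus = np.sort(np.unique(TAUS_17))
        r2 = cr_r2eff(micelle_exchange, taus)
        amplitude = r2.max() - r2.min()
        assert np.all(np.diff(r2) >= -0.03 * amplitude)
        assert r2[-1] > r2[0] + 0.8 * amplitude
        # fast-pulsing end approaches the population-weighted average
        weighted = 0.972 * 31.25 + 0.028 * 5.26
        assert r2[0] == pytest.approx(weighted, rel=0.01)

    def test_overflow_safe_at_extreme_arguments(self):
        p = ExchangeParams.from_minor(0.05, 100.0, 1e5, 50.0, 5.0)
        val = cr_r2eff(p, 0.5)  # eta ~ 1e4: cosh overflows if naive
        assert np.isfinite(val)
        assert val > 0

    def test_invalid_tau_rejected(self, micelle_exchange):
        with pytest.raises(ValidationError):
            cr_r2eff(micelle_exchange, 0.0)


class TestBlochMcConnell:
    def test_single_site_limit_exact(self):
        p = ExchangeParams(1.0, 0.0, 0.0, 5.2e3, 31.25, 5.26)
        assert bm_r2eff(p, 1e-3) == pytest.approx(31.25, rel=1e-9)

    def test_fast_pulsing_reaches_weighted_average(self, micelle_exchange):
        weighted = 0.972 * 31.25 + 0.028 * 5.26
        assert bm_r2eff(micelle_exchange, 2e-5) == pytest.approx(weighted,
                                                                 rel=0.01)

    def test_oracle_equivalence_on_slow_exchange_grid(self):
        """Closed form matches the propagated pulse sequence within 2%
        across the minor-population <= 0.05 regime at all 17 delays."""
        for p_b in (0.01, 0.028, 0.05):
            for k_ex in (100.0, 253.0, 1000.0):
                for dw in (2e3, 5.2e3):
                    p = ExchangeParams.from_minor(p_b, k_ex, dw, 31.25, 5.26)
                    for tau in np.unique(TAUS_17):
                        cr = cr_r2eff(p, tau)
                        bm = bm_r2eff(p, tau, transient_free=True)
                        assert cr == pytest.approx(bm, rel=0.02), \
                            (p_b, k_ex, dw, tau)

    def test_total_time_validation(self, micelle_exchange):
        with pytest.raises(ValidationError):
            bm_r2eff(micelle_exchange, 1e-3, total_time=1e-4)


class TestInvariants:
    def test_manifold_points_share_the_curve(self, micelle_exchange):
        """Any parameter set sharing the four invariants produces a
        bit-identical dispersion curve (exact non-identifiability)."""
        u1, u2, u3, dw = exchange_invariants(micelle_exchange)
        alt = params_from_invariants(u1, -u2, u3, dw, p_b=0.15)
        assert alt.k_ex != pytest.approx(micelle_exchange.k_ex, rel=0.2)
        np.testing.assert_allclose(cr_r2eff(alt, TAUS_17),
                                   cr_r2eff(micelle_exchange, TAUS_17),
                                   rtol=1e-10)

    def test_params_from_invariants_round_trip(self, micelle_exchange):
        u1, u2, u3, dw = exchange_invariants(micelle_exchange)
        back = params_from_invariants(u1, -u2, u3, dw,
                                      p_b=micelle_exchange.p_b)
        assert back.k_ex == pytest.approx(micelle_exchange.k_ex, rel=1e-12)
        assert back.r2_a == pytest.approx(micelle_exchange.r2_a, rel=1e-12)
        assert back.r2_b == pytest.approx(micelle_exchange.r2_b, rel=1e-9)

    def test_canonical_representative_is_deterministic(self,
                                                       micelle_exchange):
        canon = canonicalize_exchange(micelle_exchange)
        # smallest feasible minor population: R2b parked at the box floor
        assert canon.p_b <= micelle_exchange.p_b
        assert canon.r2_b == pytest.approx(0.1, abs=1e-6)
        np.testing.assert_allclose(cr_r2eff(canon, TAUS_17),
                                   cr_r2eff(micelle_exchange, TAUS_17),
                                   rtol=1e-10)
        again = canonicalize_exchange(canon)
        assert again.p_b == pytest.approx(canon.p_b, rel=1e-9)


class TestFitDispersion:
    def test_noiseless_fit_recovers_invariants_exactly(self,
                                                       micelle_exchange):
        """The curve determines the invariants; a noiseless fit recovers
        them to high precision and reproduces the curve."""
        curve, _ = gen_dispersion(micelle_exchange, noise=NoiseSpec(0.0))
        fit = fit_dispersion(curve, n_starts=16, seed=3)
        u_true = exchange_invariants(micelle_exchange)
        u_fit = exchange_invariants(fit.params)
        for a, b in zip(u_fit, u_true):
            assert a == pytest.approx(b, rel=1e-4)
        np.testing.assert_allclose(cr_r2eff(fit.params, curve.tau_cp),
                                   curve.r2_eff, rtol=1e-6)
        assert fit.converged

    def test_canonical_report_near_generating_regime(self, micelle_exchange):
        curve, _ = gen_dispersion(micelle_exchange, noise=NoiseSpec(0.0))
        fit = fit_dispersion(curve, n_starts=16, seed=3)
        # the parsimony representative of the true manifold
        assert fit.params.p_b == pytest.approx(0.0269, abs=0.001)
        assert fit.params.k_ex == pytest.approx(258.0, rel=0.02)
        assert fit.params.delta_omega == pytest.approx(5200.0, rel=0.001)
        assert fit.params.r2_a == pytest.approx(31.4, abs=0.2)

    def test_flat_curve_flagged_unidentifiable(self):
        rng = np.random.default_rng(5)
        y = 5.0 + rng.normal(0, 0.3, size=TAUS_10.shape)
        curve = DispersionCurve(TAUS_10, y)
        fit = fit_dispersion(curve, n_starts=8, seed=5)
        assert not fit.converged or fit.at_bounds

    def test_replicate_delays_kept_as_rows(self, micelle_exchange):
        curve, _ = gen_dispersion(micelle_exchange,
                                  noise=NoiseSpec(0.3, seed=9))
        assert len(curve.tau_cp) == 17
        assert np.unique(curve.tau_cp).size == 14
        # replicate rows carry independent noise
        for tau in (2e-4, 9e-4, 1.1e-3):
            vals = curve.r2_eff[curve.tau_cp == tau]
            assert len(vals) == 2 and vals[0] != vals[1]

    def test_too_few_distinct_delays_rejected(self, micelle_exchange):
        taus = np.array([1e-4, 2e-4, 3e-4, 4e-4, 5e-4, 6e-4, 7e-4])
        curve = DispersionCurve(taus, np.full(7, 10.0))
        with pytest.raises(ValidationError):
            fit_dispersion(curve)


class TestDetectExchange:
    def test_zero_noise_flat_curve_not_detected(self):
        curve, _ = gen_dispersion(flat_params(), tau_cp_preset="cpmg_empty_10",
                                  noise=NoiseSpec(0.0))
        present, stat, p = detect_exchange(curve, alpha=0.05, n_starts=4,
                                           seed=0)
        assert not present
        assert p == pytest.approx(1.0)

    def test_noisy_flat_curves_rarely_detected(self):
        hits = 0
        for seed in range(40):
            curve, _ = gen_dispersion(flat_params(),
                                      tau_cp_preset="cpmg_empty_10",
                                      noise=NoiseSpec(0.3, seed=seed))
            present, _, _ = detect_exchange(curve, alpha=0.05, n_starts=6,
                                            seed=seed)
            hits += present
        assert hits <= 4  # ~<=1.5 alpha on a small screen; full rate tested
        # in the acceptance suite

    def test_exchange_curve_detected(self, micelle_exchange):
        for seed in (1, 2, 3, 4, 5):
            curve, _ = gen_dispersion(micelle_exchange,
                                      noise=NoiseSpec(0.3, seed=seed))
            present, stat, p = detect_exchange(curve, alpha=0.05,
                                               n_starts=6, seed=seed)
            assert present and p < 0.01
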