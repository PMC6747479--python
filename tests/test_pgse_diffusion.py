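import math

import numpy as np
import pytest

from micellenmr.core_physics import (
    FitFailureError,
    SolventSpec,
    ValidationError,
    get_nucleus,
)
from micellenmr.pgse_diffusion import (
    EchoSeries,
    fit_st,
    invert_polydispersity,
    rh_to_dtr,
    st_bfactor,
    st_signal,
    stokes_einstein_rh,
)
from micellenmr.synthetic_data import NoiseSpec, gen_echo_series


def make_series(i0=100.0, d=8e-11, nucleus="1H", delta=0.002,
                big_delta=0.040, n=25, gmax=0.6):
    g = np.linspace(0.01, gmax, n)
    amps = st_signal(i0, d, nucleus, delta, big_delta, g)
    return EchoSeries(get_nucleus(nucleus), delta, big_delta, g, amps)


class TestForwardModel:
    def test_zero_gradient_gives_i0(self):
        assert st_signal(7.5, 1e-10, "1H", 0.002, 0.040, 0.0) == 7.5

    def test_zero_diffusion_gives_i0(self):
        assert st_signal(7.5, 0.0, "1H", 0.002, 0.040, 0.5) == 7.5

    def test_against_independent_scalar_evaluation(self):
        # b = (G*gamma*delta)^2 * (Delta - delta/3) evaluated by hand:
        # G=0.1 T/m, gamma(1H)=2.6752218744e8, delta=2 ms, Delta=40 ms
        gamma = 2.6752218744e8
        b = (0.1 * gamma * 0.002) ** 2 * (0.040 - 0.002 / 3.0)
        expected = math.exp(-1e-10 * b)
        got = st_signal(1.0, 1e-10, "1H", 0.002, 0.040, 0.1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert st_bfactor("1H", 0.002, 0.040, 0.1) == pytest.approx(b)

    def test_strictly_decreasing_in_gradient(self):
        g = np.linspace(0.0, 0.6, 50)
        y = st_signal(1.0, 8e-11, "1H", 0.002, 0.040, g)
        assert np.all(np.diff(y) < 0)

    def test_log_linear_in_bfactor(self):
        s = make_series()
        slope, _ = np.polyfit(s.bfactors(), np.log(s.amplitudes), 1)
        assert slope == pytest.approx(-8e-11, rel=1e-10)


class TestFit:
    def test_noiseless_exact_recovery(self):
        s = make_series(i0=42.0, d=3.3e-10)
        fit = fit_st(s)
        assert fit.d_tr == pytest.approx(3.3e-10, rel=1e-8)
        assert fit.i0 == pytest.approx(42.0, rel=1e-8)

    def test_linearized_and_nonlinear_agree_on_noiseless_data(self):
        s = make_series(i0=10.0, d=1.2e-10)
        slope, _ = np.polyfit(s.bfactors(), np.log(s.amplitudes), 1)
        fit = fit_st(s)
        assert fit.d_tr == pytest.approx(-slope, rel=1e-6)

    def test_constant_series_fails(self):
        g = np.linspace(0.01, 0.6, 10)
        s = EchoSeries(get_nucleus("1H"), 0.002, 0.040, g, np.full(10, 5.0))
        with pytest.raises(FitFailureError):
            fit_st(s)

    def test_noisy_recovery_median_within_one_percent(self):
        # 1% amplitude noise, 25 gradient steps, many seeds
        ds = []
        for seed in range(100):
            series, _ = gen_echo_series(i0=100.0, d=8e-11,
                                        noise=NoiseSpec(1.0, seed=seed))
            ds.append(fit_st(series).d_tr)
        assert np.median(ds) == pytest.approx(8e-11, rel=0.01)

    def test_series_validation(self):
        g = np.linspace(0.01, 0.6, 3)
        with pytest.raises(ValidationError):
            EchoSeries(get_nucleus("1H"), 0.002, 0.040, g, np.ones(3))
        with pytest.raises(ValidationError):
            EchoSeries(get_nucleus("1H"), 0.05, 0.040,
                       np.linspace(0.01, 0.6, 10), np.ones(10))


class TestPolydispersity:
    def test_monodisperse_mode_within_one_grid_step(self):
        s = make_series(d=8e-11)
        dist = invert_polydispersity(s, grid_size=64)
        step = np.log10(dist.grid[1] / dist.grid[0])
        assert abs(np.log10(dist.mode() / 8e-11)) <= step + 1e-12
        assert np.all(dist.weights >= 0)

    def test_two_component_mixture_resolved(self):
        # gradients strong enough that the slow component attenuates
        # substantially too (b*d1 reaches ~2)
        g = np.linspace(0.01, 3.0, 50)
        d1, d2 = 2e-11, 2e-10
        amps = 0.5 * st_signal(100.0, d1, "1H", 0.002, 0.040, g) \
            + 0.5 * st_signal(100.0, d2, "1H", 0.002, 0.040, g)
        rng = np.random.default_rng(7)
        amps = amps + rng.normal(0, 0.5, size=g.shape)
        s = EchoSeries(get_nucleus("1H"), 0.002, 0.040, g, amps)
        dist = invert_polydispersity(s, grid_size=64)
        w, grid = dist.weights, dist.grid
        # local maxima of the weight vector
        peaks = [grid[i] for i in range(1, len(w) - 1)
                 if w[i] > w[i - 1] and w[i] >= w[i + 1] and w[i] > 0.05 * w.max()]
        assert any(abs(p / d1 - 1) < 0.35 for p in peaks)
        assert any(abs(p / d2 - 1) < 0.35 for p in peaks)

    def test_infinite_regularization_flattens_weights(self):
        s = make_series(d=8e-11)
        dist = invert_polydispersity(s, grid_size=32, regularization=1e9)
        w = dist.weights
        assert w.max() > 0
        assert np.ptp(w) <= 1e-3 * w.max()

    def test_forward_reconstruction_within_noise(self):
        series, _ = gen_echo_series(i0=100.0, d=8e-11,
                                    noise=NoiseSpec(0.5, seed=3))
        dist = invert_polydispersity(series, grid_size=64)
        K = np.exp(-np.outer(series.bfactors(), dist.grid))
        resid = K @ dist.weights - series.amplitudes
        assert np.sqrt(np.mean(resid ** 2)) < 3 * 0.5


class TestStokesEinstein:
    def test_micelle_scale_radius(self):
        solvent = SolventSpec(temperature=303.0, viscosity=0.797e-3)
        res = stokes_einstein_rh(8.2e-11, solvent)
        assert res.r_h * 1e10 == pytest.approx(34.0, abs=0.5)

    def test_inverse_proportionality_in_d(self, water_303k):
        r1 = stokes_einstein_rh(8e-11, water_303k).r_h
        r2 = stokes_einstein_rh(1.6e-10, water_303k).r_h
        assert r1 == pytest.approx(2 * r2, rel=1e-12)

    def test_round_trip_exact(self, water_303k):
        r = stokes_einstein_rh(8e-11, water_303k)
        assert rh_to_dtr(r.r_h, water_303k) == pytest.approx(8e-11,
                                                             rel=1e-12)
        # invariant r_h * d_tr == kB T / (6 pi eta)
        from micellenmr.core_physics import KB, solvent_viscosity
        lhs = r.r_h * r.d_tr
        rhs = KB * 303.0 / (6 * math.pi * solvent_viscosity(water_303k))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_depends_on_temperature_only_through_t_over_eta(self):
        a = SolventSpec(temperature=293.15, viscosity=1.0e-3)
        # doubled T at doubled eta: T/eta unchanged -> same radius
        b = SolventSpec(temperature=586.30, viscosity=2.0e-3)
        assert stokes_einstein_rh(8e-11, a).r_h == pytest.approx(
            stokes_einstein_rh(8e-11, b).r_h, rel=1e-12)

    def test_nonpositive_d_rejected(self, water_303k):
        with pytest.raises(ValidationError):
            stokes_einstein_rh(0.0, water_303k)
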