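"""Synthetic experimental series with known ground truth.

Every input the analysis chain consumes can be generated here: PGSE echo
attenuations (Stejskal-Tanner forward model), relaxation decays and
inversion recoveries, and CPMG dispersion curves (Carver-Richards closed
form or Bloch-McConnell propagation), each with additive Gaussian noise.

Acquisition schedules are shipped as named presets matching the
experiments this package models: the 25-step proton PGSE ramp, the 15N R1
(10-point) and R2 (8-point) evolution-time sets, the 31P inversion-recovery
(10-point) and decay (9-point) sets, and the two CPMG delay lists (17
delays with peptide, including the replicated 0.2/0.9/1.1 ms points, and
10 delays for the empty micelle).

Reproducibility: each generator derives an independent substream from
(generator name, seed) via ``numpy.random.SeedSequence``, so identical
seeds give bit-identical series and the three generators never share a
noise stream.  Ground-truth parameters and the seed ride along in the
returned provenance dict.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core_physics import RegistryError, ValidationError, get_nucleus
from .cpmg_exchange import DispersionCurve, ExchangeParams, bm_r2eff, cr_r2eff
from .pgse_diffusion import DEFAULT_BIG_DELTA, EchoSeries, st_signal
from .relaxation_fit import DecaySeries

__all__ = [
    "NoiseSpec",
    "DECAY_PRESETS",
    "CPMG_PRESETS",
    "GRADIENT_PRESETS",
    "gen_echo_series",
    "gen_decay",
    "gen_dispersion",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation (series units) + seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


def _rng(stream: str, seed: int) -> np.random.Generator:
    # independent substream per generator: hash the stream name into the
    # spawn key so equal seeds never share noise across generators
    tag = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([tag, seed]))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: evolution-time schedules (s) per experiment
DECAY_PRESETS = {
    # 15N longitudinal, ten evolution times
    "r1_15n_10pt": np.array([0.010, 0.090, 0.170, 0.290, 0.410, 0.550,
                             0.690, 0.850, 1.010, 1.250]),
    # 15N transverse (CPMG train), eight points
    "r2_15n_8pt": np.array([0.010, 0.030, 0.050, 0.070, 0.090, 0.130,
                            0.170, 0.210]),
    # 31P inversion recovery, ten points
    "r1_31p_10pt": np.array([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0,
                             8.0, 16.0, 32.0]),
    # 31P spin-echo decay, nine points
    "r2_31p_9pt": np.array([0.00125, 0.0025, 0.005, 0.010, 0.020, 0.040,
                            0.080, 0.160, 0.320]),
}

#: CPMG pi-pi spacings (s); replicated delays appear as separate entries
CPMG_PRESETS = {
    "cpmg_tm4_17": np.array([50e-6, 60e-6, 70e-6, 80e-6, 1e-4,
                             2e-4, 2e-4, 5e-4, 9e-4, 9e-4,
                             1.1e-3, 1.1e-3, 1.2e-3, 1.3e-3, 1.4e-3,
                             1.5e-3, 2e-3]),
    "cpmg_empty_10": np.array([50e-6, 80e-6, 1e-4, 3e-4, 5e-4,
                               9e-4, 1.0e-3, 1.4e-3, 1.5e-3, 2e-3]),
}

#: gradient ramps (T/m); the proton ramp is 25 steps up to 60 G/cm, the
#: micelle (X-nucleus) ramp spans the high-gradient probe range
GRADIENT_PRESETS = {
    "proton_25": np.linspace(0.024, 0.60, 25),
    "xnucleus_25": np.linspace(0.09, 8.26, 25),
}


def _preset(table: dict, name: str) -> np.ndarray:
    try:
        return table[name].copy()
    except KeyError:
        raise RegistryError(
            f"unknown preset {name!r}; available: {sorted(table)}"
        ) from None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_echo_series(
    i0: float,
    d: float,
    nucleus: str = "1H",
    delta: float = 0.002,
    big_delta: float | None = None,
    gradients=None,
    gradient_preset: str = "proton_25",
    noise: NoiseSpec = NoiseSpec(0.0),
) -> tuple[EchoSeries, dict]:
    """Synthetic PGSE attenuation series.

    ``big_delta`` defaults to the conventional diffusion time for the
    nucleus (40 ms 1H, 60 ms 31P, 200 ms 2H).  Returns the series plus a
    provenance dict embedding the ground truth and seed.
    """
    nuc = get_nucleus(nucleus)
    if big_delta is None:
        big_delta = DEFAULT_BIG_DELTA[nuc.name]
    g = (np.asarray(gradients, dtype=float) if gradients is not None
         else _preset(GRADIENT_PRESETS, gradient_preset))
    clean = st_signal(i0, d, nuc, delta, big_delta, g)
    rng = _rng("echo", noise.seed)
    amplitudes = clean + rng.normal(0.0, noise.sigma, size=g.shape) \
        if noise.sigma > 0 else clean
    series = EchoSeries(nuc, delta, big_delta, g, amplitudes)
    provenance = {
        "generator": "gen_echo_series", "truth": {"i0": i0, "d": d},
        "nucleus": nuc.name, "delta": delta, "big_delta": big_delta,
        "sigma": noise.sigma, "seed": noise.seed,
    }
    return series, provenance


def gen_decay(
    kind: str,
    rate: float,
    schedule_preset: str = "r1_15n_10pt",
    i0: float = 100.0,
    inversion_amplitude: float = 2.0,
    noise: NoiseSpec = NoiseSpec(0.0),
) -> tuple[DecaySeries, dict]:
    """Synthetic relaxation series at a named evolution-time schedule.

    ``kind`` selects the forward model: ``decay``/``cpmg_decay`` give
    I0 exp(-R t); ``inversion_recovery`` gives
    I0 (1 - A exp(-R t)) with A = ``inversion_amplitude``.
    """
    times = _preset(DECAY_PRESETS, schedule_preset)
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    if kind == "inversion_recovery":
        clean = i0 * (1.0 - inversion_amplitude * np.exp(-rate * times))
    elif kind in ("decay", "cpmg_decay"):
        clean = i0 * np.exp(-rate * times)
    else:
        raise ValidationError(f"unknown series kind {kind!r}")
    rng = _rng("decay", noise.seed)
    amplitudes = clean + rng.normal(0.0, noise.sigma, size=times.shape) \
        if noise.sigma > 0 else clean
    series = DecaySeries(kind=kind, times=times, amplitudes=amplitudes)
    provenance = {
        "generator": "gen_decay", "truth": {"rate": rate, "i0": i0},
        "kind": kind, "schedule": schedule_preset,
        "sigma": noise.sigma, "seed": noise.seed,
    }
    if kind == "inversion_recovery":
        provenance["truth"]["inversion_amplitude"] = inversion_amplitude
    return series, provenance


def gen_dispersion(
    params: ExchangeParams,
    tau_cp_preset: str = "cpmg_tm4_17",
    noise: NoiseSpec = NoiseSpec(0.0),
    generator: str = "cr",
    total_time: float = 0.04,
) -> tuple[DispersionCurve, dict]:
    """Synthetic CPMG dispersion curve at a named delay preset.

    ``generator`` picks the forward model: ``"cr"`` (Carver-Richards
    closed form) or ``"bm"`` (Bloch-McConnell propagation over
    ``total_time``).  Replicated delays in the preset become independent
    noisy observations.
    """
    taus = _preset(CPMG_PRESETS, tau_cp_preset)
    if generator == "cr":
        clean = cr_r2eff(params, taus)
    elif generator == "bm":
        clean = np.array([bm_r2eff(params, t, total_time=total_time)
                          for t in taus])
    else:
        raise ValidationError("generator must be 'cr' or 'bm'")
    rng = _rng("dispersion", noise.seed)
    r2 = clean + rng.normal(0.0, noise.sigma, size=taus.shape) \
        if noise.sigma > 0 else clean
    if np.any(r2 <= 0):
        raise ValidationError("noise drove r2_eff non-positive; reduce "
                              "sigma")
    curve = DispersionCurve(tau_cp=taus, r2_eff=r2)
    provenance = {
        "generator": "gen_dispersion",
        "truth": {
            "p_a": params.p_a, "p_b": params.p_b, "k_ex": params.k_ex,
            "delta_omega": params.delta_omega, "r2_a": params.r2_a,
            "r2_b": params.r2_b,
        },
        "forward_model": generator, "preset": tau_cp_preset,
        "sigma": noise.sigma, "seed": noise.seed,
    }
    return curve, provenance
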