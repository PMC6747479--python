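"""Rotational correlation time from 15N R2/R1 under isotropic rotation.

For a rigid, isotropically tumbling molecule the amide 15N relaxation
rates are governed by the N-H dipolar interaction and the 15N chemical
shift anisotropy through the Lorentzian spectral density

    J(w) = (2/5) * tau_c / (1 + w^2 tau_c^2).

The standard expressions (no internal motion, no exchange) are

    R1 = (d^2/4) [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)
    R2 = (d^2/8) [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
         + (c^2/6) [4 J(0) + 3 J(wN)]

with d = mu0 hbar gammaH gammaN / (4 pi rNH^3) and c = dSigma * wN / sqrt(3).

Two estimators invert the measured R2/R1 ratio to tau_c:

* the classic closed form tau_c = sqrt(6 R2/R1 - 7) / (4 pi nuN), obtained
  by keeping only the J(0) and J(wN) terms (valid outside extreme
  narrowing, R2/R1 > 7/6);
* an exact numerical inversion of the full forward model by bracketed root
  finding, used to cross-check the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_physics import (
    HBAR,
    MU0,
    FieldSpec,
    FitFailureError,
    ValidationError,
    get_nucleus,
    larmor_frequency,
)
from .relaxation_fit import RateResult

__all__ = [
    "ModelFreeConstants",
    "TauCResult",
    "spectral_density",
    "forward_r1_r2",
    "tauc_from_ratio",
    "tauc_exact",
]


@dataclass(frozen=True)
class ModelFreeConstants:
    """Interaction constants of the amide 15N relaxation model.

    Defaults are the conventional backbone-amide values: N-H bond length
    1.02 Angstrom and an axially symmetric 15N CSA of -160 ppm.
    """

    r_nh: float = 1.02e-10        # m
    delta_sigma: float = -160.0   # ppm

    def __post_init__(self) -> None:
        if not 0.9e-10 < self.r_nh < 1.1e-10:
            raise ValidationError("r_nh outside the physical 0.9-1.1 A range")
        if not -200.0 < self.delta_sigma < -100.0:
            raise ValidationError("delta_sigma outside -200..-100 ppm")


@dataclass(frozen=True)
class TauCResult:
    """Rotational correlation time with propagated uncertainty."""

    tau_c: float          # s
    uncertainty: float    # s
    method: str           # "ratio_approximation" | "exact_inversion"

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValidationError("tau_c must be > 0")


def spectral_density(omega, tau_c: float):
    """Isotropic rigid-rotor Lorentzian J(w) = (2/5) tau_c / (1 + w^2 tau_c^2)."""
    if tau_c <= 0:
        raise ValidationError("tau_c must be > 0")
    omega = np.asarray(omega, dtype=float)
    out = 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)
    return float(out) if out.ndim == 0 else out


def _rates(rate_or_result) -> tuple[float, float]:
    if isinstance(rate_or_result, RateResult):
        return rate_or_result.rate, rate_or_result.uncertainty
    return float(rate_or_result), 0.0


def forward_r1_r2(
    tau_c: float,
    field: FieldSpec,
    constants: ModelFreeConstants = ModelFreeConstants(),
) -> tuple[float, float]:
    """15N (R1, R2) in s^-1 for a rigid isotropic rotor at ``field``."""
    if tau_c <= 0:
        raise ValidationError("tau_c must be > 0")
    nh = get_nucleus("1H")
    nn = get_nucleus("15N")
    w_h = 2.0 * math.pi * larmor_frequency(nh, field)
    w_n = 2.0 * math.pi * larmor_frequency(nn, field)
    d = MU0 * HBAR * abs(nh.gamma) * abs(nn.gamma) / (
        4.0 * math.pi * constants.r_nh ** 3)
    c = abs(constants.delta_sigma) * 1e-6 * w_n / math.sqrt(3.0)

    def j(w):
        return spectral_density(w, tau_c)

    r1 = (d * d / 4.0) * (j(w_h - w_n) + 3.0 * j(w_n) + 6.0 * j(w_h + w_n)) \
        + c * c * j(w_n)
    r2 = (d * d / 8.0) * (4.0 * j(0.0) + j(w_h - w_n) + 3.0 * j(w_n)
                          + 6.0 * j(w_h) + 6.0 * j(w_h + w_n)) \
        + (c * c / 6.0) * (4.0 * j(0.0) + 3.0 * j(w_n))
    return r1, r2


def tauc_from_ratio(
    r1: RateResult | float,
    r2: RateResult | float,
    field: FieldSpec,
) -> TauCResult:
    """Closed-form tau_c = sqrt(6 R2/R1 - 7) / (4 pi nuN).

    Derived by keeping only the J(0) and J(wN) spectral-density terms, so
    that R2/R1 = (7 + 4 wN^2 tau_c^2) / 6.  Valid for R2/R1 > 7/6; below
    that (extreme narrowing) there is no real solution and a
    ValidationError is raised.

    Uncertainty is first-order propagation from the rate uncertainties,
    treating R1 and R2 as independent.
    """
    r1_val, r1_err = _rates(r1)
    r2_val, r2_err = _rates(r2)
    if r1_val <= 0 or r2_val <= 0:
        raise ValidationError("rates must be > 0")
    rho = r2_val / r1_val
    if rho <= 7.0 / 6.0:
        raise ValidationError(
            f"R2/R1 = {rho:.4f} <= 7/6: extreme-narrowing regime, no real "
            "tau_c solution"
        )
    nu_n = larmor_frequency("15N", field)
    tau_c = math.sqrt(6.0 * rho - 7.0) / (4.0 * math.pi * nu_n)
    sigma_rho = rho * math.hypot(r1_err / r1_val, r2_err / r2_val)
    # d tau/d rho = 3 / (4 pi nuN sqrt(6 rho - 7))
    sigma_tau = 3.0 * sigma_rho / (
        4.0 * math.pi * nu_n * math.sqrt(6.0 * rho - 7.0))
    return TauCResult(tau_c=tau_c, uncertainty=sigma_tau,
                      method="ratio_approximation")


def tauc_exact(
    r1: RateResult | float,
    r2: RateResult | float,
    field: FieldSpec,
    constants: ModelFreeConstants = ModelFreeConstants(),
    bracket: tuple[float, float] = (0.1e-9, 100e-9),
) -> TauCResult:
    """tau_c by numerical inversion of the full forward R2/R1 ratio.

    Brackets the root on ``bracket`` (default 0.1-100 ns).  The uncertainty
    is propagated through the numerical derivative of the ratio with
    respect to tau_c.
    """
    r1_val, r1_err = _rates(r1)
    r2_val, r2_err = _rates(r2)
    if r1_val <= 0 or r2_val <= 0:
        raise ValidationError("rates must be > 0")
    rho = r2_val / r1_val

    def f(tc):
        fr1, fr2 = forward_r1_r2(tc, field, constants)
        return fr2 / fr1 - rho

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise FitFailureError(
            f"R2/R1 = {rho:.4f} not bracketed by tau_c in "
            f"[{lo*1e9:.3g}, {hi*1e9:.3g}] ns"
        )
    tau_c = brentq(f, lo, hi, xtol=1e-15, rtol=1e-12)
    sigma_rho = rho * math.hypot(r1_err / r1_val, r2_err / r2_val)
    h = tau_c * 1e-6
    dratio = (f(tau_c + h) - f(tau_c - h)) / (2.0 * h)
    sigma_tau = abs(sigma_rho / dratio) if dratio != 0 else 0.0
    return TauCResult(tau_c=float(tau_c), uncertainty=float(sigma_tau),
                      method="exact_inversion")
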