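"""PGSE diffusion: Stejskal-Tanner forward model, fitting, polydispersity
inversion and Stokes-Einstein hydrodynamic radii.

A pulsed-field-gradient spin-echo experiment attenuates the echo of a
species diffusing with coefficient D as

    I(G) = I0 * exp(-D * (G * gamma * delta)**2 * (Delta - delta/3))

with G the gradient strength, gamma the gyromagnetic ratio of the observed
nucleus, delta the gradient-pulse duration and Delta the diffusion time.
The b-factor b(G) = (G*gamma*delta)**2 * (Delta - delta/3) collects the
geometry.  Fitting I(G) yields D; Stokes-Einstein converts D to the radius
of the hydrodynamically equivalent sphere, Rh = kB*T / (6*pi*eta*D).

For samples that may contain several diffusing species the single-exponential
fit is complemented by a regularized inverse-Laplace inversion onto a log
grid of diffusion coefficients (non-negative least squares with a
first-difference smoothness penalty), in the spirit of the classic CONTIN
analysis of polydisperse attenuation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls

from .core_physics import (
    KB,
    FitFailureError,
    NucleusSpec,
    SolventSpec,
    ValidationError,
    get_nucleus,
    solvent_viscosity,
)

__all__ = [
    "EchoSeries",
    "DiffusionFit",
    "DiffusionDistribution",
    "HydrodynamicResult",
    "DEFAULT_BIG_DELTA",
    "st_bfactor",
    "st_signal",
    "fit_st",
    "invert_polydispersity",
    "stokes_einstein_rh",
    "rh_to_dtr",
]

#: conventional diffusion times Delta per observed nucleus (s); these are
#: presets for the synthetic generator, never silently assumed by readers.
DEFAULT_BIG_DELTA = {"1H": 0.040, "31P": 0.060, "2H": 0.200}

GAUSS_PER_CM_TO_T_PER_M = 1e-2  # 1 G/cm = 0.01 T/m


@dataclass(frozen=True)
class EchoSeries:
    """One PGSE attenuation series.

    gradients are in T/m, strictly increasing and non-negative; use
    ``EchoSeries.from_gauss_per_cm`` for tables recorded in G/cm.
    """

    nucleus: NucleusSpec
    delta: float        # gradient pulse duration, s
    big_delta: float    # diffusion time, s
    gradients: np.ndarray   # T/m
    amplitudes: np.ndarray  # arbitrary
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "gradients", g)
        object.__setattr__(self, "amplitudes", a)
        if self.errors is not None:
            e = np.asarray(self.errors, dtype=float)
            if e.shape != a.shape or np.any(e <= 0):
                raise ValidationError("errors must be positive, same length "
                                      "as amplitudes")
            object.__setattr__(self, "errors", e)
        if g.ndim != 1 or g.shape != a.shape:
            raise ValidationError("gradients and amplitudes must be 1-D and "
                                  "equal length")
        if g.size < 4:
            raise ValidationError("need at least 4 gradient points")
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValidationError("gradients must be non-negative and "
                                  "strictly increasing")
        if not (0 < self.delta < self.big_delta):
            raise ValidationError("need 0 < delta < big_delta")

    @classmethod
    def from_gauss_per_cm(cls, nucleus, delta, big_delta, gradients_gcm,
                          amplitudes, errors=None) -> "EchoSeries":
        g = np.asarray(gradients_gcm, dtype=float) * GAUSS_PER_CM_TO_T_PER_M
        return cls(nucleus, delta, big_delta, g, amplitudes, errors)

    def bfactors(self) -> np.ndarray:
        return st_bfactor(self.nucleus, self.delta, self.big_delta,
                          self.gradients)


@dataclass(frozen=True)
class DiffusionFit:
    """Two-parameter (I0, D) Stejskal-Tanner fit result."""

    d_tr: float                 # m^2/s
    i0: float
    d_tr_err: float
    i0_err: float
    covariance: np.ndarray      # 2x2, order (i0, d_tr)
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.d_tr <= 0 or self.i0 <= 0:
            raise ValidationError("d_tr and i0 must be > 0")


@dataclass(frozen=True)
class DiffusionDistribution:
    """Regularized diffusion-coefficient distribution from one series."""

    grid: np.ndarray            # m^2/s, log-spaced
    weights: np.ndarray         # >= 0
    regularization: float
    residual_norm: float

    def mode(self) -> float:
        """Grid point with the largest weight."""
        return float(self.grid[int(np.argmax(self.weights))])


@dataclass(frozen=True)
class HydrodynamicResult:
    """Stokes-Einstein radius with the inputs that produced it."""

    r_h: float                  # m
    d_tr: float                 # m^2/s
    solvent: SolventSpec
    r_h_err: float = 0.0


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def st_bfactor(nucleus: NucleusSpec | str, delta: float, big_delta: float,
               g) -> np.ndarray:
    """Stejskal-Tanner b-factor (s/m^2): (G*gamma*delta)^2 * (Delta - delta/3)."""
    if isinstance(nucleus, str):
        nucleus = get_nucleus(nucleus)
    if not (0 < delta < big_delta):
        raise ValidationError("need 0 < delta < big_delta")
    g = np.asarray(g, dtype=float)
    return (g * abs(nucleus.gamma) * delta) ** 2 * (big_delta - delta / 3.0)


def st_signal(i0: float, d: float, nucleus: NucleusSpec | str, delta: float,
              big_delta: float, g) -> np.ndarray:
    """Echo amplitude I0*exp(-D*b(G)) at gradient strength(s) ``g`` (T/m)."""
    b = st_bfactor(nucleus, delta, big_delta, g)
    return i0 * np.exp(-d * b)


# ---------------------------------------------------------------------------
# Single-component fit
# ---------------------------------------------------------------------------

def fit_st(series: EchoSeries) -> DiffusionFit:
    """Nonlinear least-squares fit of (I0, D) to an attenuation series.

    Unweighted in amplitude space unless the series carries per-point
    errors, in which case those become inverse-variance weights.  Initial
    values come from a log-linear regression of amplitude on b-factor.

    Raises
    ------
    FitFailureError
        If the series does not decay (best-fit D <= 0) or the optimizer
        fails.
    """
    if np.any(series.amplitudes <= 0):
        raise ValidationError("amplitudes must be positive to fit")
    b = series.bfactors()
    y = series.amplitudes

    # log-linear initialization; slope must be negative for a decay
    slope, intercept = np.polyfit(b, np.log(y), 1)
    d0 = max(-slope, 1e-16)
    i00 = math.exp(intercept)

    def model(bb, i0, d):
        return i0 * np.exp(-d * bb)

    sigma = series.errors
    try:
        popt, pcov = curve_fit(
            model, b, y, p0=(i00, d0), sigma=sigma,
            absolute_sigma=sigma is not None, maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"Stejskal-Tanner fit failed: {exc}") from exc
    i0_hat, d_hat = popt
    if d_hat <= 0 or not np.isfinite(d_hat):
        raise FitFailureError(
            "series does not decay with gradient (best-fit D <= 0)"
        )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return DiffusionFit(
        d_tr=float(d_hat), i0=float(i0_hat),
        d_tr_err=float(perr[1]), i0_err=float(perr[0]),
        covariance=pcov, residuals=y - model(b, *popt),
    )


# ---------------------------------------------------------------------------
# Polydispersity inversion
# ---------------------------------------------------------------------------

def invert_polydispersity(
    series: EchoSeries,
    grid_size: int = 64,
    regularization: float | None = None,
    decades: float = 4.0,
) -> DiffusionDistribution:
    """Regularized inversion of I(G) onto a log-spaced grid of D values.

    Solves  min_w ||K w - y||^2 + lam^2 ||L w||^2,  w >= 0,  with
    K_ij = exp(-b_i D_j) (plus a column of the fitted I0 scale folded into
    the weights), L the first-difference operator.  When ``regularization``
    is None, lam is chosen by the discrepancy principle: the smallest lam
    on a log grid whose residual norm reaches the estimated noise floor
    (from the single-component fit residuals).

    The grid spans ``decades`` decades centred on the single-component
    best-fit D.
    """
    fit = fit_st(series)
    d_grid = np.logspace(
        math.log10(fit.d_tr) - decades / 2.0,
        math.log10(fit.d_tr) + decades / 2.0,
        grid_size,
    )
    b = series.bfactors()
    y = series.amplitudes
    K = np.exp(-np.outer(b, d_grid))
    if np.linalg.matrix_rank(K) < 2 or y.size < 4:
        raise ValidationError("too few points for polydispersity inversion")

    L = np.diff(np.eye(grid_size), axis=0)  # first differences -> flat limit

    def solve(lam: float):
        A = np.vstack([K, lam * L])
        rhs = np.concatenate([y, np.zeros(L.shape[0])])
        w, _ = nnls(A, rhs)
        resid = float(np.linalg.norm(K @ w - y))
        return w, resid

    if regularization is not None:
        lam = float(regularization)
        w, resid = solve(lam)
    else:
        # discrepancy principle: largest lam whose misfit stays at the
        # noise floor.  The per-point sigma comes from second differences
        # of the data (var of the 2nd difference of iid noise is 6 sigma^2),
        # which is insensitive to smooth model misfit, unlike fit residuals.
        sigma = float(np.std(np.diff(y, 2))) / math.sqrt(6.0) if y.size >= 4 \
            else float(np.std(fit.residuals))
        noise = sigma * math.sqrt(max(y.size, 1))
        noise = max(noise, 1e-10 * float(np.max(y)))
        trials = [(trial, *solve(trial))
                  for trial in np.logspace(-4, 2, 25) * float(np.max(y))]
        feasible = [(t, wt, rt) for t, wt, rt in trials if rt <= noise]
        if feasible:
            lam, w, resid = max(feasible, key=lambda x: x[0])
        else:
            lam, w, resid = min(trials, key=lambda x: x[2])
    return DiffusionDistribution(
        grid=d_grid, weights=w, regularization=float(lam),
        residual_norm=resid,
    )


# ---------------------------------------------------------------------------
# Stokes-Einstein
# ---------------------------------------------------------------------------

def stokes_einstein_rh(
    d_tr: float,
    solvent: SolventSpec,
    d_tr_err: float = 0.0,
) -> HydrodynamicResult:
    """Hydrodynamic radius Rh = kB*T / (6*pi*eta*D) for a diffusing sphere.

    ``d_tr`` in m^2/s; the solvent supplies T and eta (derived from the
    viscosity table unless given explicitly).  The relative error of Rh
    equals that of D under first-order propagation.
    """
    if d_tr <= 0:
        raise ValidationError("d_tr must be > 0")
    eta = solvent_viscosity(solvent)
    r_h = KB * solvent.temperature / (6.0 * math.pi * eta * d_tr)
    r_h_err = r_h * (d_tr_err / d_tr) if d_tr_err else 0.0
    return HydrodynamicResult(r_h=r_h, d_tr=d_tr, solvent=solvent,
                              r_h_err=r_h_err)


def rh_to_dtr(r_h: float, solvent: SolventSpec) -> float:
    """Inverse Stokes-Einstein: D = kB*T / (6*pi*eta*Rh)."""
    if r_h <= 0:
        raise ValidationError("r_h must be > 0")
    eta = solvent_viscosity(solvent)
    return KB * solvent.temperature / (6.0 * math.pi * eta * r_h)
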