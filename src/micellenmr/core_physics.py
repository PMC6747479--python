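"""Physical constants, nuclei registry and solvent/stoichiometry helpers.

Everything downstream of the raw experimental tables needs a small amount
of shared physics: gyromagnetic ratios and Larmor-frequency bookkeeping for
the observed isotopes (1H, 2H, 13C, 15N, 31P), the static field of the
spectrometer, the viscosity of the aqueous solvent entering the
Stokes-Einstein relation, and the detergent-to-peptide micelle
stoichiometry used when preparing samples.

Gyromagnetic ratios are pinned to CODATA values.  Frequency ratios (the
IUPAC Xi scale, Larmor frequency relative to 1H in the same field) are the
conventional indirect-referencing values; for 13C and 15N these are the
DSS-referenced constants used throughout biomolecular NMR.  Xi and
gamma/gamma_H differ at the fourth decimal because Xi is defined against a
reference compound, not the bare nuclear moment; the two agree to 0.1%,
which the registry enforces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "KB",
    "MU0",
    "HBAR",
    "GAMMA_1H",
    "NucleusSpec",
    "FieldSpec",
    "SolventSpec",
    "NUCLEI",
    "get_nucleus",
    "gamma_to_frequency_ratio",
    "frequency_ratio_to_gamma",
    "larmor_frequency",
    "solvent_viscosity",
    "micelles_per_peptide",
    "load_config_overrides",
    "MicelleNMRError",
    "ValidationError",
    "RegistryError",
    "FitFailureError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MicelleNMRError(Exception):
    """Base class for all package errors."""


class ValidationError(MicelleNMRError, ValueError):
    """Invalid input data or parameters (CLI exit code 2)."""


class RegistryError(ValidationError):
    """Unknown nucleus or preset name."""


class FitFailureError(MicelleNMRError, RuntimeError):
    """A nonlinear fit failed to converge or hit a degenerate input
    (CLI exit code 1)."""


# ---------------------------------------------------------------------------
# Constants (SI)
# ---------------------------------------------------------------------------

KB = 1.380649e-23        # Boltzmann constant, J/K (exact)
MU0 = 1.25663706212e-6   # vacuum permeability, N/A^2
HBAR = 1.054571817e-34   # reduced Planck constant, J*s

#: gyromagnetic ratio of 1H, rad s^-1 T^-1 (CODATA)
GAMMA_1H = 2.6752218744e8


# ---------------------------------------------------------------------------
# Nuclei registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusSpec:
    """One NMR-active isotope.

    Parameters
    ----------
    name
        Isotope label, e.g. ``"1H"`` or ``"15N"``.
    gamma
        Gyromagnetic ratio in rad s^-1 T^-1, signed (15N is negative).
    frequency_ratio
        Larmor frequency relative to 1H in the same field (Xi scale,
        dimensionless, always positive).  Exactly 1 for 1H.
    """

    name: str
    gamma: float
    frequency_ratio: float

    def __post_init__(self) -> None:
        if self.frequency_ratio <= 0:
            raise ValidationError(f"frequency_ratio must be > 0 for {self.name}")
        # Xi and |gamma|/gamma_H must agree to 0.1%
        ratio = abs(self.gamma) / GAMMA_1H
        if self.name == "1H":
            if self.frequency_ratio != 1.0:
                raise ValidationError("frequency_ratio of 1H must be exactly 1")
        elif not math.isclose(ratio, self.frequency_ratio, rel_tol=1e-3):
            raise ValidationError(
                f"gamma and frequency_ratio inconsistent for {self.name}: "
                f"|gamma|/gamma_H={ratio:.6g} vs Xi={self.frequency_ratio:.6g}"
            )


def gamma_to_frequency_ratio(gamma: float) -> float:
    """Larmor-frequency ratio relative to 1H from a gyromagnetic ratio."""
    return abs(gamma) / GAMMA_1H


def frequency_ratio_to_gamma(ratio: float, sign: int = 1) -> float:
    """Gyromagnetic ratio (rad s^-1 T^-1) from a frequency ratio.

    The sign is not recoverable from the ratio and must be supplied.
    """
    return sign * ratio * GAMMA_1H


# CODATA gammas; Xi for 13C/15N are the DSS-referenced indirect-referencing
# constants, the others derive from the moments.
_REGISTRY: dict[str, NucleusSpec] = {
    n.name: n
    for n in (
        NucleusSpec("1H", 2.6752218744e8, 1.0),
        NucleusSpec("2H", 4.10662791e7, 0.153506088),
        NucleusSpec("13C", 6.728284e7, 0.251449530),
        NucleusSpec("15N", -2.71261804e7, 0.101329118),
        NucleusSpec("31P", 1.08394e8, 0.404808636),
    )
}

#: read-only view of the registered nuclei
NUCLEI = dict(_REGISTRY)


def get_nucleus(name: str) -> NucleusSpec:
    """Look up a nucleus by isotope label (e.g. ``"31P"``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown nucleus {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Static magnetic field of a spectrometer.

    Either member may be derived from the other via gamma(1H); when both
    are given they must agree to 0.1%.  The two spectrometers relevant to
    transmembrane-peptide work here are 14.1 T (1H 599.98 MHz) and 18.8 T
    (1H 799.94 MHz).
    """

    b0: float                      # Tesla
    proton_frequency: float        # Hz

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.proton_frequency <= 0:
            raise ValidationError("b0 and proton_frequency must be > 0")
        implied = GAMMA_1H * self.b0 / (2 * math.pi)
        if not math.isclose(implied, self.proton_frequency, rel_tol=1e-3):
            raise ValidationError(
                f"b0={self.b0} T implies 1H {implied/1e6:.2f} MHz, "
                f"got {self.proton_frequency/1e6:.2f} MHz (>0.1% off)"
            )

    @classmethod
    def from_proton_frequency(cls, proton_frequency: float) -> "FieldSpec":
        b0 = 2 * math.pi * proton_frequency / GAMMA_1H
        return cls(b0=b0, proton_frequency=proton_frequency)

    @classmethod
    def from_b0(cls, b0: float) -> "FieldSpec":
        return cls(b0=b0, proton_frequency=GAMMA_1H * b0 / (2 * math.pi))


def larmor_frequency(nucleus: NucleusSpec | str, field: FieldSpec) -> float:
    """Larmor frequency (Hz, positive) of ``nucleus`` at ``field``.

    Computed as Xi times the actual 1H frequency of the spectrometer, so
    that referencing follows the instrument's calibrated proton frequency
    rather than the nominal field.  |gamma|*B0/(2*pi) agrees with this to
    0.1% by the registry invariant.
    """
    if isinstance(nucleus, str):
        nucleus = get_nucleus(nucleus)
    return nucleus.frequency_ratio * field.proton_frequency


# ---------------------------------------------------------------------------
# Solvent viscosity
# ---------------------------------------------------------------------------

# Dynamic viscosity of pure H2O (mPa*s) at 5 K steps, 273.15-373.15 K.
# Standard reference-table values (IAPWS-consistent to ~0.1%).
_VISC_T = np.arange(273.15, 373.151, 5.0)
_VISC_ETA_MPAS = np.array([
    1.7914, 1.5188, 1.3061, 1.1376, 1.0016,
    0.8900, 0.7972, 0.7191, 0.6527, 0.5958,
    0.5465, 0.5036, 0.4660, 0.4329, 0.4035,
    0.3774, 0.3540, 0.3330, 0.3142, 0.2971,
    0.2817,
])

#: viscosity ratio eta(D2O)/eta(H2O) near room temperature
D2O_VISCOSITY_FACTOR = 1.23


@dataclass(frozen=True)
class SolventSpec:
    """Aqueous solvent: temperature, isotopic composition, viscosity.

    ``viscosity`` may be given explicitly (Pa*s) or left None, in which
    case it is derived from the pure-water table with a multiplicative
    D2O correction linear in ``d2o_fraction``.
    """

    temperature: float             # K
    d2o_fraction: float = 0.0      # volume fraction, 0-1
    viscosity: float | None = None  # Pa*s

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValidationError("d2o_fraction must be in [0, 1]")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValidationError("viscosity must be > 0")
        if self.viscosity is None and not (273.15 <= self.temperature <= 373.15):
            raise ValidationError(
                f"temperature {self.temperature} K outside viscosity table "
                "range 273.15-373.15 K; supply viscosity explicitly"
            )

    def with_temperature(self, temperature: float) -> "SolventSpec":
        return replace(self, temperature=temperature, viscosity=None)


def solvent_viscosity(
    solvent: SolventSpec,
    table_t: np.ndarray | None = None,
    table_eta: np.ndarray | None = None,
) -> float:
    """Dynamic viscosity (Pa*s) of the solvent.

    Explicit ``solvent.viscosity`` wins.  Otherwise the pure-H2O anchor
    table is interpolated linearly in log(eta) (viscosity is close to
    Arrhenius over this range, so log-linear interpolation reproduces the
    anchors exactly and interpolates smoothly), then scaled by
    ``1 + (D2O_VISCOSITY_FACTOR - 1) * d2o_fraction``.

    A custom anchor table may be supplied (e.g. from a config override).
    """
    if solvent.viscosity is not None:
        return solvent.viscosity
    t = solvent.temperature
    tt = _VISC_T if table_t is None else np.asarray(table_t, dtype=float)
    ee = _VISC_ETA_MPAS if table_eta is None else np.asarray(table_eta, dtype=float)
    if not (tt[0] <= t <= tt[-1]):
        raise ValidationError(
            f"temperature {t} K outside viscosity table range "
            f"{tt[0]}-{tt[-1]} K"
        )
    log_eta = float(np.interp(t, tt, np.log(ee)))
    eta_mpas = math.exp(log_eta)
    eta_mpas *= 1.0 + (D2O_VISCOSITY_FACTOR - 1.0) * solvent.d2o_fraction
    return eta_mpas * 1e-3


# ---------------------------------------------------------------------------
# Micelle stoichiometry
# ---------------------------------------------------------------------------

#: literature defaults for SDS at pH ~6.5
SDS_CMC_MM = 8.3
SDS_AGGREGATION_NUMBER = 55


def micelles_per_peptide(
    c_detergent: float,
    cmc: float,
    n_agg: float,
    c_peptide: float,
    use_free_monomer_correction: bool = False,
) -> float:
    """Micelle-to-peptide molar ratio of a detergent/peptide sample.

    Parameters are concentrations in any one consistent unit (mM
    conventionally).  The micelle concentration is ``c_detergent / n_agg``
    by default; with the free-monomer correction enabled the CMC worth of
    free detergent is subtracted first, ``(c_detergent - cmc) / n_agg``.
    The uncorrected convention is the default: a 110 mM SDS sample with
    aggregation number 55 and 1 mM peptide is quoted as 2:1.

    Raises
    ------
    ValidationError
        If ``c_detergent <= cmc`` with the correction enabled (no micelles
        can form), or on non-physical inputs.
    """
    if n_agg < 1:
        raise ValidationError("aggregation number must be >= 1")
    if c_peptide <= 0:
        raise ValidationError("peptide concentration must be > 0")
    if cmc < 0 or c_detergent < 0:
        raise ValidationError("concentrations must be >= 0")
    effective = c_detergent
    if use_free_monomer_correction:
        if c_detergent <= cmc:
            raise ValidationError(
                f"detergent concentration {c_detergent} is at or below the "
                f"CMC {cmc}: no micelles form"
            )
        effective = c_detergent - cmc
    return effective / n_agg / c_peptide


# ---------------------------------------------------------------------------
# Config overrides
# ---------------------------------------------------------------------------

def load_config_overrides(path: str | Path) -> dict:
    """Read a JSON config file overriding viscosity table / CMC defaults.

    Recognised keys: ``viscosity_table`` (``{"temperature_k": [...],
    "eta_mpas": [...]}``), ``cmc_mm``, ``aggregation_number``.  Unknown
    keys are rejected to catch typos early.
    """
    data = json.loads(Path(path).read_text())
    allowed = {"viscosity_table", "cmc_mm", "aggregation_number"}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "viscosity_table" in data:
        vt = data["viscosity_table"]
        t = np.asarray(vt["temperature_k"], dtype=float)
        e = np.asarray(vt["eta_mpas"], dtype=float)
        if t.shape != e.shape or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("viscosity_table must be two equal-length "
                                  "arrays with strictly increasing temperature")
        data["viscosity_table"] = {"temperature_k": t, "eta_mpas": e}
    return data
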