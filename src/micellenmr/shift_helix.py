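"""Chemical-shift perturbation between two media and helical-wheel
amphipathicity summaries.

CSP maps where a peptide feels a different environment in two membrane
mimetics: for each residue the signed difference of a chemical shift
(conventionally the amide proton) between medium b and medium a.  The
helical-wheel projection places residues around a circle at the ideal
alpha-helical 100 degrees per residue and classifies each as hydrophobic
or hydrophilic; clustering of the hydrophobic residues on one side of the
wheel (quantified by the circular mean resultant length of their angles)
is the signature of an amphipathic helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_physics import ValidationError

__all__ = [
    "ShiftTable",
    "WheelAssignment",
    "CspResult",
    "HYDROPHOBIC_RESIDUES",
    "csp",
    "combined_csp",
    "wheel",
    "hydrophobic_moment_direction",
    "amphipathicity",
    "parse_sequence",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: default hydrophobic residue classes for face assignment
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVW")


@dataclass(frozen=True)
class ShiftTable:
    """Per-residue chemical shifts, one row per (residue, atom).

    ``entries`` is a DataFrame with columns residue_number, residue_type,
    atom, shift_ppm.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"residue_number", "residue_type", "atom", "shift_ppm"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValidationError(f"shift table missing columns: "
                                  f"{sorted(missing)}")
        df = self.entries
        if not np.all(np.isfinite(df["shift_ppm"].to_numpy(dtype=float))):
            raise ValidationError("shifts must be finite")
        for atom, grp in df.groupby("atom"):
            nums = grp["residue_number"].to_numpy()
            if np.any(np.diff(nums) <= 0):
                raise ValidationError(
                    f"residue numbers must be strictly increasing per atom "
                    f"(atom {atom!r})"
                )

    @classmethod
    def from_records(cls, records) -> "ShiftTable":
        """Build from (residue_number, residue_type, atom, shift_ppm) rows."""
        df = pd.DataFrame(records, columns=["residue_number", "residue_type",
                                            "atom", "shift_ppm"])
        return cls(df)

    def atom_shifts(self, atom: str) -> pd.Series:
        sub = self.entries[self.entries["atom"] == atom]
        return pd.Series(sub["shift_ppm"].to_numpy(dtype=float),
                         index=sub["residue_number"].to_numpy(dtype=int))


@dataclass(frozen=True)
class WheelAssignment:
    """One residue on the helical wheel."""

    residue_number: int
    residue_type: str
    angle: float        # degrees, [0, 360)
    face: str           # "hydrophobic" | "hydrophilic"


@dataclass(frozen=True)
class CspResult:
    """Signed per-residue shift differences with bookkeeping of residues
    present in only one table."""

    atom: str
    differences: pd.Series          # index residue_number, ppm (b - a)
    missing_in_a: tuple
    missing_in_b: tuple


def csp(table_a: ShiftTable, table_b: ShiftTable, atom: str = "HN") -> CspResult:
    """Signed chemical-shift perturbation delta_b - delta_a per residue.

    Negative values are upfield shifts in medium b relative to medium a.
    Residues covered by only one table are reported as missing, never as
    zero.

    Raises
    ------
    ValidationError
        If the two tables share no residue for the requested atom.
    """
    a = table_a.atom_shifts(atom)
    b = table_b.atom_shifts(atom)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValidationError(
            f"no overlapping residues for atom {atom!r} between the tables"
        )
    diffs = (b.loc[common] - a.loc[common]).astype(float)
    return CspResult(
        atom=atom,
        differences=diffs,
        missing_in_a=tuple(sorted(b.index.difference(a.index))),
        missing_in_b=tuple(sorted(a.index.difference(b.index))),
    )


def combined_csp(delta_h: pd.Series, delta_n: pd.Series,
                 n_scale: float = 5.0) -> pd.Series:
    """Combined-magnitude CSP sqrt(dH^2 + (dN/n_scale)^2) per residue.

    Off the default path — the signed single-atom form is the primary
    summary; this is provided for tables that carry both 1H and 15N
    shifts.
    """
    common = delta_h.index.intersection(delta_n.index)
    if len(common) == 0:
        raise ValidationError("no overlapping residues between dH and dN")
    return np.sqrt(delta_h.loc[common] ** 2
                   + (delta_n.loc[common] / n_scale) ** 2)


def parse_sequence(text: str) -> str:
    """One-letter sequence from a plain string or FASTA-formatted text."""
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError("empty sequence")
    if lines[0].startswith(">"):
        lines = lines[1:]
    seq = "".join(lines).upper().replace(" ", "")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"invalid residue letters: {sorted(bad)}")
    if not seq:
        raise ValidationError("empty sequence")
    return seq


def wheel(
    sequence: str,
    start_residue: int = 1,
    per_residue_rotation: float = 100.0,
    hydrophobic_set=HYDROPHOBIC_RESIDUES,
) -> list[WheelAssignment]:
    """Helical-wheel projection of a sequence.

    Residue i sits at angle ((i - start_residue) * per_residue_rotation)
    mod 360; the default 100 degrees per residue is the ideal alpha-helix
    (3.6 residues per turn).  The angle depends only on the index, the
    face only on membership in ``hydrophobic_set``.
    """
    seq = parse_sequence(sequence)
    out = []
    for offset, aa in enumerate(seq):
        num = start_residue + offset
        angle = (offset * per_residue_rotation) % 360.0
        face = "hydrophobic" if aa in hydrophobic_set else "hydrophilic"
        out.append(WheelAssignment(num, aa, angle, face))
    return out


def hydrophobic_moment_direction(assignments) -> tuple[float, float]:
    """Circular mean resultant length and mean angle (degrees) of the
    hydrophobic residues on the wheel.

    The resultant length is 1 when all hydrophobic residues sit at one
    angle and 0 when they are spread uniformly; it is the amphipathicity
    statistic used by :func:`amphipathicity`.
    """
    angles = np.array([math.radians(a.angle) for a in assignments
                       if a.face == "hydrophobic"])
    if angles.size == 0:
        raise ValidationError("no hydrophobic residues on the wheel")
    z = np.exp(1j * angles).mean()
    return float(abs(z)), float(math.degrees(np.angle(z)) % 360.0)


def amphipathicity(assignments, threshold: float = 0.4) -> dict:
    """Amphipathicity summary of a wheel projection.

    Returns the circular mean resultant length of the hydrophobic angles,
    the mean hydrophobic direction, the hydrophobic fraction and a boolean
    ``amphipathic`` flag (resultant length above ``threshold``, a
    documented heuristic).
    """
    resultant, direction = hydrophobic_moment_direction(assignments)
    n_phob = sum(1 for a in assignments if a.face == "hydrophobic")
    return {
        "resultant_length": resultant,
        "mean_direction_deg": direction,
        "hydrophobic_fraction": n_phob / len(assignments),
        "amphipathic": resultant > threshold,
        "threshold": threshold,
    }
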