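"""Monoisotopic mass arithmetic for residues, peptides and modifications.

All masses are monoisotopic daltons. Residue masses are the standard
monoisotopic residue (i.e. dehydrated) masses; a peptide's neutral mass is
the residue sum plus one water. m/z values follow the usual convention
(M + z*H+) / z with the proton mass 1.007276 Da.

This module is the numerical foundation of the package: digestion,
cross-link modelling, the fingerprint scanner and the search engine all
express their arithmetic through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

__all__ = [
    "PROTON",
    "WATER",
    "AMMONIA",
    "HYDROGEN",
    "SULFUR",
    "HYDROGEN_SULFIDE",
    "DISULFIDE_DELTA",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "Modification",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "ACETYL_PROTEIN_NTERM",
    "BUILTIN_MODIFICATIONS",
    "InvalidResidueError",
    "residue_mass",
    "peptide_neutral_mass",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_window",
    "round_mz",
]

# Fundamental constants (Da), fixed to six decimals.
PROTON = 1.007276
WATER = 18.010565
AMMONIA = 17.026549
HYDROGEN = 1.007825
SULFUR = 31.972071
HYDROGEN_SULFIDE = 33.987721  # = SULFUR + 2 * HYDROGEN

#: Mass change of forming a disulfide bond between two free thiols (-2H).
DISULFIDE_DELTA = -2.0 * HYDROGEN

#: Standard monoisotopic residue masses (Da) for the 20 canonical amino acids.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,  # isobaric with Leu
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Token accepted as a modification target for the protein N-terminus.
PROTEIN_NTERM = "protein-nterm"


class InvalidResidueError(ValueError):
    """Raised for residue codes outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class Modification:
    """A named mass shift applied to a residue or terminus.

    Parameters
    ----------
    name : str
        Human-readable name (e.g. ``"Oxidation"``).
    target : str
        Single residue letter, or the token ``"protein-nterm"``.
    delta_mass : float
        Monoisotopic mass shift in Da.
    variable : bool
        Whether the modification is considered variable in a search.
    """

    name: str
    target: str
    delta_mass: float
    variable: bool = True

    def __post_init__(self) -> None:
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError(f"non-finite delta mass for modification {self.name!r}")
        if self.target != PROTEIN_NTERM and self.target not in MONOISOTOPIC_RESIDUE_MASSES:
            raise ValueError(
                f"modification {self.name!r} targets unknown residue/terminus {self.target!r}"
            )


CARBAMIDOMETHYL = Modification("Carbamidomethyl", "C", 57.021464)
OXIDATION = Modification("Oxidation", "M", 15.994915)
ACETYL_PROTEIN_NTERM = Modification("Acetyl", PROTEIN_NTERM, 42.010565)

BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    m.name: m for m in (CARBAMIDOMETHYL, OXIDATION, ACETYL_PROTEIN_NTERM)
}

#: An applied modification: (modification, 1-based residue position; 0 = N-terminus).
AppliedMod = Tuple[Modification, int]


def residue_mass(code: str) -> float:
    """Monoisotopic residue mass of a single amino-acid letter.

    Raises
    ------
    InvalidResidueError
        For any letter outside the 20 standard codes (including the
        ambiguity codes B, J, O, U, X, Z).
    """
    try:
        return MONOISOTOPIC_RESIDUE_MASSES[code]
    except KeyError:
        raise InvalidResidueError(f"invalid amino-acid code {code!r}") from None


def _validate_mods(seq: str, mods: Sequence[AppliedMod]) -> None:
    for mod, pos in mods:
        if mod.target == PROTEIN_NTERM:
            if pos != 0:
                raise ValueError(
                    f"terminal modification {mod.name!r} must be applied at position 0"
                )
            continue
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"modification {mod.name!r} position {pos} outside peptide of length {len(seq)}"
            )
        if seq[pos - 1] != mod.target:
            raise ValueError(
                f"modification {mod.name!r} targets {mod.target!r} but residue at "
                f"position {pos} is {seq[pos - 1]!r}"
            )


def peptide_neutral_mass(seq: str, mods: Sequence[AppliedMod] = ()) -> float:
    """Neutral monoisotopic mass of a peptide with applied modifications.

    The mass is the sum of residue masses plus one water plus all
    modification deltas. ``mods`` are ``(Modification, position)`` pairs with
    1-based residue positions (0 denotes the N-terminus for terminal mods).
    """
    if not seq:
        raise ValueError("empty peptide sequence")
    total = WATER
    for i, code in enumerate(seq):
        try:
            total += MONOISOTOPIC_RESIDUE_MASSES[code]
        except KeyError:
            raise InvalidResidueError(
                f"invalid amino-acid code {code!r} at position {i + 1}"
            ) from None
    _validate_mods(seq, mods)
    for mod, _pos in mods:
        total += mod.delta_mass
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at a positive integer charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass corresponding to an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def ppm_window(value: float, ppm: float) -> float:
    """Half-width in Da of a ±ppm window around ``value``."""
    return abs(value) * ppm * 1e-6


def round_mz(value: float, decimals: int = 4) -> float:
    """Round a reported mass/m-z value half-up at the printed precision.

    All constants in this module carry six decimals, so any sum of them is
    exact at six decimals up to float epsilon; rounding the 6-decimal
    representation half-up reproduces conventional printed m/z values even
    when the true value is a decimal tie (e.g. 874.405350 -> 874.4054),
    where binary floats would otherwise tip the wrong way.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{value:.6f}").quantize(quantum, rounding=ROUND_HALF_UP))
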