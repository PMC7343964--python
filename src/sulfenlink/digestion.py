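"""In-silico Trypsin/Lys-C digestion with missed cleavages and coordinates.

Cleavage is C-terminal to K/R and, by default, suppressed when the next
residue is proline (the prevailing search-engine convention). Peptide
coordinates are 1-based inclusive protein residue indices, matching the
Cys598/Cys75-style site naming used throughout the package.

Also houses the reporter-isobaric conflict screen: tryptic peptides (of the
forward database or of reversed decoys) whose neutral mass coincides with
the reporter peptide's will produce spurious high-scoring matches in a
target-decoy search and must be reported so the user can mask them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO

from .chem import InvalidResidueError, MONOISOTOPIC_RESIDUE_MASSES, peptide_neutral_mass, ppm_window

__all__ = [
    "ProteinRecord",
    "DigestPeptide",
    "DigestionSettings",
    "read_fasta",
    "write_fasta",
    "reverse_decoy",
    "digest",
    "digest_database",
    "cys_peptides",
    "IsobaricConflict",
    "find_isobaric_reporter_conflicts",
]

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein: accession, free-text description, sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with provenance and 1-based inclusive coordinates."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int

    def cys_protein_positions(self) -> Tuple[int, ...]:
        """1-based protein coordinates of every Cys in the peptide."""
        return tuple(self.start + i for i, c in enumerate(self.sequence) if c == "C")

    def cys_peptide_positions(self) -> Tuple[int, ...]:
        """1-based peptide-internal positions of every Cys."""
        return tuple(i + 1 for i, c in enumerate(self.sequence) if c == "C")


@dataclass(frozen=True)
class DigestionSettings:
    """Digestion defaults: tryptic, <=2 missed cleavages, length 6-60."""

    max_missed: int = 2
    min_len: int = 6
    max_len: int = 60
    proline_rule: bool = True


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read a FASTA database; the first whitespace token is the accession."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        records.append(ProteinRecord(acc, rec.description, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write proteins as uncompressed FASTA, 60 residues per line."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            if not header.startswith(rec.accession):
                header = f"{rec.accession} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def reverse_decoy(protein: ProteinRecord) -> ProteinRecord:
    """Full-sequence reversal decoy with a ``DECOY_`` accession prefix."""
    return ProteinRecord(
        DECOY_PREFIX + protein.accession,
        f"{DECOY_PREFIX}{protein.accession} reversed",
        protein.sequence[::-1],
    )


def _validate_sequence(protein: ProteinRecord) -> None:
    for i, code in enumerate(protein.sequence):
        if code not in MONOISOTOPIC_RESIDUE_MASSES:
            raise InvalidResidueError(
                f"protein {protein.accession!r}: invalid residue {code!r} at position {i + 1}"
            )


def cleavage_boundaries(sequence: str, proline_rule: bool = True) -> List[int]:
    """0-based boundary offsets splitting the sequence into fully-cleaved pieces.

    A boundary ``b`` means cleavage between ``sequence[b-1]`` and
    ``sequence[b]``; the returned list always starts with 0 and ends with
    ``len(sequence)``.
    """
    n = len(sequence)
    bounds = [0]
    for i in range(n - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            bounds.append(i + 1)
    bounds.append(n)
    return bounds


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 60,
    proline_rule: bool = True,
) -> List[DigestPeptide]:
    """All tryptic peptides of one protein within the configured bounds.

    Peptides are ordered by start coordinate, then length; coordinates are
    1-based inclusive and ``missed_cleavages`` counts uncut internal K/R
    sites.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    _validate_sequence(protein)
    bounds = cleavage_boundaries(protein.sequence, proline_rule)
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            seq = protein.sequence[bounds[a] : bounds[b]]
            if not min_len <= len(seq) <= max_len:
                continue
            peptides.append(
                DigestPeptide(
                    sequence=seq,
                    parent_accession=protein.accession,
                    start=bounds[a] + 1,
                    end=bounds[b],
                    missed_cleavages=b - a - 1,
                )
            )
    return peptides


def digest_database(
    database: Sequence[ProteinRecord], settings: DigestionSettings = DigestionSettings()
) -> List[DigestPeptide]:
    """Digest every protein of a database with shared settings."""
    if not database:
        raise ValueError("empty protein database")
    out: List[DigestPeptide] = []
    for protein in database:
        out.extend(
            digest(
                protein,
                max_missed=settings.max_missed,
                min_len=settings.min_len,
                max_len=settings.max_len,
                proline_rule=settings.proline_rule,
            )
        )
    return out


def cys_peptides(
    database: Sequence[ProteinRecord], settings: DigestionSettings = DigestionSettings()
) -> List[DigestPeptide]:
    """Digest the database and keep peptides containing at least one Cys.

    These are the candidate disulfide partners: only a cysteine thiol can
    participate in the mixed disulfide with the reporter.
    """
    return [p for p in digest_database(database, settings) if "C" in p.sequence]


@dataclass(frozen=True)
class IsobaricConflict:
    """A peptide whose mass collides with the reporter's within tolerance."""

    accession: str
    peptide: DigestPeptide
    source: str  # "target" or "decoy"
    delta_ppm: float

    @property
    def reason(self) -> str:
        return (
            f"{self.source} peptide {self.peptide.sequence!r} is isobaric with the "
            f"reporter ({self.delta_ppm:+.3f} ppm)"
        )


def find_isobaric_reporter_conflicts(
    database: Sequence[ProteinRecord],
    reporter_sequence: str,
    mass_tol_ppm: float = 20.0,
    settings: DigestionSettings | None = None,
) -> List[IsobaricConflict]:
    """Flag target and reversed-decoy peptides isobaric with the reporter.

    A protein tail such as ``...RDWLESC`` reverses into a ``CSELWDR``
    tryptic decoy peptide that is isobaric (Leu/Ile identity) with the
    ``CSEIWDR`` reporter and would absorb reporter-driven spectra as
    high-scoring decoys; such segments should be masked before decoy
    generation. The screen digests both the forward proteins and their
    full reversals.
    """
    if settings is None:
        settings = DigestionSettings(min_len=1, max_len=60, max_missed=2)
    reporter_mass = peptide_neutral_mass(reporter_sequence)
    tol_da = ppm_window(reporter_mass, mass_tol_ppm)
    conflicts: List[IsobaricConflict] = []
    for protein in database:
        for source, prot in (("target", protein), ("decoy", reverse_decoy(protein))):
            for pep in digest(
                prot,
                max_missed=settings.max_missed,
                min_len=settings.min_len,
                max_len=settings.max_len,
                proline_rule=settings.proline_rule,
            ):
                if "C" not in pep.sequence:
                    continue
                mass = peptide_neutral_mass(pep.sequence)
                if abs(mass - reporter_mass) <= tol_da:
                    conflicts.append(
                        IsobaricConflict(
                            accession=protein.accession,
                            peptide=pep,
                            source=source,
                            delta_ppm=(mass - reporter_mass) / reporter_mass * 1e6,
                        )
                    )
    return conflicts
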