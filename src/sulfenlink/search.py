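"""Reporter-anchored disulfide cross-link search with target-decoy FDR.

One chain of every cross-link is fixed to the reporter peptide (plus its
missed-cleavage variants), which reduces the quadratic cross-link search
to a linear-peptide-style lookup: the partner's neutral mass must equal
the observed precursor neutral mass minus the reporter chain mass plus
two hydrogens. Candidates come from a mass-sorted index of cysteine
peptides (targets) and reversed-protein decoys, with variable
modifications expanded combinatorially.

Scoring is a simple additive information score: each matched theoretical
fragment contributes -log10 of its probability of being matched by chance
given the spectrum's peak density and the fragment tolerance. The score
has a closed-form null, which keeps the target-decoy FDR estimate
analyzable; it makes no attempt to reproduce any external search engine's
score scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    ACETYL_PROTEIN_NTERM,
    CARBAMIDOMETHYL,
    HYDROGEN,
    OXIDATION,
    AppliedMod,
    Modification,
    mass_from_mz,
    peptide_neutral_mass,
    ppm_window,
)
from .crosslink import CrossLinkedPeptide, ReporterPeptide, CSEIWDR_REPORTER, theoretical_fragments
from .digestion import (
    DigestPeptide,
    DigestionSettings,
    ProteinRecord,
    cys_peptides,
    find_isobaric_reporter_conflicts,
    reverse_decoy,
)
from .spectra import Spectrum, Tolerance, match_peaks

__all__ = [
    "SearchSettings",
    "CandidateEntry",
    "PartnerIndex",
    "build_partner_index",
    "expand_modifications",
    "score_psm",
    "search_spectrum",
    "search_spectra",
    "PSM",
    "compute_fdr",
    "peptide_level_fdr",
    "protein_groups",
]


@dataclass(frozen=True)
class SearchSettings:
    """Search parameters (defaults: 20 ppm tolerances, <=2 missed cleavages,
    charges 2-6, partners >= 6 residues, 1% FDR)."""

    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 20.0
    max_missed: int = 2
    min_partner_len: int = 6
    max_partner_len: int = 60
    max_var_mods: int = 3
    charges_considered: Tuple[int, ...] = (2, 3, 4, 5, 6)
    fdr_threshold: float = 0.01
    max_fragment_charge: int = 2
    variable_mods: Tuple[Modification, ...] = (OXIDATION, CARBAMIDOMETHYL, ACETYL_PROTEIN_NTERM)

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")

    def digestion(self) -> DigestionSettings:
        return DigestionSettings(
            max_missed=self.max_missed,
            min_len=self.min_partner_len,
            max_len=self.max_partner_len,
        )


@dataclass(frozen=True)
class CandidateEntry:
    """One partner hypothesis: sequence + linked Cys + modification state."""

    mass: float
    sequence: str
    accession: str
    start: int
    linked_cys: int  # 1-based position within the peptide
    mods: Tuple[AppliedMod, ...]
    is_decoy: bool

    @property
    def linked_protein_position(self) -> int:
        return self.start + self.linked_cys - 1


def expand_modifications(
    peptide: DigestPeptide,
    linked_cys: int,
    settings: SearchSettings,
    protein_nterm: bool = False,
) -> List[Tuple[AppliedMod, ...]]:
    """Enumerate variable-modification states for one candidate peptide.

    Sites: oxidation on each Met, carbamidomethyl on each non-linked Cys,
    N-terminal acetyl when the peptide starts the protein. The linked Cys
    is never carbamidomethylated (its thiol is in the disulfide). At most
    ``max_var_mods`` are applied; the unmodified state is always included.
    """
    sites: List[AppliedMod] = []
    for mod in settings.variable_mods:
        if mod.target == "protein-nterm":
            if protein_nterm:
                sites.append((mod, 0))
            continue
        for i, res in enumerate(peptide.sequence, start=1):
            if res == mod.target and not (mod.name == CARBAMIDOMETHYL.name and i == linked_cys):
                sites.append((mod, i))
    states: List[Tuple[AppliedMod, ...]] = [()]
    for k in range(1, min(settings.max_var_mods, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            positions = [pos for _, pos in combo]
            if len(positions) == len(set(positions)):
                states.append(tuple(combo))
    return states


class PartnerIndex:
    """Mass-sorted candidate index supporting ppm range queries."""

    def __init__(self, entries: Sequence[CandidateEntry]):
        if not entries:
            raise ValueError("empty candidate set")
        ordered = sorted(entries, key=lambda e: (e.mass, e.sequence, e.accession, e.is_decoy))
        self.entries: List[CandidateEntry] = ordered
        self.masses = np.array([e.mass for e in ordered])

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, mass: float, tol_da: float) -> List[CandidateEntry]:
        """All entries with |entry.mass - mass| <= tol_da."""
        lo = int(np.searchsorted(self.masses, mass - tol_da, side="left"))
        hi = int(np.searchsorted(self.masses, mass + tol_da, side="right"))
        return self.entries[lo:hi]

    @property
    def n_targets(self) -> int:
        return sum(not e.is_decoy for e in self.entries)

    @property
    def n_decoys(self) -> int:
        return sum(e.is_decoy for e in self.entries)


def build_partner_index(
    database: Sequence[ProteinRecord],
    settings: SearchSettings = SearchSettings(),
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
    with_decoys: bool = True,
    mask_isobaric_decoys: bool = True,
) -> PartnerIndex:
    """Build the candidate index from a protein database.

    Targets are cysteine-containing tryptic peptides; decoys come from
    full-protein reversal (the reporter itself is never part of the decoy
    space). Decoy peptides isobaric with the reporter are masked by
    default: a reversed segment reading like the reporter would soak up
    genuine reporter-anchored spectra as high-scoring decoys and wreck the
    FDR estimate.
    """
    digestion = settings.digestion()
    reporter_mass = peptide_neutral_mass(reporter.sequence)
    mask_tol = ppm_window(reporter_mass, settings.precursor_tol_ppm)

    entries: List[CandidateEntry] = []

    def add_protein(protein: ProteinRecord, is_decoy: bool) -> None:
        for pep in cys_peptides([protein], digestion):
            mass0 = peptide_neutral_mass(pep.sequence)
            if is_decoy and mask_isobaric_decoys and abs(mass0 - reporter_mass) <= mask_tol:
                continue
            nterm = pep.start == 1
            for cys_pos in pep.cys_peptide_positions():
                for mods in expand_modifications(pep, cys_pos, settings, protein_nterm=nterm):
                    entries.append(
                        CandidateEntry(
                            mass=mass0 + sum(m.delta_mass for m, _ in mods),
                            sequence=pep.sequence,
                            accession=pep.parent_accession,
                            start=pep.start,
                            linked_cys=cys_pos,
                            mods=mods,
                            is_decoy=is_decoy,
                        )
                    )

    for protein in database:
        add_protein(protein, is_decoy=False)
        if with_decoys:
            add_protein(reverse_decoy(protein), is_decoy=True)
    return PartnerIndex(entries)


@dataclass
class PSM:
    """A scored spectrum-to-cross-link match."""

    spectrum_title: str
    clpep: CrossLinkedPeptide
    score: float
    matched_fragments: int
    is_decoy: bool
    accession: str
    linked_protein_position: int
    charge: int
    precursor_error_ppm: float
    is_self_link: bool = False
    ambiguous: bool = False
    q_value: Optional[float] = None


def score_psm(
    spectrum: Spectrum,
    clpep: CrossLinkedPeptide,
    settings: SearchSettings = SearchSettings(),
) -> Tuple[float, int]:
    """Additive -log10 random-match score over matched theoretical fragments.

    The per-fragment random-match probability is ``n_peaks * 2 * tol_da /
    mz_span`` (capped below 1), i.e. the chance that at least one of the
    spectrum's peaks falls in the fragment's tolerance window were peaks
    placed uniformly at random. Deterministic; intensity-free.
    """
    if len(spectrum) == 0:
        return 0.0, 0
    frags = theoretical_fragments(clpep, max_charge=settings.max_fragment_charge)
    targets = [f.mz for f in frags]
    tol = Tolerance(settings.fragment_tol_ppm, "ppm")
    matches = match_peaks(spectrum, targets, tol)
    span = max(float(spectrum.mz[-1] - spectrum.mz[0]), 1.0)
    density = len(spectrum) / span
    score = 0.0
    for m in matches:
        p = min(0.999, density * 2.0 * tol.window(m.target_mz))
        score += -np.log10(p)
    return float(score), len(matches)


def _reporter_anchors(
    reporter: ReporterPeptide, extra_anchor_sequences: Sequence[str] = ()
) -> List[ReporterPeptide]:
    anchors = [reporter]
    for seq in extra_anchor_sequences:
        idx = seq.index("C") + 1
        anchors.append(ReporterPeptide(seq, reactive_cys_index=idx))
    return anchors


def search_spectrum(
    spectrum: Spectrum,
    index: PartnerIndex,
    settings: SearchSettings = SearchSettings(),
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
    extra_anchor_sequences: Sequence[str] = (),
    max_rank: int = 5,
) -> List[PSM]:
    """Rank partner candidates for one spectrum.

    For each considered charge (the spectrum's own if known, otherwise all
    of ``charges_considered``) and each reporter anchor (the base reporter
    plus any missed-cleavage variants), the required partner mass is
    ``precursor_neutral - anchor_mass + 2H``; candidates within the
    precursor ppm window are scored and returned in descending score order
    with deterministic tie-breaking. Equal-scoring top candidates (e.g.
    Leu/Ile isobars) are flagged ambiguous.
    """
    charges: Sequence[int]
    if spectrum.precursor_charge is not None and spectrum.precursor_charge in settings.charges_considered:
        charges = (spectrum.precursor_charge,)
    elif spectrum.precursor_charge is not None:
        return []
    else:
        charges = settings.charges_considered

    psms: List[PSM] = []
    for z in charges:
        neutral = mass_from_mz(spectrum.precursor_mz, z)
        tol_da = ppm_window(neutral, settings.precursor_tol_ppm)
        for anchor in _reporter_anchors(reporter, extra_anchor_sequences):
            anchor_mass = anchor.neutral_mass()
            partner_mass = neutral - anchor_mass + 2 * HYDROGEN
            if partner_mass <= 0:
                continue
            for entry in index.query(partner_mass, tol_da):
                clpep = CrossLinkedPeptide(
                    reporter_sequence=anchor.sequence,
                    partner_sequence=entry.sequence,
                    reporter_cys_index=anchor.reactive_cys_index,
                    partner_cys_index=entry.linked_cys,
                    partner_mods=entry.mods,
                )
                score, n_matched = score_psm(spectrum, clpep, settings)
                theo = clpep.neutral_mass()
                psms.append(
                    PSM(
                        spectrum_title=spectrum.title,
                        clpep=clpep,
                        score=score,
                        matched_fragments=n_matched,
                        is_decoy=entry.is_decoy,
                        accession=entry.accession,
                        linked_protein_position=entry.linked_protein_position,
                        charge=z,
                        precursor_error_ppm=(neutral - theo) / theo * 1e6,
                        is_self_link=clpep.is_self_link(),
                    )
                )
    psms.sort(
        key=lambda p: (
            -p.score,
            p.is_decoy,
            p.clpep.partner_sequence,
            p.accession,
            p.linked_protein_position,
        )
    )
    if len(psms) >= 2 and psms[0].score == psms[1].score:
        psms[0].ambiguous = True
        psms[1].ambiguous = True
    return psms[:max_rank]


def search_spectra(
    spectra: Iterable[Spectrum],
    index: PartnerIndex,
    settings: SearchSettings = SearchSettings(),
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
    extra_anchor_sequences: Sequence[str] = (),
) -> List[PSM]:
    """Best PSM per spectrum across a spectrum collection."""
    best: List[PSM] = []
    for spectrum in spectra:
        ranked = search_spectrum(
            spectrum, index, settings, reporter, extra_anchor_sequences, max_rank=1
        )
        if ranked:
            best.append(ranked[0])
    return best


def _qvalues(psms: List[PSM]) -> None:
    """Attach target-decoy q-values in place (PSMs sorted by score desc)."""
    n_decoy = 0
    n_target = 0
    fdrs = []
    for p in psms:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(n_target, 1))
    q = float("inf")
    for i in range(len(psms) - 1, -1, -1):
        q = min(q, fdrs[i])
        psms[i].q_value = q


def compute_fdr(
    psms: Sequence[PSM],
    threshold: float | None = None,
) -> Tuple[List[PSM], List[PSM]]:
    """Spectrum-level target-decoy FDR.

    Keeps the best PSM per spectrum, estimates FDR at score ``s`` as
    ``#decoys >= s / #targets >= s``, converts to q-values by a running
    minimum, and returns ``(all_psms_with_q, accepted_targets)`` where the
    accepted set is targets with q <= threshold.
    """
    if threshold is None:
        threshold = SearchSettings().fdr_threshold
    best_per_spectrum: Dict[str, PSM] = {}
    for p in psms:
        cur = best_per_spectrum.get(p.spectrum_title)
        if cur is None or (p.score, not p.is_decoy) > (cur.score, not cur.is_decoy):
            best_per_spectrum[p.spectrum_title] = p
    pool = sorted(
        best_per_spectrum.values(),
        key=lambda p: (-p.score, p.is_decoy, p.spectrum_title),
    )
    if not any(not p.is_decoy for p in pool):
        raise ValueError("no target PSMs to estimate FDR from")
    _qvalues(pool)
    accepted = [p for p in pool if not p.is_decoy and p.q_value is not None and p.q_value <= threshold]
    return pool, accepted


def peptide_level_fdr(
    psms: Sequence[PSM], threshold: float | None = None
) -> Tuple[List[PSM], List[PSM]]:
    """Target-decoy FDR on the best PSM per partner peptide (sequence+mods)."""
    if threshold is None:
        threshold = SearchSettings().fdr_threshold
    best: Dict[Tuple[str, Tuple[AppliedMod, ...], bool], PSM] = {}
    for p in psms:
        key = (p.clpep.partner_sequence, p.clpep.partner_mods, p.is_decoy)
        cur = best.get(key)
        if cur is None or p.score > cur.score:
            best[key] = p
    pool = sorted(best.values(), key=lambda p: (-p.score, p.is_decoy, p.clpep.partner_sequence))
    if not any(not p.is_decoy for p in pool):
        raise ValueError("no target PSMs to estimate FDR from")
    _qvalues(pool)
    accepted = [p for p in pool if not p.is_decoy and p.q_value <= threshold]
    return pool, accepted


def protein_groups(accepted: Sequence[PSM]) -> pd.DataFrame:
    """Group accepted PSMs by protein accession (simple grouping report)."""
    rows: Dict[str, Dict[str, object]] = {}
    for p in accepted:
        g = rows.setdefault(
            p.accession,
            {"accession": p.accession, "n_psms": 0, "peptides": set(), "sites": set()},
        )
        g["n_psms"] = int(g["n_psms"]) + 1
        g["peptides"].add(p.clpep.partner_sequence)  # type: ignore[union-attr]
        g["sites"].add(p.linked_protein_position)  # type: ignore[union-attr]
    out = [
        {
            "accession": g["accession"],
            "n_psms": g["n_psms"],
            "n_peptides": len(g["peptides"]),  # type: ignore[arg-type]
            "n_sites": len(g["sites"]),  # type: ignore[arg-type]
        }
        for g in rows.values()
    ]
    return pd.DataFrame(out, columns=["accession", "n_psms", "n_peptides", "n_sites"]).sort_values(
        "accession", ignore_index=True
    )


def psms_to_table(psms: Sequence[PSM]) -> pd.DataFrame:
    """Flatten PSMs into a pLink-style report table."""
    rows = []
    for p in psms:
        rows.append(
            {
                "title": p.spectrum_title,
                "peptide_A": p.clpep.reporter_sequence,
                "peptide_B": p.clpep.partner_sequence,
                "linked_positions": f"{p.clpep.reporter_cys_index}-{p.clpep.partner_cys_index}",
                "protein": p.accession,
                "protein_cys_position": p.linked_protein_position,
                "mods": ";".join(f"{m.name}@{pos}" for m, pos in p.clpep.partner_mods),
                "charge": p.charge,
                "precursor_error_ppm": p.precursor_error_ppm,
                "score": p.score,
                "matched_fragments": p.matched_fragments,
                "is_decoy": p.is_decoy,
                "is_self_link": p.is_self_link,
                "ambiguous": p.ambiguous,
                "q_value": p.q_value,
            }
        )
    return pd.DataFrame(rows)
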