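"""Ground-truth synthetic data: proteomes, cross-link spectra, controls.

Emulates the study conditions the rest of the package is designed for:
random protein databases at the Arabidopsis cysteine frequency (1.86% of
residues), cross-linked precursors formed as reporter + partner - 2H at
charges 2-6 (heavily skewed to >= 3+), MS/MS spectra carrying a
configurable fraction of both chains' b/y ions plus the full 10-ion
reporter fingerprint, uniform noise peaks, and linear-peptide-only or
pure-noise negative controls. Every generated spectrum has exactly one
truth-table row, and everything is deterministic under the mandatory seed.

Fragment and precursor m/z values receive a small ppm jitter emulating
instrument calibration error; the diagnostic fingerprint ions are planted
at their exact m/z (a centroided high-resolution peak sits well within
the scanner's 0.01 Da window, and planting them exactly keeps the
planted-positive truth unambiguous). Intensities are log-normal and
purely cosmetic: no downstream computation uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import MONOISOTOPIC_RESIDUE_MASSES, mz_from_mass
from .crosslink import (
    CrossLinkedPeptide,
    CSEIWDR_REPORTER,
    ReporterPeptide,
    reporter_diagnostic_ions,
    theoretical_fragments,
)
from .digestion import DigestPeptide, DigestionSettings, ProteinRecord, cys_peptides, write_fasta
from .spectra import Spectrum, write_mgf

__all__ = [
    "SimulationSettings",
    "generate_proteome",
    "sample_crosslinks",
    "plant_crosslink_spectra",
    "generate_linear_shotgun",
    "generate_noise_spectra",
    "simulate_dataset",
]

_RESIDUES = sorted(MONOISOTOPIC_RESIDUE_MASSES)

TRUTH_COLUMNS = [
    "title",
    "kind",
    "partner_sequence",
    "partner_accession",
    "linked_protein_position",
    "charge",
    "n_planted_fragments",
    "n_noise_peaks",
    "seed",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Generator defaults mirroring the study conditions.

    ``cys_frequency`` 0.0186 is the Arabidopsis proteome cysteine fraction;
    the charge distribution puts ~95% of cross-link precursors at >= 3+;
    ``mz_jitter_ppm`` = 5 keeps essentially all true peaks inside 20 ppm
    search windows. ``seed`` is mandatory.
    """

    seed: int
    n_proteins: int = 500
    protein_length_mean: float = 300.0
    protein_length_sd: float = 60.0
    protein_length_min: int = 60
    cys_frequency: float = 0.0186
    charge_probs: Tuple[Tuple[int, float], ...] = (
        (2, 0.05),
        (3, 0.50),
        (4, 0.30),
        (5, 0.10),
        (6, 0.05),
    )
    fragment_coverage: float = 0.9
    plant_fingerprint: bool = True
    noise_peaks: int = 50
    mz_jitter_ppm: float = 5.0
    noise_mz_range: Tuple[float, float] = (100.0, 1500.0)
    min_partner_len: int = 6
    max_partner_len: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.cys_frequency < 1:
            raise ValueError("cys_frequency must be in [0, 1)")
        if not 0 <= self.fragment_coverage <= 1:
            raise ValueError("fragment_coverage must be in [0, 1]")
        total = sum(p for _, p in self.charge_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("charge probabilities must sum to 1")


def _rng(settings: SimulationSettings, stream: int) -> np.random.Generator:
    return np.random.default_rng([settings.seed, stream])


def _residue_probs(settings: SimulationSettings) -> np.ndarray:
    probs = np.full(len(_RESIDUES), (1.0 - settings.cys_frequency) / (len(_RESIDUES) - 1))
    probs[_RESIDUES.index("C")] = settings.cys_frequency
    return probs


def _has_tryptic_cys_peptide(protein: ProteinRecord, settings: SimulationSettings) -> bool:
    digestion = DigestionSettings(
        max_missed=0,
        min_len=settings.min_partner_len,
        max_len=settings.max_partner_len,
    )
    try:
        return bool(cys_peptides([protein], digestion))
    except ValueError:
        return False


def generate_proteome(settings: SimulationSettings) -> List[ProteinRecord]:
    """Random protein database with a guaranteed tryptic Cys peptide each.

    Residues are drawn i.i.d. with the configured Cys frequency (the other
    19 residues uniform); proteins lacking a fully tryptic Cys peptide of
    partner-compatible length are resampled up to a bounded number of
    attempts, after which generation fails (e.g. at cys_frequency = 0).
    """
    rng = _rng(settings, 0)
    probs = _residue_probs(settings)
    proteins: List[ProteinRecord] = []
    for i in range(settings.n_proteins):
        accession = f"SYN{i + 1:04d}"
        for _attempt in range(50):
            length = max(
                settings.protein_length_min,
                int(rng.normal(settings.protein_length_mean, settings.protein_length_sd)),
            )
            seq = "".join(rng.choice(_RESIDUES, size=length, p=probs))
            candidate = ProteinRecord(accession, f"{accession} synthetic protein", seq)
            if _has_tryptic_cys_peptide(candidate, settings):
                proteins.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not generate protein {accession} with a tryptic Cys peptide "
                f"(cys_frequency={settings.cys_frequency}); constraints infeasible?"
            )
    return proteins


def sample_crosslinks(
    database: Sequence[ProteinRecord],
    n_crosslinks: int,
    settings: SimulationSettings,
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
) -> List[Tuple[CrossLinkedPeptide, str, int]]:
    """Sample distinct partner peptides and pair each with the reporter.

    Returns ``(crosslink, accession, linked protein coordinate)`` triples.
    Partners are fully tryptic Cys peptides; when a peptide has several
    cysteines the linked one is chosen at random.
    """
    digestion = DigestionSettings(
        max_missed=0, min_len=settings.min_partner_len, max_len=settings.max_partner_len
    )
    candidates = cys_peptides(database, digestion)
    if len(candidates) < n_crosslinks:
        raise ValueError(
            f"database yields only {len(candidates)} candidate partners, "
            f"need {n_crosslinks}"
        )
    rng = _rng(settings, 1)
    chosen = rng.choice(len(candidates), size=n_crosslinks, replace=False)
    out = []
    for idx in chosen:
        pep = candidates[int(idx)]
        cys_positions = pep.cys_peptide_positions()
        linked = int(cys_positions[rng.integers(len(cys_positions))])
        clpep = CrossLinkedPeptide(
            reporter_sequence=reporter.sequence,
            partner_sequence=pep.sequence,
            reporter_cys_index=reporter.reactive_cys_index,
            partner_cys_index=linked,
        )
        out.append((clpep, pep.parent_accession, pep.start + linked - 1))
    return out


def _jitter(values: np.ndarray, ppm_sd: float, rng: np.random.Generator) -> np.ndarray:
    if ppm_sd <= 0:
        return values
    return values * (1.0 + rng.normal(0.0, ppm_sd * 1e-6, size=len(values)))


def _sample_charge(settings: SimulationSettings, rng: np.random.Generator) -> int:
    charges = [z for z, _ in settings.charge_probs]
    probs = [p for _, p in settings.charge_probs]
    return int(rng.choice(charges, p=probs))


def _noise_peaks(settings: SimulationSettings, rng: np.random.Generator) -> np.ndarray:
    lo, hi = settings.noise_mz_range
    return rng.uniform(lo, hi, size=settings.noise_peaks)


def _intensities(n: int, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(10.0, 1.0, size=n))


def plant_crosslink_spectra(
    crosslinks: Sequence[Tuple[CrossLinkedPeptide, str, int]],
    settings: SimulationSettings,
    title_prefix: str = "xl",
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """MS/MS spectra of cross-links with known composition.

    Per spectrum: the precursor sits at the true cross-link m/z (2-6+) with
    ppm jitter; each singly charged b/y fragment of either chain is planted
    with probability ``fragment_coverage`` (jittered); the full diagnostic
    fingerprint is planted exactly when ``plant_fingerprint``; noise peaks
    are uniform over the noise m/z range.
    """
    rng = _rng(settings, 2)
    fingerprint = reporter_diagnostic_ions()
    spectra: List[Spectrum] = []
    truth_rows = []
    for i, (clpep, accession, protein_pos) in enumerate(crosslinks):
        z = _sample_charge(settings, rng)
        precursor = mz_from_mass(clpep.neutral_mass(), z)
        precursor *= 1.0 + rng.normal(0.0, settings.mz_jitter_ppm * 1e-6)
        frags = [
            f
            for f in theoretical_fragments(clpep, max_charge=1, include_triplet=False)
            if f.neutral_loss is None
        ]
        keep = rng.random(len(frags)) <= settings.fragment_coverage
        planted = np.array([f.mz for f, k in zip(frags, keep) if k])
        planted = _jitter(planted, settings.mz_jitter_ppm, rng)
        parts = [planted]
        if settings.plant_fingerprint:
            parts.append(np.array(fingerprint.mzs()))
        noise = _noise_peaks(settings, rng)
        parts.append(noise)
        mz = np.concatenate(parts)
        title = f"{title_prefix}|{i}|{clpep.partner_sequence}"
        spectra.append(
            Spectrum(
                title=title,
                precursor_mz=precursor,
                precursor_charge=z,
                mz=mz,
                intensity=_intensities(len(mz), rng),
            )
        )
        n_planted = int(keep.sum()) + (len(fingerprint) if settings.plant_fingerprint else 0)
        truth_rows.append(
            {
                "title": title,
                "kind": "crosslink",
                "partner_sequence": clpep.partner_sequence,
                "partner_accession": accession,
                "linked_protein_position": protein_pos,
                "charge": z,
                "n_planted_fragments": n_planted,
                "n_noise_peaks": settings.noise_peaks,
                "seed": settings.seed,
            }
        )
    return spectra, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def generate_linear_shotgun(
    database: Sequence[ProteinRecord],
    n_spectra: int,
    settings: SimulationSettings,
    title_prefix: str = "lin",
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """Linear-peptide-only spectra: the negative control for the scanner.

    Random fully tryptic peptides (any composition) fragmented into their
    singly charged b/y ions at the configured coverage, plus noise. No
    reporter chain, hence no full fingerprint is ever planted.
    """
    if not database:
        raise ValueError("empty protein database")
    digestion = DigestionSettings(max_missed=0, min_len=6, max_len=30)
    peptides: List[DigestPeptide] = []
    from .digestion import digest

    for protein in database:
        peptides.extend(
            digest(protein, max_missed=0, min_len=digestion.min_len, max_len=digestion.max_len)
        )
    if not peptides:
        raise ValueError("database yields no linear peptides")
    rng = _rng(settings, 3)
    from .chem import PROTON, WATER, peptide_neutral_mass

    spectra: List[Spectrum] = []
    truth_rows = []
    for i in range(n_spectra):
        pep = peptides[int(rng.integers(len(peptides)))]
        z = int(rng.choice([2, 3], p=[0.7, 0.3]))
        mass = peptide_neutral_mass(pep.sequence)
        precursor = mz_from_mass(mass, z) * (1.0 + rng.normal(0.0, settings.mz_jitter_ppm * 1e-6))
        prefix = 0.0
        frag_mzs = []
        for j, res in enumerate(pep.sequence[:-1], start=1):
            prefix += peptide_neutral_mass(res) - WATER
            frag_mzs.append(prefix + PROTON)  # b ion
            frag_mzs.append(mass - prefix + PROTON)  # y ion (y_{n-j})
        frag_arr = np.array(frag_mzs)
        keep = rng.random(len(frag_arr)) <= settings.fragment_coverage
        planted = _jitter(frag_arr[keep], settings.mz_jitter_ppm, rng)
        noise = _noise_peaks(settings, rng)
        mz = np.concatenate([planted, noise])
        title = f"{title_prefix}|{i}|{pep.sequence}"
        spectra.append(
            Spectrum(
                title=title,
                precursor_mz=precursor,
                precursor_charge=z,
                mz=mz,
                intensity=_intensities(len(mz), rng),
            )
        )
        truth_rows.append(
            {
                "title": title,
                "kind": "linear",
                "partner_sequence": pep.sequence,
                "partner_accession": pep.parent_accession,
                "linked_protein_position": -1,
                "charge": z,
                "n_planted_fragments": int(keep.sum()),
                "n_noise_peaks": settings.noise_peaks,
                "seed": settings.seed,
            }
        )
    return spectra, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def generate_noise_spectra(
    n_spectra: int,
    settings: SimulationSettings,
    title_prefix: str = "noise",
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """Pure-noise spectra with random precursors (search-specificity control)."""
    rng = _rng(settings, 4)
    spectra: List[Spectrum] = []
    truth_rows = []
    for i in range(n_spectra):
        z = _sample_charge(settings, rng)
        precursor = float(rng.uniform(400.0, 1300.0))
        mz = _noise_peaks(settings, rng)
        title = f"{title_prefix}|{i}"
        spectra.append(
            Spectrum(
                title=title,
                precursor_mz=precursor,
                precursor_charge=z,
                mz=mz,
                intensity=_intensities(len(mz), rng),
            )
        )
        truth_rows.append(
            {
                "title": title,
                "kind": "noise",
                "partner_sequence": "",
                "partner_accession": "",
                "linked_protein_position": -1,
                "charge": z,
                "n_planted_fragments": 0,
                "n_noise_peaks": settings.noise_peaks,
                "seed": settings.seed,
            }
        )
    return spectra, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


@dataclass
class SimulatedDataset:
    """A complete synthetic experiment with its ground truth."""

    database: List[ProteinRecord]
    spectra: List[Spectrum]
    truth: pd.DataFrame


def simulate_dataset(
    settings: SimulationSettings,
    n_crosslinks: int = 300,
    n_linear: int = 0,
    n_noise: int = 300,
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
) -> SimulatedDataset:
    """Generate a proteome plus cross-link / linear / noise spectra."""
    database = generate_proteome(settings)
    crosslinks = sample_crosslinks(database, n_crosslinks, settings, reporter)
    spectra, truth = plant_crosslink_spectra(crosslinks, settings)
    frames = [truth]
    if n_linear:
        lin_spectra, lin_truth = generate_linear_shotgun(database, n_linear, settings)
        spectra += lin_spectra
        frames.append(lin_truth)
    if n_noise:
        noise_spectra, noise_truth = generate_noise_spectra(n_noise, settings)
        spectra += noise_spectra
        frames.append(noise_truth)
    return SimulatedDataset(
        database=database,
        spectra=spectra,
        truth=pd.concat(frames, ignore_index=True),
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Dict[str, Path]:
    """Write FASTA, MGF and truth TSV for a simulated dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "proteome.fasta"
    mgf = out / "spectra.mgf"
    truth = out / "truth.tsv"
    write_fasta(dataset.database, fasta)
    write_mgf(dataset.spectra, mgf)
    dataset.truth.to_csv(truth, sep="\t", index=False)
    return {"fasta": fasta, "mgf": mgf, "truth": truth}
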