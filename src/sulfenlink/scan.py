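"""Fingerprint scanning: count reporter diagnostic ions per MS/MS spectrum.

The scanner answers one question per spectrum: how many of the reporter's
characteristic ions are present as peaks within an absolute m/z tolerance
(default 0.01 Da), irrespective of intensity? Spectra carrying the full
fingerprint are strong cross-link candidates, but the scanner is
identification-free by design: naming the partner peptide is the search
engine's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .crosslink import Fingerprint, reporter_diagnostic_ions
from .spectra import Spectrum, Tolerance, match_peaks, read_mgf

__all__ = [
    "FingerprintResult",
    "scan_spectrum",
    "scan_spectra",
    "scan_file",
    "expected_false_full_rate",
    "peak_occurrence_histogram",
]


@dataclass(frozen=True)
class FingerprintResult:
    """Per-spectrum scan outcome."""

    spectrum_title: str
    ions_matched: int
    matched_labels: Tuple[str, ...]
    full_fingerprint: bool


def scan_spectrum(spectrum: Spectrum, fingerprint: Fingerprint | None = None) -> FingerprintResult:
    """Count fingerprint ions present in one spectrum (intensity ignored)."""
    if fingerprint is None:
        fingerprint = reporter_diagnostic_ions()
    if len(fingerprint) == 0:
        raise ValueError("empty fingerprint")
    tol = Tolerance(fingerprint.tolerance_da, "da")
    matches = match_peaks(spectrum, fingerprint.mzs(), tol)
    matched_targets = {m.target_mz for m in matches}
    labels = tuple(
        label for label, mz in fingerprint.entries if mz in matched_targets
    )
    return FingerprintResult(
        spectrum_title=spectrum.title,
        ions_matched=len(labels),
        matched_labels=labels,
        full_fingerprint=len(labels) == len(fingerprint),
    )


def scan_spectra(
    spectra: Iterable[Spectrum],
    fingerprint: Fingerprint | None = None,
    min_ions: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Scan spectra; return rows with >= ``min_ions`` matches and a summary.

    The summary counts total spectra, spectra at each match count, and
    full-fingerprint spectra regardless of the reporting cutoff.
    """
    if fingerprint is None:
        fingerprint = reporter_diagnostic_ions()
    if not 0 <= min_ions <= len(fingerprint):
        raise ValueError(
            f"min_ions must be in 0..{len(fingerprint)}, got {min_ions}"
        )
    rows = []
    counts = {k: 0 for k in range(len(fingerprint) + 1)}
    total = 0
    full = 0
    for spectrum in spectra:
        res = scan_spectrum(spectrum, fingerprint)
        total += 1
        counts[res.ions_matched] += 1
        full += res.full_fingerprint
        if res.ions_matched >= min_ions:
            rows.append(
                {
                    "title": res.spectrum_title,
                    "ions_matched": res.ions_matched,
                    "matched_labels": ";".join(res.matched_labels),
                    "full_fingerprint": res.full_fingerprint,
                }
            )
    table = pd.DataFrame(
        rows, columns=["title", "ions_matched", "matched_labels", "full_fingerprint"]
    )
    summary = {"total_spectra": total, "full_fingerprint": full}
    summary.update({f"ions_{k}": v for k, v in counts.items()})
    return table, summary


def scan_file(
    mgf_path: str | Path,
    fingerprint: Fingerprint | None = None,
    min_ions: int = 8,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Scan every spectrum of an MGF file (default reporting cutoff 8/10)."""
    return scan_spectra(read_mgf(mgf_path), fingerprint, min_ions=min_ions)


def expected_false_full_rate(
    n_peaks: int,
    fingerprint: Fingerprint | None = None,
    mz_range: Tuple[float, float] = (100.0, 1500.0),
) -> float:
    """Probability that uniform random peaks fake a full fingerprint.

    For peaks i.i.d. uniform on ``mz_range``, each fingerprint ion is hit
    with probability 1 - (1 - 2*tol/range)^n; the full-fingerprint rate is
    the product over ions (independent to excellent approximation since the
    ions are separated by > 2*tol).
    """
    if fingerprint is None:
        fingerprint = reporter_diagnostic_ions()
    lo, hi = mz_range
    span = hi - lo
    p_single = 1.0 - (1.0 - 2.0 * fingerprint.tolerance_da / span) ** n_peaks
    return float(p_single ** len(fingerprint))


def peak_occurrence_histogram(
    spectra: Iterable[Spectrum],
    bin_width: float = 0.001,
    mz_range: Tuple[float, float] = (100.0, 1500.0),
) -> pd.Series:
    """Occurrence counts of peaks on a fixed m/z grid across spectra.

    Counts, per bin, the number of spectra containing at least one peak in
    that bin — the de novo route to discovering consistent diagnostic ions
    from a collection of confidently matched spectra. Only non-empty bins
    are returned, indexed by bin lower edge.
    """
    lo, hi = mz_range
    n_bins = int(np.ceil((hi - lo) / bin_width))
    totals: Dict[int, int] = {}
    for spectrum in spectra:
        in_range = spectrum.mz[(spectrum.mz >= lo) & (spectrum.mz < hi)]
        bins = np.unique(((in_range - lo) / bin_width).astype(int))
        for b in bins:
            totals[b] = totals.get(b, 0) + 1
    if not totals:
        return pd.Series(dtype=int)
    keys = sorted(totals)
    return pd.Series(
        [totals[k] for k in keys],
        index=[lo + k * bin_width for k in keys],
        dtype=int,
    )
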