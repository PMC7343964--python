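"""MGF reading/writing and tolerance-based peak matching.

Spectra are held as sorted numpy peak arrays. MGF parsing is delegated to
pyteomics; this module adds validation (per-block errors for missing
precursor information) and the peak-matching primitive shared by the
fingerprint scanner (absolute Da tolerance) and the search engine (ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "Tolerance",
    "PeakMatch",
    "read_mgf",
    "write_mgf",
    "match_peaks",
    "count_matched",
]


@dataclass(frozen=True)
class Tolerance:
    """A matching tolerance, either absolute (``"da"``) or relative (``"ppm"``)."""

    value: float
    unit: str = "da"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {self.unit!r}")

    def window(self, mz: float) -> float:
        """Half-width in Da of the acceptance window at a given m/z."""
        return self.value if self.unit == "da" else abs(mz) * self.value * 1e-6


@dataclass
class Spectrum:
    """One MS/MS record: precursor, optional charge/RT, sorted peak list."""

    title: str
    precursor_mz: float
    precursor_charge: Optional[int] = None
    retention_time: Optional[float] = None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.title!r}: precursor m/z must be positive")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"spectrum {self.title!r}: peak arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeakMatch:
    """An observed peak explaining a target m/z within tolerance."""

    target_mz: float
    observed_mz: float
    delta_da: float
    delta_ppm: float
    intensity: float


def read_mgf(path: str | Path) -> List[Spectrum]:
    """Read an MGF file into a list of spectra.

    ``PEPMASS`` (first token) is the precursor m/z; ``CHARGE`` like ``3+``
    becomes +3; zero-intensity peaks are retained. A block without PEPMASS
    raises with the 1-based block index.
    """
    spectra: List[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"MGF block {i} in {path}: missing PEPMASS")
            charge = None
            raw_charge = params.get("charge")
            if raw_charge:
                charge = int(raw_charge[0])
            rt = params.get("rtinseconds")
            spectra.append(
                Spectrum(
                    title=str(params.get("title", f"spectrum_{i}")),
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    retention_time=float(rt) if rt is not None else None,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with TITLE/PEPMASS/CHARGE/RTINSECONDS headers.

    Output is plain text with fixed 6-decimal formatting, so identical
    inputs yield byte-identical files.
    """
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


def match_peaks(
    spectrum: Spectrum, targets: Sequence[float], tolerance: Tolerance
) -> List[PeakMatch]:
    """For each target m/z, the nearest observed peak within tolerance.

    Matching is per target: one observed peak may satisfy several targets
    (occurrence counting, not assignment). Ties at equal |delta| are broken
    toward the higher-intensity peak. Intensity is recorded but plays no
    role in whether a peak matches.
    """
    if len(targets) == 0:
        raise ValueError("no target m/z values supplied")
    out: List[PeakMatch] = []
    mz = spectrum.mz
    if len(mz) == 0:
        return out
    idx = np.searchsorted(mz, targets)
    for t, j in zip(targets, idx):
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(mz):
                delta = mz[k] - t
                if abs(delta) <= tolerance.window(t):
                    cand = (abs(delta), -spectrum.intensity[k], k)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            k = best[2]
            out.append(
                PeakMatch(
                    target_mz=float(t),
                    observed_mz=float(mz[k]),
                    delta_da=float(mz[k] - t),
                    delta_ppm=float((mz[k] - t) / t * 1e6),
                    intensity=float(spectrum.intensity[k]),
                )
            )
    return out


def count_matched(spectrum: Spectrum, targets: Sequence[float], tolerance: Tolerance) -> int:
    """Number of targets with at least one peak within tolerance."""
    return len(match_peaks(spectrum, targets, tolerance))
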