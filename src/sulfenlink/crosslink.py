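"""Disulfide cross-link model: precursor arithmetic, fragments, fingerprint.

A cross-linked (CL) peptide is two tryptic chains joined by a disulfide
between two cysteines; its neutral mass is the sum of the chain masses
minus two hydrogens. On HCD fragmentation, b/y ions of either chain that
contain the linked cysteine carry the *other* chain as a constant mass
offset, while the disulfide bond itself can cleave to yield a diagnostic
triplet of reporter-chain precursor species: the thiol (MH+), the
persulfide (MH+ + S, homolytic S-S cleavage leaving both sulfurs on the
reporter) and the dehydroalanine form (MH+ - SH2, both sulfurs lost).

The default fingerprint of the CSEIWDR reporter is the 10-ion set
{y2..y6, y2*-NH3, y3*-NH3, MH+, MH+ +S, MH+ -SH2}. y1 is excluded: it is
the C-terminal Arg immonium-free y ion shared with every Arg-terminated
tryptic peptide and carries no reporter specificity. The "MH+ - 2H"
species (the intact-disulfide precursor stripped of the partner) can be
appended as an optional eleventh ion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .chem import (
    AMMONIA,
    DISULFIDE_DELTA,
    HYDROGEN,
    HYDROGEN_SULFIDE,
    PROTON,
    SULFUR,
    WATER,
    AppliedMod,
    CARBAMIDOMETHYL,
    mz_from_mass,
    peptide_neutral_mass,
)

__all__ = [
    "ReporterPeptide",
    "CSEIWDR_REPORTER",
    "CrossLinkedPeptide",
    "FragmentIon",
    "Fingerprint",
    "crosslink_precursor_mass",
    "reporter_diagnostic_ions",
    "theoretical_fragments",
]


@dataclass(frozen=True)
class ReporterPeptide:
    """The fixed reporter chain anchoring every cross-link of interest.

    ``reactive_cys_index`` is the 1-based position of the single reactive
    cysteine within the peptide; ``protein_context_residue`` its 1-based
    coordinate in the source protein (598 for the YAP1C probe).
    """

    sequence: str
    reactive_cys_index: int = 1
    protein_context_residue: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sequence.count("C") != 1:
            raise ValueError(
                f"reporter {self.sequence!r} must contain exactly one Cys"
            )
        if self.sequence[self.reactive_cys_index - 1] != "C":
            raise ValueError(
                f"reporter {self.sequence!r}: no Cys at index {self.reactive_cys_index}"
            )

    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self.sequence)


#: The YAP1C probe's tryptic reporter peptide containing redox-active Cys598.
CSEIWDR_REPORTER = ReporterPeptide("CSEIWDR", reactive_cys_index=1, protein_context_residue=598)


@dataclass(frozen=True)
class CrossLinkedPeptide:
    """An ordered (reporter chain, partner chain) disulfide pair.

    Modifications are per chain; carbamidomethyl on a linked cysteine is
    rejected because an alkylated thiol cannot be in a disulfide.
    """

    reporter_sequence: str
    partner_sequence: str
    reporter_cys_index: int
    partner_cys_index: int
    reporter_mods: Tuple[AppliedMod, ...] = ()
    partner_mods: Tuple[AppliedMod, ...] = ()

    def __post_init__(self) -> None:
        for name, seq, idx, mods in (
            ("reporter", self.reporter_sequence, self.reporter_cys_index, self.reporter_mods),
            ("partner", self.partner_sequence, self.partner_cys_index, self.partner_mods),
        ):
            if not 1 <= idx <= len(seq) or seq[idx - 1] != "C":
                raise ValueError(f"{name} chain {seq!r}: linked residue {idx} is not Cys")
            for mod, pos in mods:
                if pos == idx and mod.name == CARBAMIDOMETHYL.name:
                    raise ValueError(
                        f"{name} chain {seq!r}: carbamidomethyl on the linked Cys {idx}"
                    )

    def reporter_chain_mass(self) -> float:
        return peptide_neutral_mass(self.reporter_sequence, self.reporter_mods)

    def partner_chain_mass(self) -> float:
        return peptide_neutral_mass(self.partner_sequence, self.partner_mods)

    def neutral_mass(self) -> float:
        """Sum of chain masses minus two hydrogens (the disulfide bond)."""
        return self.reporter_chain_mass() + self.partner_chain_mass() + DISULFIDE_DELTA

    def is_self_link(self) -> bool:
        """True for reporter x reporter (inter-probe self-trapping) pairs."""
        return self.partner_sequence == self.reporter_sequence


def crosslink_precursor_mass(
    reporter_sequence: str,
    partner_sequence: str,
    reporter_mods: Sequence[AppliedMod] = (),
    partner_mods: Sequence[AppliedMod] = (),
) -> float:
    """Neutral mass of a disulfide cross-link: mass(A) + mass(B) - 2H.

    Both chains must contain a cysteine available for the bond.
    """
    for seq in (reporter_sequence, partner_sequence):
        if "C" not in seq:
            raise ValueError(f"chain {seq!r} has no Cys to cross-link")
    return (
        peptide_neutral_mass(reporter_sequence, reporter_mods)
        + peptide_neutral_mass(partner_sequence, partner_mods)
        + DISULFIDE_DELTA
    )


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: chain, series, index, losses, charge, m/z."""

    chain: str  # "reporter" | "partner"
    series: str  # "b" | "y" | "precursor"
    index: int
    charge: int
    mz: float
    neutral_mass: float
    neutral_loss: Optional[str] = None  # None | "NH3" | "SH2"
    sulfur_gain: bool = False
    carries_partner: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.neutral_loss is not None and self.sulfur_gain:
            raise ValueError("neutral loss and sulfur gain are mutually exclusive")


@dataclass(frozen=True)
class Fingerprint:
    """An ordered diagnostic-ion list with its matching tolerance."""

    entries: Tuple[Tuple[str, float], ...]
    tolerance_da: float = 0.01

    def __post_init__(self) -> None:
        mzs = [mz for _, mz in self.entries]
        for i, a in enumerate(mzs):
            for b in mzs[i + 1 :]:
                if abs(a - b) <= 2 * self.tolerance_da:
                    raise ValueError(
                        f"fingerprint ions at {a:.4f} and {b:.4f} are closer than "
                        f"2x tolerance ({self.tolerance_da} Da)"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> Tuple[str, ...]:
        return tuple(label for label, _ in self.entries)

    def mzs(self) -> Tuple[float, ...]:
        return tuple(mz for _, mz in self.entries)


def _y_ion_mz(seq: str, length: int, loss: float = 0.0) -> float:
    neutral = peptide_neutral_mass(seq[-length:]) - loss
    return neutral + PROTON


def reporter_diagnostic_ions(
    reporter: ReporterPeptide = CSEIWDR_REPORTER,
    tolerance_da: float = 0.01,
    include_minus_2h: bool = False,
) -> Fingerprint:
    """The reporter's diagnostic-ion fingerprint (10 ions by default).

    Composition: singly charged y2..y6 of the reporter chain, y2 and y3
    with ammonia loss (y2*, y3*), and the disulfide-cleavage precursor
    triplet (thiol MH+, persulfide MH+ +S, dehydroalanine MH+ -SH2). With
    ``include_minus_2h`` the intact-disulfide "MH+ -2H" species is appended
    as an eleventh ion.
    """
    seq = reporter.sequence
    n = len(seq)
    entries: List[Tuple[str, float]] = []
    for k in range(2, min(6, n - 1) + 1):
        entries.append((f"y{k}", _y_ion_mz(seq, k)))
    for k in (2, 3):
        if k <= n - 1:
            entries.append((f"y{k}*", _y_ion_mz(seq, k, loss=AMMONIA)))
    mh = peptide_neutral_mass(seq) + PROTON
    entries.append(("MH+", mh))
    entries.append(("MH+S", mh + SULFUR))
    entries.append(("MH-SH2", mh - HYDROGEN_SULFIDE))
    if include_minus_2h:
        entries.append(("MH-2H", mh - 2 * HYDROGEN))
    return Fingerprint(tuple(entries), tolerance_da=tolerance_da)


def _chain_fragments(
    seq: str,
    mods: Sequence[AppliedMod],
    linked_cys: int,
    partner_offset: float,
    chain_name: str,
    max_charge: int,
    nh3_loss_y: Sequence[int],
) -> List[FragmentIon]:
    n = len(seq)
    res_masses = [peptide_neutral_mass(c) - WATER for c in seq]
    for mod, pos in mods:
        res_masses[max(pos, 1) - 1] += mod.delta_mass
    prefix = [0.0]
    for m in res_masses:
        prefix.append(prefix[-1] + m)

    out: List[FragmentIon] = []
    for i in range(1, n):  # b1..b(n-1), y1..y(n-1)
        b_neutral = prefix[i]
        b_offset = linked_cys <= i
        if b_offset:
            b_neutral += partner_offset
        y_len = n - i
        y_neutral = prefix[n] - prefix[i] + WATER
        y_offset = linked_cys > i
        if y_offset:
            y_neutral += partner_offset
        for z in range(1, max_charge + 1):
            out.append(
                FragmentIon(
                    chain=chain_name,
                    series="b",
                    index=i,
                    charge=z,
                    mz=(b_neutral + z * PROTON) / z,
                    neutral_mass=b_neutral,
                    carries_partner=b_offset,
                    label=f"{chain_name}:b{i}^{z}",
                )
            )
            out.append(
                FragmentIon(
                    chain=chain_name,
                    series="y",
                    index=y_len,
                    charge=z,
                    mz=(y_neutral + z * PROTON) / z,
                    neutral_mass=y_neutral,
                    carries_partner=y_offset,
                    label=f"{chain_name}:y{y_len}^{z}",
                )
            )
            if y_len in nh3_loss_y and not y_offset:
                out.append(
                    FragmentIon(
                        chain=chain_name,
                        series="y",
                        index=y_len,
                        charge=z,
                        mz=(y_neutral - AMMONIA + z * PROTON) / z,
                        neutral_mass=y_neutral - AMMONIA,
                        neutral_loss="NH3",
                        carries_partner=False,
                        label=f"{chain_name}:y{y_len}*^{z}",
                    )
                )
    return out


def theoretical_fragments(
    clpep: CrossLinkedPeptide,
    max_charge: int = 1,
    include_triplet: bool = True,
    nh3_losses_all_chains: bool = False,
) -> List[FragmentIon]:
    """All theoretical b/y fragments of a cross-link plus the triplet.

    Fragments containing a linked cysteine carry the other chain as a mass
    offset (partner neutral mass minus two hydrogens). NH3 losses are
    generated for reporter y2/y3 only unless ``nh3_losses_all_chains``.
    Ordering is deterministic: chain, series, index, charge, loss.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    rep_offset = clpep.partner_chain_mass() - 2 * HYDROGEN
    par_offset = clpep.reporter_chain_mass() - 2 * HYDROGEN
    frags = _chain_fragments(
        clpep.reporter_sequence,
        clpep.reporter_mods,
        clpep.reporter_cys_index,
        rep_offset,
        "reporter",
        max_charge,
        nh3_loss_y=(2, 3),
    )
    frags += _chain_fragments(
        clpep.partner_sequence,
        clpep.partner_mods,
        clpep.partner_cys_index,
        par_offset,
        "partner",
        max_charge,
        nh3_loss_y=(2, 3) if nh3_losses_all_chains else (),
    )
    if include_triplet:
        mh_neutral = peptide_neutral_mass(clpep.reporter_sequence, clpep.reporter_mods)
        mh = mh_neutral + PROTON
        frags.append(
            FragmentIon(
                chain="reporter",
                series="precursor",
                index=0,
                charge=1,
                mz=mh,
                neutral_mass=mh_neutral,
                label="reporter:MH+",
            )
        )
        frags.append(
            FragmentIon(
                chain="reporter",
                series="precursor",
                index=0,
                charge=1,
                mz=mh + SULFUR,
                neutral_mass=mh_neutral + SULFUR,
                sulfur_gain=True,
                label="reporter:MH+S",
            )
        )
        frags.append(
            FragmentIon(
                chain="reporter",
                series="precursor",
                index=0,
                charge=1,
                mz=mh - HYDROGEN_SULFIDE,
                neutral_mass=mh_neutral - HYDROGEN_SULFIDE,
                neutral_loss="SH2",
                label="reporter:MH-SH2",
            )
        )
    frags.sort(key=lambda f: (f.chain, f.series, f.index, f.charge, f.neutral_loss or "", f.sulfur_gain))
    return frags
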