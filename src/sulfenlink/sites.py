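"""Site assembly: from cross-link PSMs to non-redundant sulfenylated sites.

Trypsin missed cleavages make several cross-linked peptides report the
same protein cysteine; this module collapses that redundancy (grouping by
the (accession, 1-based Cys coordinate) site key, with the peptide
matching the fewest proteins as representative), filters sites on minimum
PSM support pooled across samples, resolves shared-peptide ambiguity with
linear-peptide protein-level evidence, computes condition overlaps, and
tests domain overrepresentation of sulfenylated cysteines with a
hypergeometric test and Benjamini-Hochberg correction.

Peptide-to-protein matching is exact-string: Leu and Ile are distinct
letters here even though they are isobaric for mass purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .digestion import ProteinRecord

__all__ = [
    "CLPeptideObservation",
    "SiteAssignment",
    "LinearEvidence",
    "map_peptide_to_sites",
    "collapse_redundant",
    "resolve_ambiguity",
    "filter_min_psms",
    "condition_overlap",
    "domain_enrichment",
]


@dataclass(frozen=True)
class CLPeptideObservation:
    """An identified cross-linked partner peptide with its PSM support.

    ``linked_cys_index`` is 1-based within the peptide; ``psm_counts`` maps
    condition name to PSM count.
    """

    sequence: str
    linked_cys_index: int
    psm_counts: Mapping[str, int] = field(default_factory=dict)

    def total_psms(self) -> int:
        return sum(self.psm_counts.values())


@dataclass
class SiteAssignment:
    """A non-redundant sulfenylated cysteine site."""

    protein_accession: str
    cys_position: int
    representative_peptide: str
    supporting_peptides: List[str]
    psm_count_per_condition: Dict[str, int]
    ambiguous_proteins: List[str] = field(default_factory=list)
    flag: str = ""

    def total_psms(self) -> int:
        return sum(self.psm_count_per_condition.values())


#: accession -> (n_linear_peptides, n_psms) from the protein-level run.
LinearEvidence = Mapping[str, Tuple[int, int]]


def map_peptide_to_sites(
    peptide_sequence: str,
    linked_cys_index_in_peptide: int,
    database: Sequence[ProteinRecord],
) -> List[Tuple[str, int]]:
    """All (accession, 1-based Cys coordinate) occurrences of a peptide.

    Every occurrence in every protein contributes one site, including
    repeated occurrences within a single protein. Raises if the peptide is
    absent from the database or the linked index is not a Cys.
    """
    if not 1 <= linked_cys_index_in_peptide <= len(peptide_sequence):
        raise ValueError("linked Cys index outside the peptide")
    if peptide_sequence[linked_cys_index_in_peptide - 1] != "C":
        raise ValueError(
            f"residue {linked_cys_index_in_peptide} of {peptide_sequence!r} is not Cys"
        )
    sites: List[Tuple[str, int]] = []
    for protein in database:
        start = protein.sequence.find(peptide_sequence)
        while start != -1:
            sites.append((protein.accession, start + linked_cys_index_in_peptide))
            start = protein.sequence.find(peptide_sequence, start + 1)
    if not sites:
        raise ValueError(f"peptide {peptide_sequence!r} not found in the database")
    return sites


def collapse_redundant(
    observations: Sequence[CLPeptideObservation],
    database: Sequence[ProteinRecord],
) -> List[SiteAssignment]:
    """Group peptides reporting the same protein site into one assignment.

    Peptides sharing an (accession, Cys coordinate) site are grouped; the
    representative is the peptide matching the fewest proteins, ties broken
    by shorter sequence then lexicographic order; PSM counts are summed.
    ``ambiguous_proteins`` lists all accessions the representative matches
    when more than one (empty otherwise). Order-independent and idempotent.
    """
    site_map: Dict[Tuple[str, int], List[CLPeptideObservation]] = {}
    peptide_sites: Dict[Tuple[str, int], List[Tuple[str, int]]] = {}
    for obs in observations:
        key = (obs.sequence, obs.linked_cys_index)
        if key not in peptide_sites:
            peptide_sites[key] = map_peptide_to_sites(obs.sequence, obs.linked_cys_index, database)
        for site in peptide_sites[key]:
            site_map.setdefault(site, []).append(obs)

    def n_proteins(obs: CLPeptideObservation) -> int:
        return len({acc for acc, _ in peptide_sites[(obs.sequence, obs.linked_cys_index)]})

    assignments: List[SiteAssignment] = []
    for (accession, pos), members in sorted(site_map.items()):
        # A peptide observed twice in the input contributes its counts once
        # per distinct (sequence, linked index) identity.
        unique: Dict[Tuple[str, int], CLPeptideObservation] = {}
        pooled: Dict[Tuple[str, int], Dict[str, int]] = {}
        for obs in members:
            key = (obs.sequence, obs.linked_cys_index)
            unique[key] = obs
            counts = pooled.setdefault(key, {})
            for cond, n in obs.psm_counts.items():
                counts[cond] = counts.get(cond, 0) + n
        rep = min(
            unique.values(),
            key=lambda o: (n_proteins(o), len(o.sequence), o.sequence),
        )
        totals: Dict[str, int] = {}
        for counts in pooled.values():
            for cond, n in counts.items():
                totals[cond] = totals.get(cond, 0) + n
        rep_accessions = sorted({acc for acc, _ in peptide_sites[(rep.sequence, rep.linked_cys_index)]})
        assignments.append(
            SiteAssignment(
                protein_accession=accession,
                cys_position=pos,
                representative_peptide=rep.sequence,
                supporting_peptides=sorted({s for s, _ in unique}),
                psm_count_per_condition=totals,
                ambiguous_proteins=rep_accessions if len(rep_accessions) > 1 else [],
            )
        )
    return assignments


def resolve_ambiguity(
    site_candidates: Sequence[str],
    linear_evidence: LinearEvidence,
) -> Tuple[List[str], str]:
    """Prefer the one candidate protein backed by linear-peptide evidence.

    If exactly one of >= 2 candidate accessions has linear peptides from
    the protein-level enrichment run, it is preferred and the flag is
    ``"resolved-by-protein-evidence"``; otherwise all candidates are kept
    with flag ``"unresolved"``.
    """
    if len(site_candidates) < 2:
        raise ValueError("ambiguity resolution needs >= 2 candidate proteins")
    with_evidence = [
        acc for acc in site_candidates if linear_evidence.get(acc, (0, 0))[0] > 0
    ]
    if len(with_evidence) == 1:
        return with_evidence, "resolved-by-protein-evidence"
    return list(site_candidates), "unresolved"


def filter_min_psms(
    sites: Sequence[SiteAssignment], min_psms: int = 2
) -> List[SiteAssignment]:
    """Keep sites whose PSM count pooled across all conditions >= min_psms."""
    return [s for s in sites if s.total_psms() >= min_psms]


def condition_overlap(site_sets: Mapping[str, Set]) -> Dict[FrozenSet[str], int]:
    """Exclusive-region (Venn) counts over per-condition site sets.

    Returns a map from each non-empty condition combination to the number
    of items found in exactly those conditions; the values sum to the size
    of the union.
    """
    if len(site_sets) < 2:
        raise ValueError("condition overlap needs >= 2 conditions")
    conditions = list(site_sets)
    universe = set().union(*site_sets.values())
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            regions[frozenset(combo)] = 0
    for item in universe:
        membership = frozenset(c for c in conditions if item in site_sets[c])
        regions[membership] += 1
    return regions


def domain_enrichment(
    sites: Sequence[Tuple[str, int]],
    background_cys: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of sulfenylated Cys in domains.

    ``background_cys`` needs columns ``accession``, ``cys_position``,
    ``domain_label``; a cysteine outside any domain may carry an empty or
    NaN label (those rows count toward the background universe only). For
    each domain: k = sulfenylated Cys in the domain, K = background Cys in
    the domain, n = all sulfenylated Cys, N = all background Cys; the
    upper-tail p-value is P[X >= k] for X ~ Hypergeom(N, K, n), corrected
    across domains with Benjamini-Hochberg.
    """
    required = {"accession", "cys_position", "domain_label"}
    missing = required - set(background_cys.columns)
    if missing:
        raise ValueError(f"background table lacks columns: {sorted(missing)}")
    bg_sites = set(zip(background_cys["accession"], background_cys["cys_position"]))
    offenders = sorted(set(sites) - bg_sites)
    if offenders:
        raise ValueError(f"sites absent from the background table: {offenders}")

    site_set = set(sites)
    N = len(bg_sites)
    n = len(site_set)
    labelled = background_cys.dropna(subset=["domain_label"])
    labelled = labelled[labelled["domain_label"] != ""]
    rows = []
    for domain, grp in labelled.groupby("domain_label"):
        domain_sites = set(zip(grp["accession"], grp["cys_position"]))
        K = len(domain_sites)
        k = len(domain_sites & site_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"domain_label": domain, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)}
        )
    table = pd.DataFrame(rows, columns=["domain_label", "k", "K", "n", "N", "p_value"])
    if len(table):
        table["fdr_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(["p_value", "domain_label"], ignore_index=True)
    else:
        table["fdr_bh"] = pd.Series(dtype=float)
    return table


def sites_to_table(sites: Sequence[SiteAssignment]) -> pd.DataFrame:
    """Flatten site assignments to a TSV-ready table."""
    rows = []
    for s in sites:
        row = {
            "accession": s.protein_accession,
            "cys_position": s.cys_position,
            "representative_peptide": s.representative_peptide,
            "supporting_peptides": ";".join(s.supporting_peptides),
            "total_psms": s.total_psms(),
            "ambiguous_proteins": ";".join(s.ambiguous_proteins),
            "flag": s.flag,
        }
        for cond, count in sorted(s.psm_count_per_condition.items()):
            row[f"psms_{cond}"] = count
        rows.append(row)
    return pd.DataFrame(rows)
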