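"""Site assembly: mapping, redundancy collapse, ambiguity, enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sulfenlink.digestion import ProteinRecord
from sulfenlink.sites import (
    CLPeptideObservation,
    collapse_redundant,
    condition_overlap,
    domain_enrichment,
    filter_min_psms,
    map_peptide_to_sites,
    resolve_ambiguity,
)


class TestMapPeptideToSites:
    def test_unique_peptide_single_site(self, tiny_database):
        assert map_peptide_to_sites("VIEYCK", 5, tiny_database) == [("TGT1", 9)]

    def test_shared_peptide_two_proteins(self, tiny_database):
        sites = map_peptide_to_sites("KLKECEK", 5, tiny_database)
        assert sorted(sites) == [("TGT2", 8), ("TGT3", 12)]

    def test_repeated_occurrence_within_one_protein(self):
        db = [ProteinRecord("P", "", "MKACDEFKRACDEFKGG")]
        sites = map_peptide_to_sites("ACDEFK", 2, db)
        assert sites == [("P", 4), ("P", 11)]

    def test_absent_peptide_rejected(self, tiny_database):
        with pytest.raises(ValueError, match="not found"):
            map_peptide_to_sites("CCCCCC", 1, tiny_database)

    def test_linked_index_must_be_cys(self, tiny_database):
        with pytest.raises(ValueError, match="not Cys"):
            map_peptide_to_sites("VIEYCK", 1, tiny_database)


class TestCollapseRedundant:
    def test_missed_cleavage_pair_collapses_to_one_site(self, tiny_database):
        obs = [
            CLPeptideObservation("CATITPDEGR", 1, {"ctrl": 3}),
            CLPeptideObservation("CATITPDEGRVTEFGLK", 1, {"h2o2": 2}),
        ]
        sites = collapse_redundant(obs, tiny_database)
        assert len(sites) == 1
        site = sites[0]
        assert (site.protein_accession, site.cys_position) == ("TGT4", 5)
        assert site.representative_peptide == "CATITPDEGR"  # tie -> shorter
        assert sorted(site.supporting_peptides) == [
            "CATITPDEGR",
            "CATITPDEGRVTEFGLK",
        ]
        assert site.psm_count_per_condition == {"ctrl": 3, "h2o2": 2}
        assert site.ambiguous_proteins == []

    def test_representative_prefers_fewest_proteins(self, tiny_database):
        # KLKECEK matches two proteins; a longer unique peptide at the same
        # TGT2 site must win the representative role.
        db = tiny_database
        obs = [
            CLPeptideObservation("KLKECEK", 5, {"ctrl": 1}),
            CLPeptideObservation("KLKECEKTTTR", 5, {"ctrl": 1}),
        ]
        sites = collapse_redundant(obs, db)
        by_site = {(s.protein_accession, s.cys_position): s for s in sites}
        tgt2 = by_site[("TGT2", 8)]
        assert tgt2.representative_peptide == "KLKECEKTTTR"
        assert tgt2.ambiguous_proteins == []
        tgt3 = by_site[("TGT3", 12)]
        assert tgt3.representative_peptide == "KLKECEK"
        assert sorted(tgt3.ambiguous_proteins) == ["TGT2", "TGT3"]

    def test_single_site_idempotent(self, tiny_database):
        obs = [CLPeptideObservation("VIEYCK", 5, {"ctrl": 2})]
        once = collapse_redundant(obs, tiny_database)
        assert len(once) == 1
        again = collapse_redundant(
            [
                CLPeptideObservation(
                    once[0].representative_peptide, 5, once[0].psm_count_per_condition
                )
            ],
            tiny_database,
        )
        assert [(s.protein_accession, s.cys_position) for s in again] == [
            (once[0].protein_accession, once[0].cys_position)
        ]

    def test_order_independent(self, tiny_database, rng):
        obs = [
            CLPeptideObservation("CATITPDEGR", 1, {"a": 1}),
            CLPeptideObservation("CATITPDEGRVTEFGLK", 1, {"b": 2}),
            CLPeptideObservation("KLKECEK", 5, {"a": 4}),
            CLPeptideObservation("VIEYCK", 5, {"b": 1}),
        ]
        ref = collapse_redundant(obs, tiny_database)
        perm = [obs[i] for i in rng.permutation(len(obs))]
        assert collapse_redundant(perm, tiny_database) == ref

    def test_group_count_equals_site_set_cardinality(self, rng):
        """Random fixtures: one output group per distinct protein site."""
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        db = [
            ProteinRecord(f"P{i}", "", "".join(rng.choice(residues, size=60)))
            for i in range(30)
        ]
        observations = []
        expected_sites = set()
        for protein in db:
            seq = protein.sequence
            for start in range(0, len(seq) - 8, 7):
                pep = seq[start : start + 8]
                if "C" not in pep:
                    continue
                linked = pep.index("C") + 1
                observations.append(CLPeptideObservation(pep, linked, {"x": 1}))
                for other in db:
                    pos = other.sequence.find(pep)
                    while pos != -1:
                        expected_sites.add((other.accession, pos + linked))
                        pos = other.sequence.find(pep, pos + 1)
        if not observations:
            pytest.skip("no Cys windows drawn")
        sites = collapse_redundant(observations, db)
        assert len(sites) == len(expected_sites)
        assert {(s.protein_accession, s.cys_position) for s in sites} == expected_sites

    def test_site_count_never_exceeds_unique_peptide_count(self, tiny_database):
        obs = [
            CLPeptideObservation("CATITPDEGR", 1, {"a": 1}),
            CLPeptideObservation("CATITPDEGRVTEFGLK", 1, {"a": 1}),
        ]
        sites = collapse_redundant(obs, tiny_database)
        assert len(sites) <= len(obs)


class TestResolveAmbiguity:
    def test_single_evidence_candidate_preferred(self):
        evidence = {"PP5": (23, 194), "PPI2": (0, 0)}
        chosen, flag = resolve_ambiguity(["PP5", "PPI2"], evidence)
        assert chosen == ["PP5"]
        assert flag == "resolved-by-protein-evidence"

    def test_both_with_evidence_unresolved(self):
        chosen, flag = resolve_ambiguity(
            ["A", "B"], {"A": (2, 5), "B": (1, 1)}
        )
        assert chosen == ["A", "B"] and flag == "unresolved"

    def test_neither_with_evidence_unresolved(self):
        chosen, flag = resolve_ambiguity(["A", "B"], {})
        assert chosen == ["A", "B"] and flag == "unresolved"

    def test_requires_at_least_two_candidates(self):
        with pytest.raises(ValueError):
            resolve_ambiguity(["A"], {})


class TestFilterMinPsms:
    def make_site(self, counts):
        from sulfenlink.sites import SiteAssignment

        return SiteAssignment("P", 1, "PEP", ["PEP"], counts)

    def test_single_psm_dropped_at_default(self):
        assert filter_min_psms([self.make_site({"a": 1})]) == []

    def test_counts_pool_across_conditions(self):
        kept = filter_min_psms([self.make_site({"a": 1, "b": 1})])
        assert len(kept) == 1

    def test_min_one_is_identity(self):
        sites = [self.make_site({"a": 1}), self.make_site({"b": 3})]
        assert filter_min_psms(sites, 1) == sites

    def test_monotone_in_threshold(self):
        sites = [self.make_site({"a": k}) for k in range(1, 6)]
        sizes = [len(filter_min_psms(sites, m)) for m in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)


class TestConditionOverlap:
    def test_two_set_venn(self):
        regions = condition_overlap({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions[frozenset({"A"})] == 1
        assert regions[frozenset({"B"})] == 1
        assert regions[frozenset({"A", "B"})] == 1

    def test_identical_sets_all_shared(self):
        regions = condition_overlap({"A": {1, 2}, "B": {1, 2}})
        assert regions[frozenset({"A", "B"})] == 2
        assert regions[frozenset({"A"})] == regions[frozenset({"B"})] == 0

    def test_counts_sum_to_union(self, rng):
        sets = {
            name: set(rng.integers(0, 50, size=rng.integers(5, 25)).tolist())
            for name in "ABC"
        }
        regions = condition_overlap(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))
        # brute-force membership enumeration
        for combo, count in regions.items():
            expected = sum(
                1
                for item in set().union(*sets.values())
                if {n for n in sets if item in sets[n]} == set(combo)
            )
            assert count == expected

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_overlap({"A": {1}})


def make_background(rows):
    return pd.DataFrame(rows, columns=["accession", "cys_position", "domain_label"])


class TestDomainEnrichment:
    def test_domain_covering_everything_not_enriched(self):
        bg = make_background([("P", i, "D") for i in range(1, 6)])
        sites = [("P", i) for i in range(1, 6)]
        table = domain_enrichment(sites, bg)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_domain_p_is_one(self):
        bg = make_background(
            [("P", 1, "D1"), ("P", 2, "D2"), ("P", 3, "D2"), ("P", 4, None)]
        )
        table = domain_enrichment([("P", 2)], bg).set_index("domain_label")
        assert table.loc["D1", "k"] == 0
        assert table.loc["D1", "p_value"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle(self):
        """Upper-tail p equals the exhaustive subset enumeration for N=12."""
        N, K, n = 12, 5, 6
        bg = make_background(
            [("P", i, "D" if i <= K else None) for i in range(1, N + 1)]
        )
        # sulfenylated set: n sites of which k are in the domain
        for k in range(0, min(K, n) + 1):
            in_domain = list(range(1, k + 1))
            outside = list(range(K + 1, K + 1 + n - k))
            sites = [("P", i) for i in in_domain + outside]
            table = domain_enrichment(sites, bg).set_index("domain_label")
            # enumeration: fraction of n-subsets of N with >= k in-domain
            universe = list(range(1, N + 1))
            hits = total = 0
            for subset in combinations(universe, n):
                total += 1
                hits += sum(1 for s in subset if s <= K) >= k
            assert table.loc["D", "p_value"] == pytest.approx(hits / total, rel=1e-9)

    def test_site_missing_from_background_rejected(self):
        bg = make_background([("P", 1, "D")])
        with pytest.raises(ValueError, match="absent"):
            domain_enrichment([("P", 2)], bg)

    def test_bh_adjustment_monotone_in_p(self, rng):
        rows = []
        sites = []
        for d in range(8):
            for i in range(10):
                pos = d * 100 + i
                rows.append(("P", pos, f"D{d}"))
                if rng.random() < (d + 1) / 10:
                    sites.append(("P", pos))
        if not sites:
            pytest.skip("no sites drawn")
        table = domain_enrichment(sites, make_background(rows))
        ordered = table.sort_values("p_value")
        assert ordered["fdr_bh"].is_monotonic_increasing
        assert ((table["fdr_bh"] >= table["p_value"] - 1e-12)).all()
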