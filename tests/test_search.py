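"""Reporter-anchored cross-link search, scoring and target-decoy FDR."""

import numpy as np
import pytest

from sulfenlink.chem import HYDROGEN, PROTON, mass_from_mz, mz_from_mass, peptide_neutral_mass
from sulfenlink.crosslink import CSEIWDR_REPORTER, CrossLinkedPeptide, theoretical_fragments
from sulfenlink.digestion import ProteinRecord
from sulfenlink.search import (
    PSM,
    SearchSettings,
    build_partner_index,
    compute_fdr,
    expand_modifications,
    peptide_level_fdr,
    score_psm,
    search_spectrum,
)
from sulfenlink.spectra import Spectrum

SETTINGS = SearchSettings()


def planted_spectrum(clpep, charge=3, title="planted", extra=()):
    frags = theoretical_fragments(clpep, max_charge=1)
    mz = np.array([f.mz for f in frags] + list(extra))
    return Spectrum(
        title=title,
        precursor_mz=mz_from_mass(clpep.neutral_mass(), charge),
        precursor_charge=charge,
        mz=mz,
        intensity=np.ones_like(mz),
    )


def make_psm(title, score, is_decoy, partner="VIEYCK"):
    clpep = CrossLinkedPeptide("CSEIWDR", partner, 1, partner.index("C") + 1)
    return PSM(
        spectrum_title=title,
        clpep=clpep,
        score=score,
        matched_fragments=5,
        is_decoy=is_decoy,
        accession="ACC",
        linked_protein_position=10,
        charge=3,
        precursor_error_ppm=0.0,
    )


class TestPartnerIndex:
    def test_single_unmodified_peptide_mass(self):
        db = [ProteinRecord("P", "", "GGKVIEYCKAAR")]
        index = build_partner_index(db, SETTINGS, with_decoys=False)
        entries = index.query(753.3731, 0.01)
        assert len(entries) == 1
        assert entries[0].sequence == "VIEYCK"
        assert entries[0].mass == pytest.approx(753.3731, abs=2e-4)

    def test_two_met_oxidation_states(self):
        db = [ProteinRecord("P", "", "GGKAMCMAAKGGR")]
        index = build_partner_index(db, SETTINGS, with_decoys=False)
        variants = [e for e in index.entries if e.sequence == "AMCMAAK"]
        assert len(variants) == 4  # 0, M2, M4, both oxidized
        masses = sorted(e.mass for e in variants)
        base = peptide_neutral_mass("AMCMAAK")
        assert masses[0] == pytest.approx(base)
        assert masses[1] == masses[2] == pytest.approx(base + 15.994915)
        assert masses[3] == pytest.approx(base + 2 * 15.994915)

    def test_query_outside_range_is_empty(self):
        db = [ProteinRecord("P", "", "GGKVIEYCKAAR")]
        index = build_partner_index(db, SETTINGS, with_decoys=False)
        assert index.query(5000.0, 0.05) == []

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            build_partner_index([ProteinRecord("P", "", "GGKAAAR")], SETTINGS)

    def test_decoys_from_reversed_proteins(self):
        db = [ProteinRecord("P", "", "GGKVIEYCKAAR")]
        index = build_partner_index(db, SETTINGS)
        assert index.n_decoys > 0
        assert all(
            e.accession.startswith("DECOY_") == e.is_decoy for e in index.entries
        )

    def test_linked_cys_never_carbamidomethylated(self):
        db = [ProteinRecord("P", "", "GGKACCAAKGGR")]
        index = build_partner_index(db, SETTINGS, with_decoys=False)
        for e in index.entries:
            for mod, pos in e.mods:
                assert not (mod.name == "Carbamidomethyl" and pos == e.linked_cys)


class TestExpandModifications:
    def test_cap_on_simultaneous_mods(self):
        from sulfenlink.digestion import DigestPeptide

        pep = DigestPeptide("MMMMCK", "P", 10, 15, 0)
        states = expand_modifications(pep, 5, SearchSettings(max_var_mods=2))
        assert max(len(s) for s in states) == 2
        assert () in states


class TestScorePsm:
    def test_exact_fragment_list_matches_everything(self):
        clpep = CrossLinkedPeptide("CSEIWDR", "VIEYCK", 1, 5)
        s = planted_spectrum(clpep)
        frags = theoretical_fragments(clpep, max_charge=SETTINGS.max_fragment_charge)
        score, matched = score_psm(s, clpep, SETTINGS)
        # every charge-1 target matches; charge-2 targets may or may not
        assert matched >= sum(f.charge == 1 for f in frags)
        assert score > 0

    def test_empty_spectrum_scores_zero(self):
        clpep = CrossLinkedPeptide("CSEIWDR", "VIEYCK", 1, 5)
        empty = Spectrum(title="e", precursor_mz=500.0, mz=np.empty(0), intensity=np.empty(0))
        assert score_psm(empty, clpep, SETTINGS) == (0.0, 0)

    def test_random_spectra_match_binomial_null(self, rng):
        """Mean matched-fragment count on random spectra follows the
        uniform-peak random-match model."""
        clpep = CrossLinkedPeptide("CSEIWDR", "HMIEDDCTDNGIPLPNVTSK", 1, 7)
        frags = theoretical_fragments(clpep, max_charge=SETTINGS.max_fragment_charge)
        lo, hi, n_peaks, n_spectra = 100.0, 1500.0, 200, 300
        counts = []
        for i in range(n_spectra):
            mz = rng.uniform(lo, hi, size=n_peaks)
            s = Spectrum(title=f"r{i}", precursor_mz=800.0, mz=mz, intensity=np.ones(n_peaks))
            counts.append(score_psm(s, clpep, SETTINGS)[1])
        in_range = [f.mz for f in frags if lo <= f.mz <= hi]
        expected = sum(
            1 - (1 - 2 * (m * 20e-6) / (hi - lo)) ** n_peaks for m in in_range
        )
        sd = np.sqrt(expected)  # Poisson-ish spread of the per-spectrum count
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(n_spectra) + 0.05


@pytest.fixture(scope="module")
def index(tiny_database):
    return build_partner_index(tiny_database, SETTINGS)


class TestSearchSpectrum:

    def test_planted_crosslink_ranks_first(self, index):
        clpep = CrossLinkedPeptide("CSEIWDR", "VIEYCK", 1, 5)
        psms = search_spectrum(planted_spectrum(clpep), index, SETTINGS)
        assert psms
        top = psms[0]
        assert top.clpep.partner_sequence == "VIEYCK"
        assert not top.is_decoy
        assert abs(top.precursor_error_ppm) <= SETTINGS.precursor_tol_ppm

    def test_no_candidate_within_tolerance_returns_empty(self, index):
        s = Spectrum(title="far", precursor_mz=3333.333, precursor_charge=3,
                     mz=np.array([500.0]), intensity=np.array([1.0]))
        assert search_spectrum(s, index, SETTINGS) == []

    def test_unknown_charge_tries_all_considered(self, index):
        clpep = CrossLinkedPeptide("CSEIWDR", "VIEYCK", 1, 5)
        s = planted_spectrum(clpep, charge=3)
        s.precursor_charge = None
        psms = search_spectrum(s, index, SETTINGS)
        assert psms and psms[0].clpep.partner_sequence == "VIEYCK"
        assert psms[0].charge == 3

    def test_isobaric_leu_ile_candidates_tie_and_flag(self):
        db = [
            ProteinRecord("A", "", "GGKVIEYCKAAR"),
            ProteinRecord("B", "", "GGKVLEYCKAAR"),
        ]
        index = build_partner_index(db, SETTINGS, with_decoys=False)
        clpep = CrossLinkedPeptide("CSEIWDR", "VIEYCK", 1, 5)
        psms = search_spectrum(planted_spectrum(clpep), index, SETTINGS)
        assert len(psms) >= 2
        assert psms[0].score == psms[1].score
        assert psms[0].ambiguous and psms[1].ambiguous
        assert {psms[0].clpep.partner_sequence, psms[1].clpep.partner_sequence} == {
            "VIEYCK",
            "VLEYCK",
        }

    def test_missed_cleavage_anchor_variant(self, index):
        clpep = CrossLinkedPeptide("EGSLLRCSEIWDR", "VIEYCK", 7, 5)
        psms = search_spectrum(
            planted_spectrum(clpep),
            index,
            SETTINGS,
            extra_anchor_sequences=("EGSLLRCSEIWDR", "CSEIWDRITTHPK"),
        )
        assert psms
        assert psms[0].clpep.reporter_sequence == "EGSLLRCSEIWDR"
        assert psms[0].clpep.partner_sequence == "VIEYCK"

    def test_self_link_flagged(self, index):
        clpep = CrossLinkedPeptide("CSEIWDR", "CSEIWDR", 1, 1)
        psms = search_spectrum(planted_spectrum(clpep), index, SETTINGS)
        assert psms and psms[0].is_self_link
        assert psms[0].clpep.partner_sequence == "CSEIWDR"

    def test_precursor_arithmetic_invariant(self, index):
        clpep = CrossLinkedPeptide("CSEIWDR", "KLKECEK", 1, 5)
        for z in (2, 3, 4):
            for p in search_spectrum(planted_spectrum(clpep, charge=z), index, SETTINGS):
                observed = mass_from_mz(
                    mz_from_mass(clpep.neutral_mass(), z), z
                )
                theo = p.clpep.neutral_mass()
                assert abs(observed - theo) / theo * 1e6 <= SETTINGS.precursor_tol_ppm


class TestComputeFdr:
    def test_no_decoys_all_accepted(self):
        psms = [make_psm(f"s{i}", 10.0 - i * 0.01, False) for i in range(100)]
        pool, accepted = compute_fdr(psms, threshold=0.01)
        assert len(accepted) == 100
        assert all(p.q_value == 0.0 for p in pool)

    def test_hand_enumerated_decoy_case(self):
        psms = [make_psm(f"t{i}", 10.0 - i, False) for i in range(10)]
        psms.append(make_psm("d", 9.5, True))
        pool, accepted = compute_fdr(psms, threshold=0.01)
        by_title = {p.spectrum_title: p for p in pool}
        assert by_title["t0"].q_value == 0.0
        for i in range(1, 10):
            assert by_title[f"t{i}"].q_value == pytest.approx(0.1)
        assert by_title["d"].q_value == pytest.approx(0.1)
        assert [p.spectrum_title for p in accepted] == ["t0"]
        _, loose = compute_fdr(psms, threshold=0.15)
        assert len(loose) == 10

    def test_best_psm_per_spectrum_kept(self):
        psms = [make_psm("s", 5.0, False), make_psm("s", 9.0, False)]
        pool, _ = compute_fdr(psms, threshold=0.5)
        assert len(pool) == 1 and pool[0].score == 9.0

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            compute_fdr([make_psm("d", 5.0, True)])

    def test_qvalues_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        psms = [
            make_psm(f"s{i}", float(rng.normal(5, 2)), bool(rng.random() < 0.3))
            for i in range(200)
        ]
        if not any(not p.is_decoy for p in psms):
            pytest.skip("no targets drawn")
        pool, _ = compute_fdr(psms, threshold=0.01)
        qs = [p.q_value for p in pool]
        assert qs == sorted(qs)

    def test_peptide_level_pools_by_partner(self):
        psms = [
            make_psm("s1", 9.0, False, "VIEYCK"),
            make_psm("s2", 7.0, False, "VIEYCK"),
            make_psm("s3", 8.0, False, "KLKECEK"),
        ]
        pool, accepted = peptide_level_fdr(psms, threshold=0.5)
        assert len(pool) == 2
        assert {p.clpep.partner_sequence for p in accepted} == {"VIEYCK", "KLKECEK"}
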