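"""Candidate search, domain confirmation, protein statistics and naming."""

import numpy as np
import pytest

from familyscan import identification as ident
from familyscan.genome_io import GeneModel, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestTranslateCds:
    @pytest.mark.parametrize("cds,protein", [
        ("ATGTGA", "M"),  # aa = orf/3 - 1: the initiator Met counts
        ("ATGGGTTAA", "MG"),
        ("ATGGCTTGCGATTAG", "MACD"),
    ])
    def test_standard_code(self, cds, protein):
        assert ident.translate_cds(cds) == protein

    @pytest.mark.parametrize("cds", [
        "ATGGG",           # not divisible by 3
        "GTGGGTTAA",       # non-ATG start
        "ATGGGTGGT",       # no terminal stop
        "ATGTAAGGTTGA",    # internal stop
    ])
    def test_rejections(self, cds):
        with pytest.raises(ident.CdsError):
            ident.translate_cds(cds)

    def test_table_sized_cds(self, default_sim):
        # a 732-nt clean ORF yields a 243-residue protein
        rng = np.random.default_rng(0)
        from familyscan.synthetic_data import back_translate

        protein = "M" + "".join(rng.choice(list(AA), size=242))
        cds = back_translate(rng, protein)
        assert len(cds) == 732
        assert ident.translate_cds(cds) == protein


class TestProteinStats:
    def test_mw_glycine(self):
        # average residue mass 57.052 plus one water
        assert ident.compute_mw("G") == pytest.approx(75.07, abs=0.01)
        assert ident.compute_mw("GG") == pytest.approx(132.12, abs=0.01)

    def test_mw_additive(self):
        a, b = "MKVLA", "DERTW"
        assert ident.compute_mw(a + b) == pytest.approx(
            ident.compute_mw(a) + ident.compute_mw(b) - 18.015, abs=0.05)

    def test_mw_empty_is_error(self):
        with pytest.raises(ValueError):
            ident.compute_mw("")

    def test_pi_is_charge_root(self):
        # independent oracle: brute-force pH grid over per-residue charges
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        seq = "ACDEFGHIKLMNPQRSTVWY"
        pi = ident.compute_pi(seq)
        ip = IsoelectricPoint(seq)
        grid = np.arange(0.0, 14.0, 0.001)
        charges = np.array([ip.charge_at_pH(ph) for ph in grid])
        brute = grid[np.argmin(np.abs(charges))]
        assert pi == pytest.approx(brute, abs=0.05)
        assert abs(ip.charge_at_pH(pi)) < 0.01

    def test_pi_monotone_in_charge(self):
        assert ident.compute_pi("KKKKKKK") > ident.compute_pi("DDDDDDD")


class TestDomainScan:
    def test_consensus_self_match(self):
        profile = ident.build_profile()
        hit = ident.scan_domain(SequenceRecord("c", profile.consensus), profile)
        assert hit is not None and hit.start == 1 and hit.end == profile.length
        assert hit.score == pytest.approx(profile.self_score())

    def test_planted_offset(self):
        profile = ident.build_profile()
        rng = np.random.default_rng(42)
        flank = "".join(rng.choice(list(AA), size=50))
        tail = "".join(rng.choice(list(AA), size=30))
        hit = ident.scan_domain(
            SequenceRecord("p", flank + profile.consensus + tail), profile)
        assert hit.start == 51

    def test_shuffled_null_rate(self):
        # empirical null: shuffles of a real domain hit the threshold rarely
        profile = ident.build_profile()
        rng = np.random.default_rng(7)
        residues = list(profile.consensus + "AEKLVDGRSTPQNH" * 5)
        false_hits = 0
        for _ in range(100):
            rng.shuffle(residues)
            if ident.scan_domain(SequenceRecord("s", "".join(residues)), profile):
                false_hits += 1
        assert false_hits <= 5

    def test_short_protein_returns_none(self):
        profile = ident.build_profile()
        assert ident.scan_domain(SequenceRecord("s", "MKV"), profile) is None


class TestSimilaritySearch:
    def test_self_hit_full_identity(self):
        rng = np.random.default_rng(1)
        seq = "M" + "".join(rng.choice(list(AA), size=149))
        rec = SequenceRecord("q", seq)
        hits = ident.similarity_search([rec], [rec])
        assert hits and hits[0].identity_pct == 100.0

    def test_unrelated_null_rate(self):
        rng = np.random.default_rng(5)
        misses = 0
        for _ in range(100):
            a = SequenceRecord("a", "".join(rng.choice(list(AA), size=150)))
            b = SequenceRecord("b", "".join(rng.choice(list(AA), size=150)))
            if not ident.similarity_search([a], [b]):
                misses += 1
        assert misses >= 95

    def test_planted_homolog_recovered(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(AA), size=200))
        mutant = list(seq)
        for pos in rng.choice(200, size=40, replace=False):  # 80% identity
            mutant[pos] = AA[rng.integers(0, 20)]
        hits = ident.similarity_search(
            [SequenceRecord("q", seq)], [SequenceRecord("h", "".join(mutant))])
        assert [h.subject_id for h in hits] == ["h"]

    def test_empty_database(self):
        assert ident.similarity_search([SequenceRecord("q", "MKV")], []) == []


class TestKeywordSearch:
    def test_matches_and_non_matches(self):
        ann = {
            "a": "17.6 kDa class I small heat shock protein",
            "b": "heat shock factor",
            "c": "Hsp20/alpha crystallin family",
        }
        assert ident.keyword_search(ann) == {"a", "c"}

    def test_empty_keywords(self):
        assert ident.keyword_search({"a": "anything"}, keywords=()) == set()


class TestConfirmAndName:
    def test_mw_window_boundaries(self):
        profile = ident.build_profile()
        consensus = profile.consensus  # 113 aa, ~13.2 kDa: below the window
        small = consensus
        mid = consensus + "K" * 60      # ~20 kDa, domain present
        cands = ident.CandidateSet()
        cands.add(["small", "mid"], "hmm_search")
        kept = ident.confirm_members(cands, {"small": small, "mid": mid}, profile)
        assert kept == ["mid"]

    def test_synthetic_truth_recovered_exactly(self, default_sim):
        profile = ident.build_profile()
        records = [SequenceRecord(k, v, default_sim.annotations.get(k, ""))
                   for k, v in default_sim.proteins.items()]
        cands = ident.gather_candidates(records, profile,
                                        annotations=default_sim.annotations)
        kept = ident.confirm_members(cands, default_sim.proteins, profile)
        assert sorted(kept) == sorted(default_sim.truth["family_members"])

    def test_order_invariance(self, default_sim):
        profile = ident.build_profile()
        cands_fwd, cands_rev = ident.CandidateSet(), ident.CandidateSet()
        ids = sorted(default_sim.proteins)
        cands_fwd.add(ids, "hmm_search")
        cands_rev.add(ids[::-1], "keyword")
        assert (ident.confirm_members(cands_fwd, default_sim.proteins, profile)
                == ident.confirm_members(cands_rev, default_sim.proteins, profile))

    def test_positional_naming(self):
        genes = [
            GeneModel("b", "1", "?", 79702817, 79703750),
            GeneModel("a", "1", "?", 6195606, 6196992),
            GeneModel("c", "2", "?", 36223235, 36224237),
        ]
        names = ident.assign_names(genes, "St")
        assert names == {"a": "St-1", "b": "St-2", "c": "St-3"}
        # shuffled input gives identical naming
        assert ident.assign_names(genes[::-1], "St") == names

    def test_duplicate_position_is_error(self):
        genes = [GeneModel("a", "1", "?", 10, 20), GeneModel("a", "1", "?", 10, 30)]
        with pytest.raises(ValueError):
            ident.assign_names(genes)

    def test_numeric_chromosome_order(self):
        genes = [GeneModel("x", "chr10", "?", 5, 9), GeneModel("y", "chr2", "?", 5, 9)]
        assert ident.assign_names(genes)["y"] == "Gene-1"
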