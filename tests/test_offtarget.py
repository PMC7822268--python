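import random

import pytest

from oligopipe.core import DesignType, Transcript
from oligopipe.enumeration import EnumerationConfig, enumerate_candidates
from oligopipe.errors import (
    ConfigurationError,
    EmptyDatabaseError,
    QueryTooShortError,
)
from oligopipe.offtarget import (
    Hit,
    build_index,
    offtarget_profile,
    search,
    summarize,
)

from conftest import make_candidate, random_dna
from oracles import brute_force_gene_summary, brute_force_hits


def _db(rng: random.Random, n: int, length: int, prefix: str = "D"):
    return [
        Transcript(f"{prefix}{i}", f"G{prefix}{i}", "human",
                   random_dna(rng, length))
        for i in range(n)
    ]


class TestSearch:
    def test_self_match_found_at_mm0(self, rng):
        db = _db(rng, 1, 60)
        query = db[0].sequence[10:29]
        hits = search(build_index(db), query)
        assert Hit("D0", "GD0", 10, "+", 0) in hits

    def test_one_substitution_found_at_mm1(self, rng):
        db = _db(rng, 1, 60)
        window = list(db[0].sequence[10:29])
        window[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[5]]
        hits = search(build_index(db), "".join(window))
        assert any(h.offset == 10 and h.mismatches == 1 for h in hits)

    def test_three_mismatches_absent(self):
        text = "ACGTACGTACGTACGTACGTACGT"
        db = [Transcript("D0", "GD0", "human", text)]
        query = list(text[:19])
        for pos in (2, 9, 16):
            query[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[pos]]
        hits = search(build_index(db), "".join(query))
        assert all(h.offset != 0 for h in hits)

    def test_all_n_query_hits_nothing(self, rng):
        db = _db(rng, 2, 100)
        assert search(build_index(db), "N" * 19) == []

    def test_query_too_short(self, rng):
        with pytest.raises(QueryTooShortError):
            search(build_index(_db(rng, 1, 50)), "ACGTACGT")

    def test_empty_database_rejected(self):
        with pytest.raises(EmptyDatabaseError):
            build_index([])

    def test_matches_brute_force_on_random_db(self, rng):
        db = _db(rng, 10, 200)
        index = build_index(db)
        for _ in range(50):
            query = random_dna(rng, 19)
            got = {(h.transcript_id, h.offset, h.mismatches)
                   for h in search(index, query)}
            assert got == brute_force_hits(db, query)

    def test_matches_brute_force_with_planted_near_hits(self, rng):
        db = _db(rng, 5, 150)
        # plant windows at 0..2 mismatches of a known query
        query = random_dna(rng, 19)
        for i, n_mm in enumerate((0, 1, 2)):
            seq = list(db[i].sequence)
            window = list(query)
            for pos in rng.sample(range(19), n_mm):
                window[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[pos]]
            seq[40:59] = window
            db[i] = Transcript(db[i].transcript_id, db[i].gene_id,
                               "human", "".join(seq))
        got = {(h.transcript_id, h.offset, h.mismatches)
               for h in search(build_index(db), query)}
        assert got == brute_force_hits(db, query)
        for i, n_mm in enumerate((0, 1, 2)):
            assert (f"D{i}", 40, n_mm) in got

    def test_n_in_text_counts_as_mismatch(self):
        db = [Transcript("D0", "GD0", "human", "ACGTACGTANGTACGTACGTA")]
        query = "ACGTACGTACGTACGTACG"
        hits = search(build_index(db), query)
        assert any(h.offset == 0 and h.mismatches == 1 for h in hits)


class TestSummarize:
    def test_target_gene_excluded(self):
        hits = [Hit("T1", "G1", 0, "+", 0), Hit("T1v2", "G1", 5, "+", 1)]
        s = summarize(hits, "G1")
        assert s.as_tuple() == (0, 0, 0)

    def test_gene_counted_at_minimum_level_only(self):
        hits = [Hit("D1", "GD1", 0, "+", 2), Hit("D1b", "GD1", 9, "+", 0)]
        s = summarize(hits, "G1")
        assert s.as_tuple() == (1, 0, 0)

    def test_distinct_genes_per_level(self):
        hits = [
            Hit("D1", "GD1", 0, "+", 0),
            Hit("D2", "GD2", 0, "+", 1),
            Hit("D3", "GD3", 0, "+", 1),
            Hit("D4", "GD4", 0, "+", 2),
        ]
        assert summarize(hits, "G1").as_tuple() == (1, 2, 1)

    def test_order_invariance(self, rng):
        hits = [
            Hit(f"D{i}", f"GD{i % 3}", i, "+", rng.randrange(3))
            for i in range(20)
        ]
        shuffled = hits[:]
        rng.shuffle(shuffled)
        assert summarize(hits, "GD0").as_tuple() == \
            summarize(shuffled, "GD0").as_tuple()


class TestProfile:
    def test_target_only_database_all_zero(self, rng):
        primary = Transcript("T1", "G1", "human", random_dna(rng, 100))
        cands = enumerate_candidates(
            primary, EnumerationConfig(k=19, design_type="SIRNA")
        )
        index = build_index([primary])
        for c in cands:
            offtarget_profile(c, index, None, target_gene_id="G1")
            assert all(
                c.properties[p] == 0
                for p in ("cdna_mm0", "cdna_mm1", "cdna_mm2",
                          "cdna_pass_mm0", "cdna_pass_mm1", "cdna_pass_mm2")
            )

    def test_aso_requires_gene_index(self, rng):
        c = make_candidate(random_dna(rng, 20), design_type=DesignType.ASO)
        index = build_index(_db(rng, 1, 100))
        with pytest.raises(ConfigurationError):
            offtarget_profile(c, index, None, target_gene_id="G1")

    def test_aso_planted_decoy_and_parent_gene(self, rng):
        primary = Transcript("T1", "G1", "human", random_dna(rng, 80))
        window = primary.sequence[20:40]
        decoy_cdna = Transcript("D1", "GD1", "human",
                                random_dna(rng, 100) + window)
        gene = Transcript("G1_unspliced", "G1", "human", primary.sequence)
        other_gene = Transcript("GX", "GGX", "human",
                                random_dna(rng, 50) + window)
        c = make_candidate(window, start=20, design_type=DesignType.ASO)
        offtarget_profile(
            c,
            build_index([primary, decoy_cdna], "cdna"),
            build_index([gene, other_gene], "gene"),
            target_gene_id="G1",
        )
        assert c.properties["cdna_mm0"] == 1
        assert c.properties["gene_mm0"] >= 1

    def test_irrelevant_decoy_never_changes_summary(self, rng):
        primary = Transcript("T1", "G1", "human", random_dna(rng, 60))
        db = [primary] + _db(rng, 3, 120)
        cands = enumerate_candidates(
            primary, EnumerationConfig(k=19, design_type="SIRNA")
        )
        base = {}
        index = build_index(db)
        for c in cands:
            offtarget_profile(c, index, None, target_gene_id="G1")
            base[c.oligo_id] = (c.properties["cdna_mm0"],
                                c.properties["cdna_mm1"],
                                c.properties["cdna_mm2"])
        # a decoy at Hamming distance >= 3 from every window: all-G text
        # against windows that contain non-G bases at >= 3 positions
        far = Transcript("DF", "GDF", "human", "G" * 120)
        index2 = build_index(db + [far])
        for c in cands:
            if sum(1 for b in c.sense_seq if b != "G") < 3:
                continue
            offtarget_profile(c, index2, None, target_gene_id="G1")
            assert base[c.oligo_id] == (c.properties["cdna_mm0"],
                                        c.properties["cdna_mm1"],
                                        c.properties["cdna_mm2"])

    def test_sirna_profile_equals_brute_force(self, rng):
        primary = Transcript("T1", "G1", "human", random_dna(rng, 60))
        db = [primary] + _db(rng, 8, 300)
        index = build_index(db)
        cands = enumerate_candidates(
            primary, EnumerationConfig(k=19, design_type="SIRNA")
        )
        for c in cands:
            offtarget_profile(c, index, None, target_gene_id="G1")
            guide = brute_force_gene_summary(db, c.sense_seq, "G1")
            passenger = brute_force_gene_summary(db, c.antisense_seq, "G1")
            assert (c.properties["cdna_mm0"], c.properties["cdna_mm1"],
                    c.properties["cdna_mm2"]) == guide
            assert (c.properties["cdna_pass_mm0"], c.properties["cdna_pass_mm1"],
                    c.properties["cdna_pass_mm2"]) == passenger
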