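import random

import pytest

from oligopipe.core import reverse_complement
from oligopipe.errors import EmptyInputError, InvalidSequenceError
from oligopipe.thermo import (
    T37,
    hairpin_screen,
    load_params,
    nn_duplex_dg,
    nn_duplex_tm,
    self_dimer_dg,
    thermo_profile,
)

from conftest import random_dna
from oracles import max_stem, nn_dg_sum, nn_table


@pytest.fixture(scope="module", params=["dna_dna", "dna_rna"])
def params(request):
    return load_params(request.param)


class TestParameterSets:
    def test_internal_consistency_every_entry(self, params):
        # dG37 == dH - T37*dS/1000 within 0.05 kcal/mol, checked on load
        params.check_consistency(tol=0.05)
        for dh, ds, dg in params.stacks.values():
            assert abs((dh - T37 * ds / 1000.0) - dg) <= 0.05

    def test_all_sixteen_stacks_present(self, params):
        bases = "ACGT"
        assert set(params.stacks) == {a + b for a in bases for b in bases}


class TestDuplexDg:
    def test_length_two_is_init_plus_one_stack(self, params):
        table = nn_table(params.name)
        dg = nn_duplex_dg("AC", params)
        expected = table.get("init", (0, 0, 0))[2] + table["AC"][2]
        for term_key, terminal in (("term_AT", "A"), ("term_GC", "C")):
            if term_key in table:
                expected += table[term_key][2]
        assert dg == pytest.approx(expected)

    def test_matches_hand_summation(self, params):
        table = nn_table(params.name)
        assert nn_duplex_dg("ACGTACGT", params) == pytest.approx(
            nn_dg_sum("ACGTACGT", table)
        )

    def test_oracle_equality_on_many_random_sequences(self, params):
        table = nn_table(params.name)
        rng = random.Random(7)
        for _ in range(1000):
            seq = random_dna(rng, rng.randint(2, 30))
            assert nn_duplex_dg(seq, params) == pytest.approx(
                nn_dg_sum(seq, table), abs=1e-9
            )

    def test_additivity_of_appended_stack(self):
        # the hybrid set has no terminal corrections, so extending the
        # sequence adds exactly one stack term
        params = load_params("dna_rna")
        rng = random.Random(11)
        for _ in range(50):
            seq = random_dna(rng, 15)
            base = random_dna(rng, 1)
            diff = nn_duplex_dg(seq + base, params) - nn_duplex_dg(seq, params)
            assert diff == pytest.approx(params.stacks[seq[-1] + base][2])

    def test_rejects_ambiguity_and_short_input(self, params):
        with pytest.raises(InvalidSequenceError):
            nn_duplex_dg("ACGNAC", params)
        with pytest.raises(EmptyInputError):
            nn_duplex_dg("A", params)


class TestTm:
    def test_monotone_in_oligo_concentration(self, params):
        tms = [
            nn_duplex_tm("ACGTACGTACGTACGTACG", params, oligo_conc=c)
            for c in (1e-9, 1e-7, 1e-5)
        ]
        assert tms == sorted(tms)

    def test_dg_consistent_with_dh_ds_at_37(self, params):
        # recompute dG37 from the same dH/dS totals the Tm uses
        rng = random.Random(13)
        table = nn_table(params.name)
        for _ in range(100):
            seq = random_dna(rng, 19)
            dh = ds = 0.0
            for key in ["init"] if "init" in table else []:
                dh += table[key][0]
                ds += table[key][1]
            for i in range(18):
                dh += table[seq[i:i + 2]][0]
                ds += table[seq[i:i + 2]][1]
            for terminal in (seq[0], seq[-1]):
                key = "term_AT" if terminal in "AT" else "term_GC"
                if key in table:
                    dh += table[key][0]
                    ds += table[key][1]
            assert nn_duplex_dg(seq, params) == pytest.approx(
                dh - T37 * ds / 1000.0, abs=0.05 * 21
            )

    def test_gc_run_melts_higher_than_at_run(self, params):
        assert nn_duplex_tm("G" * 15, params) > nn_duplex_tm("AT" * 7 + "A", params)

    def test_salt_correction_direction(self, params):
        seq = "ACGTACGTACGTACGTACG"
        assert nn_duplex_tm(seq, params, na_conc=0.1) < nn_duplex_tm(seq, params)

    def test_nonpositive_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            nn_duplex_tm("ACGTAC", params, oligo_conc=0.0)


class TestSelfDimer:
    def test_no_self_complementarity_scores_zero(self, params):
        assert self_dimer_dg("AAAAAAAA", params) == 0.0

    def test_palindrome_equals_full_duplex(self, params):
        seq = "ACGCGCGT"
        assert reverse_complement(seq) == seq
        assert self_dimer_dg(seq, params) == pytest.approx(
            nn_duplex_dg(seq, params)
        )

    def test_never_positive(self, params, rng):
        for _ in range(200):
            seq = random_dna(rng, rng.randint(8, 25))
            assert self_dimer_dg(seq, params) <= 0.0

    def test_reverse_complement_symmetry(self):
        # holds for the DNA:DNA set, whose stack table is
        # reverse-complement symmetric
        params = load_params("dna_dna")
        rng = random.Random(23)
        for _ in range(200):
            seq = random_dna(rng, rng.randint(8, 20))
            assert self_dimer_dg(seq, params) == pytest.approx(
                self_dimer_dg(reverse_complement(seq), params)
            )


class TestHairpin:
    def test_planted_four_bp_stem(self):
        # GGGG ... loop AAA ... CCCC: stem 4, loop 3
        assert hairpin_screen("GGGGAAACCCC") == 4

    def test_planted_six_bp_stem(self):
        assert hairpin_screen("ATGGGGGGAAATCCCCCCAT"[2:-2]) >= 6

    def test_below_min_stem_is_zero(self):
        assert hairpin_screen("GGGAAACCC") == 0  # best stem 3 < min_stem 4

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(150):
            seq = random_dna(rng, rng.randint(8, 22))
            expected = max_stem(seq, min_loop=3)
            got = hairpin_screen(seq, min_stem=1, min_loop=3)
            assert got == expected

    def test_upper_bound(self, rng):
        for _ in range(100):
            seq = random_dna(rng, rng.randint(10, 25))
            assert hairpin_screen(seq, min_stem=1) <= (len(seq) - 3) // 2


def test_thermo_profile_fields(params):
    p = thermo_profile("ACGTACGTACGTACGTACG", params)
    assert p.duplex_dg37 < 0
    assert p.hairpin_stem_max >= 0
    assert p.self_dimer_dg37 <= 0
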