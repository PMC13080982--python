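"""The three-part codelength calculus against independent oracles."""

import math
from itertools import permutations

import mpmath
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgcompress import codec
from fgcompress.message_length import (
    SymbolModel,
    codebook_size_cost,
    log_star,
    part1,
    part2,
    part3,
    substring_cost,
    total_length,
)
from fgcompress.smiles_text import tokenize


@pytest.fixture
def worked_model():
    """The symbol code P(C)=0.5, P(N)=0.25 of the transmission example."""
    return SymbolModel(probs={"C": 0.5, "N": 0.25, "O": 0.25})


class TestLogStar:
    def test_anchor_values_default_convention(self):
        assert log_star(4) == 2.0
        assert log_star(1) == 0.0

    def test_sixteen_matches_term_by_term_summation(self):
        # literal term-by-term: keep iterated logs while strictly > 1
        terms = [math.log2(16)]
        while terms[-1] > 1.0:
            t = math.log2(terms[-1])
            if t > 1.0:
                terms.append(t)
            else:
                break
        assert log_star(16) == pytest.approx(sum(terms))

    def test_literal_series_gives_three_bits_for_four(self):
        assert log_star(4, convention="literal") == pytest.approx(3.0)

    def test_rissanen_adds_normalizer(self):
        assert log_star(4, convention="rissanen") == pytest.approx(
            3.0 + math.log2(2.865064)
        )

    @pytest.mark.parametrize("conv", ["anchored", "literal", "rissanen"])
    def test_monotone_non_decreasing(self, conv):
        vals = [log_star(n, conv) for n in range(1, 200)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            log_star(0)

    def test_size_cost_zero_flag(self):
        assert codebook_size_cost(0) == 1.0
        assert codebook_size_cost(3) == log_star(3)


class TestSubstringCost:
    def test_worked_example_seven_bits(self, worked_model):
        toks = tokenize("CCCN").tokens
        length_bits = log_star(4)
        c_bits = 3 * worked_model.cost("C")
        n_bits = 1 * worked_model.cost("N")
        assert (length_bits, c_bits, n_bits) == (2.0, 3.0, 2.0)
        assert substring_cost(toks, worked_model) == 7.0

    def test_certain_symbol_costs_only_its_length_term(self):
        model = SymbolModel(probs={"C": 1.0})
        assert substring_cost(("C",), model) == 0.0  # log*(1) + 0

    def test_two_equiprobable_symbols(self):
        model = SymbolModel(probs={"C": 0.5, "N": 0.5})
        assert substring_cost(("C", "N"), model) == pytest.approx(log_star(2) + 2.0)

    def test_zero_probability_symbol_rejected(self, worked_model):
        with pytest.raises(ValueError):
            substring_cost(("P",), worked_model)

    def test_additive_up_to_length_term(self, worked_model):
        a = tokenize("CC").tokens
        b = tokenize("CNN").tokens
        lhs = (
            substring_cost(a + b, worked_model)
            - substring_cost(a, worked_model)
            - substring_cost(b, worked_model)
        )
        rhs = log_star(5) - log_star(2) - log_star(3)
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestPart1:
    def test_empty_codebook_is_the_zero_flag_only(self, worked_model):
        assert part1([], worked_model) == 1.0

    def test_single_entry_worked_example(self, worked_model):
        assert part1([tokenize("CCCN").tokens], worked_model) == pytest.approx(
            log_star(1) + 7.0
        )

    def test_additivity_over_entries(self, worked_model):
        e = tokenize("CCCN").tokens
        assert part1([e, e], worked_model) == pytest.approx(log_star(2) + 14.0)


def _part2_mpmath(counts):
    """Arbitrary-precision evaluation of the MML87 multinomial codelength."""
    with mpmath.workdps(60):
        n = sum(counts)
        m = len(counts)
        val = mpmath.log(mpmath.gamma(n + m) / mpmath.gamma(m), 2)
        val += sum(mpmath.log(1 / mpmath.gamma(c + 1), 2) for c in counts)
        val += mpmath.log((m - 1) * mpmath.pi, 2) / 2 - mpmath.mpf("0.4")
        return float(val)


class TestPart2:
    def test_small_example_against_arbitrary_precision(self):
        expected = (
            math.log2(24.0 / 1.0)
            - math.log2(2.0)
            - math.log2(1.0)
            + 0.5 * math.log2(math.pi)
            - 0.4
        )
        assert part2([2, 1]) == pytest.approx(expected, abs=1e-12)
        assert part2([2, 1]) == pytest.approx(_part2_mpmath([2, 1]), abs=1e-9)
        assert part2([2, 1]) == pytest.approx(4.0107, abs=5e-4)

    def test_two_singletons_closed_form(self):
        expected = math.log2(6.0) + 0.5 * math.log2(math.pi) - 0.4
        assert part2([1, 1]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 5, 17])
    def test_matches_mpmath_up_to_ten_thousand(self, m):
        for n_each in (1, 7, 10_000 // m):
            counts = [n_each] * m
            assert part2(counts) == pytest.approx(_part2_mpmath(counts), abs=1e-9)

    def test_strictly_increasing_in_n_at_fixed_m(self):
        vals = [part2([n, n]) for n in range(1, 30)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_single_item_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            part2([5])

    def test_order_invariance(self):
        base = part2([5, 2, 9, 1])
        for perm in permutations([5, 2, 9, 1]):
            assert part2(list(perm)) == pytest.approx(base, abs=1e-12)


class TestPart3:
    def test_exact_small_values(self):
        assert part3([3, 1]) == pytest.approx(2.0)  # log2(4!/3!/1!)
        assert part3([7]) == 0.0
        assert part3([1] * 6) == pytest.approx(math.log2(math.factorial(6)))

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8).filter(
            lambda c: 0 < sum(c) <= 50
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_equals_exact_multinomial_coefficient(self, counts):
        n = sum(counts)
        coeff = math.factorial(n)
        for c in counts:
            coeff //= math.factorial(c)
        assert part3(counts) == pytest.approx(math.log2(coeff), abs=1e-9)


class TestTotalLength:
    def test_degenerate_one_symbol_dataset(self):
        seqs = [tokenize("C") for _ in range(4)]
        enc = codec.encode_identity(seqs)
        model = SymbolModel.from_sequences(seqs)
        ml = total_length(codec.Codebook(), enc, model)
        assert ml.p1 == 1.0  # empty codebook flag
        assert ml.p2 == 0.0  # one vocabulary item: no free parameters
        assert ml.p3 == 0.0  # a single arrangement
        assert ml.total == ml.p1 + ml.p2 + ml.p3

    def test_carbonyl_codebook_is_finite_and_decodable(self, carbonyl_trio):
        model = SymbolModel.from_sequences(carbonyl_trio)
        enc = codec.encode_identity(carbonyl_trio)
        cw = codec.make_codeword(1)
        codec.substitute(enc, tokenize("(=O)").tokens, cw, inplace=True)
        book = codec.Codebook(
            entries=[codec.CodebookEntry(codeword=cw, expansion=tokenize("(=O)").tokens)]
        )
        codec.decrement_nested(book, enc)
        # vocabulary collapses to {codeword, C, N, S}
        assert set(enc.vocab_counts) == {cw, "C", "N", "S"}
        ml = total_length(book, enc, model)
        assert math.isfinite(ml.total) and ml.p1 > 0 and ml.p3 >= 0
        assert codec.decode(enc, book) == ["C(=O)", "N(=O)", "S(=O)"]

    def test_invariant_total_is_sum_of_parts(self, branch_example):
        model = SymbolModel.from_sequences(branch_example)
        enc = codec.encode_identity(branch_example)
        ml = total_length(codec.Codebook(), enc, model)
        assert ml.total == pytest.approx(ml.p1 + ml.p2 + ml.p3)
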