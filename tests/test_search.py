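"""Greedy search behaviour: scoring, acceptance, termination, oracle parity."""

import pytest

from fgcompress import codec
from fgcompress.message_length import SymbolModel
from fgcompress.search import (
    GreedySearch,
    SearchConfig,
    greedy_step_oracle,
    run,
    score_candidate,
)
from fgcompress.smiles_text import tokenize
from fgcompress.synthetic import generate_planted


class TestScoreCandidate:
    def test_single_occurrence_rejected_by_prefilter(self, branch_example):
        model = SymbolModel.from_sequences(branch_example)
        enc = codec.encode_identity(branch_example)
        with pytest.raises(ValueError, match="min_occurrences"):
            score_candidate(enc, codec.Codebook(), model, tokenize("CCN").tokens)

    def test_single_occurrence_candidate_never_pays_for_itself(self, branch_example):
        """With the pre-filter lifted, a once-occurring substring still
        increases the message: its codebook entry is never amortized."""
        model = SymbolModel.from_sequences(branch_example)
        enc = codec.encode_identity(branch_example)
        cfg = SearchConfig(max_substring_len=5, min_occurrences=1)
        d = score_candidate(enc, codec.Codebook(), model, tokenize("CCN").tokens, cfg)
        assert d > 0

    def test_highly_repeated_motif_scores_negative(self):
        data = generate_planted(
            100, motif="C(=O)N", plant_rate=1.0, seed=0, require_parseable=False
        )
        seqs = [tokenize(s) for s in data.smiles]
        model = SymbolModel.from_sequences(seqs)
        enc = codec.encode_identity(seqs)
        cfg = SearchConfig(max_substring_len=6)
        assert score_candidate(enc, codec.Codebook(), model, tokenize("C(=O)N").tokens, cfg) < 0

    def test_deterministic_to_the_bit(self, branch_example):
        model = SymbolModel.from_sequences(branch_example)
        enc = codec.encode_identity(branch_example)
        cfg = SearchConfig(max_substring_len=5)
        cand = tokenize("N(O)").tokens
        d1 = score_candidate(enc, codec.Codebook(), model, cand, cfg)
        d2 = score_candidate(enc, codec.Codebook(), model, cand, cfg)
        assert d1 == d2

    def test_invalid_candidate_is_an_error(self, branch_example):
        model = SymbolModel.from_sequences(branch_example)
        enc = codec.encode_identity(branch_example)
        with pytest.raises(ValueError, match="validity"):
            score_candidate(enc, codec.Codebook(), model, tokenize("O)").tokens)


class TestRun:
    def test_bracketed_substring_found_first_with_larger_max_len(self, branch_example):
        """max_len=5 reaches a complete bracketed substructure in one step;
        max_len=2 cannot accept one at iteration 1."""
        _, _, tr5 = run(branch_example, SearchConfig(max_substring_len=5))
        assert "(" in tr5.records[0].substring and ")" in tr5.records[0].substring
        assert "N(O)" in tr5.records[0].substring
        _, _, tr2 = run(branch_example, SearchConfig(max_substring_len=2))
        assert ")" not in tr2.records[0].substring

    def test_larger_max_len_compresses_at_least_as_well(self, branch_example):
        _, _, tr5 = run(branch_example, SearchConfig(max_substring_len=5))
        _, _, tr2 = run(branch_example, SearchConfig(max_substring_len=2))
        assert tr5.records[-1].total_bits <= tr2.records[-1].total_bits + 1e-9

    def test_single_molecule_with_nothing_repeating(self):
        book, _, trace = run([tokenize("C")], SearchConfig())
        assert len(book) == 0 and trace.records == []

    def test_total_strictly_decreases_over_accepted_iterations(self):
        data = generate_planted(30, plant_rate=0.7, seed=9, require_parseable=False)
        _, _, trace = run(
            [tokenize(s) for s in data.smiles], SearchConfig(max_substring_len=5)
        )
        totals = [trace.initial_bits] + [r.total_bits for r in trace.records]
        assert len(totals) > 1
        assert all(b < a for a, b in zip(totals, totals[1:]))
        deltas = [r.delta_bits for r in trace.records]
        assert all(d < 0 for d in deltas)

    def test_unlimited_iterations_terminates(self):
        data = generate_planted(15, plant_rate=0.5, seed=21, require_parseable=False)
        book, enc, trace = run(
            [tokenize(s) for s in data.smiles],
            SearchConfig(max_substring_len=4, max_iterations=None),
        )
        assert codec.decode(enc, book) == data.smiles

    def test_lossless_at_every_iteration(self):
        data = generate_planted(20, plant_rate=0.6, seed=33, require_parseable=False)
        seqs = [tokenize(s) for s in data.smiles]
        gs = GreedySearch(seqs, SearchConfig(max_substring_len=5))
        while gs.step() is not None:
            assert codec.decode(gs.encoded, gs.codebook) == data.smiles

    def test_planted_motif_recovered_among_first_accepted(self):
        data = generate_planted(100, motif="C(=O)N", plant_rate=0.6, seed=7)
        _, _, trace = run(
            [tokenize(s) for s in data.smiles],
            SearchConfig(max_substring_len=6, max_iterations=3),
        )
        found = [r.substring for r in trace.records[:3]]
        assert any("C(=O)N" in s for s in found), found


class TestOracle:
    def test_refuses_large_states(self):
        data = generate_planted(200, plant_rate=0.5, seed=0, require_parseable=False)
        seqs = [tokenize(s) for s in data.smiles]
        enc = codec.encode_identity(seqs)
        with pytest.raises(ValueError, match="refuses"):
            greedy_step_oracle(enc, codec.Codebook(), SymbolModel.from_sequences(seqs))

    def test_no_improving_candidate_returns_none(self):
        seqs = [tokenize("CN")]
        enc = codec.encode_identity(seqs)
        model = SymbolModel.from_sequences(seqs)
        assert greedy_step_oracle(enc, codec.Codebook(), model) is None

    def test_matches_implementation_step_by_step(self):
        """Exhaustive from-scratch rescoring agrees with the incremental
        greedy choice at every iteration on small random fixtures."""
        for seed in range(5):
            data = generate_planted(
                6, plant_rate=0.6, seed=seed, require_parseable=False
            )
            seqs = [tokenize(s) for s in data.smiles]
            cfg = SearchConfig(max_substring_len=4)
            gs = GreedySearch(seqs, cfg)
            assert gs.encoded.n_tokens <= 200
            while True:
                oracle = greedy_step_oracle(gs.encoded, gs.codebook, gs.model, cfg)
                record = gs.step()
                if record is None:
                    assert oracle is None
                    break
                assert oracle is not None
                assert oracle[0] == record.substring
                assert oracle[1] == pytest.approx(record.delta_bits, abs=1e-6)
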