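"""Greedy MML codebook induction over a tokenized SMILES dataset.

Each iteration enumerates every contiguous token run (length 2..max_len) of
the *current* encoded stream — so candidates may contain earlier codewords
and the effective substructure length is unbounded — filters them through
the substructure validity rules (applied to the candidate's base-symbol
expansion), scores the exact change in total message length that replacing
all non-overlapping occurrences would produce, and accepts the best
candidate if and only if it strictly shortens the message.

Scoring is exact, not heuristic: the incremental scorer reproduces, to float
precision, the full three-part recomputation that :func:`greedy_step_oracle`
performs from scratch.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.special import gammaln

from . import codec
from .codec import Codebook, CodebookEntry, EncodedDataset
from .message_length import (
    MessageLength,
    SymbolModel,
    codebook_size_cost,
    substring_cost,
    total_length,
)
from .smiles_text import (
    DEFAULT_FORBIDDEN,
    SymbolSequence,
    detokenize,
    expand,
    is_valid_substring,
)

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "TraceRecord",
    "GreedySearch",
    "run",
    "score_candidate",
    "greedy_step_oracle",
]

_LN2 = math.log(2.0)

#: Numerical resolution below which a message-length change is treated as
#: zero; protects termination against float noise in near-tie deltas.
ACCEPT_TOL = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the greedy search.

    ``max_substring_len`` is the enumeration cap (the large-corpus runs in
    the field use 8); nested codewords let final substructures exceed it.
    ``min_occurrences`` prunes candidates that occur once: a single
    occurrence can never amortise its codebook entry.
    """

    max_substring_len: int = 8
    max_iterations: int | None = None
    min_occurrences: int = 2
    log_star_convention: str = "anchored"
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_substring_len < 2:
            raise ValueError("max_substring_len must be >= 2 for any candidate to help")
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    substring: str
    delta_bits: float
    total_bits: float
    codebook_size: int


@dataclass
class SearchTrace:
    """Per-iteration record of accepted substitutions."""

    initial_bits: float = 0.0
    records: list[TraceRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "substring": r.substring,
                    "delta_bits": r.delta_bits,
                    "total_bits": r.total_bits,
                    "codebook_size": r.codebook_size,
                }
                for r in self.records
            ],
            columns=["iteration", "substring", "delta_bits", "total_bits", "codebook_size"],
        )


def _enumerate_candidates(
    encoded: EncodedDataset, max_len: int
) -> dict[tuple[str, ...], int]:
    """Map candidate token tuple -> non-overlapping leftmost occurrence count.

    Position lists are gathered molecule by molecule, left to right, so the
    greedy non-overlap count can be computed in one pass per candidate.
    """
    positions: dict[tuple[str, ...], list[tuple[int, int]]] = {}
    for mi, mol in enumerate(encoded.molecules):
        n = len(mol)
        for i in range(n - 1):
            for k in range(2, min(max_len, n - i) + 1):
                t = tuple(mol[i : i + k])
                positions.setdefault(t, []).append((mi, i))
    counts: dict[tuple[str, ...], int] = {}
    for t, pos in positions.items():
        k = len(t)
        c = 0
        last_mol, last_end = -1, -1
        for mi, i in pos:
            if mi != last_mol or i >= last_end:
                c += 1
                last_mol, last_end = mi, i + k
        counts[t] = c
    return counts


class _Scorer:
    """Exact incremental message-length deltas for one search state."""

    def __init__(
        self,
        encoded: EncodedDataset,
        codebook: Codebook,
        model: SymbolModel,
        config: SearchConfig,
    ):
        self.encoded = encoded
        self.codebook = codebook
        self.model = model
        self.config = config
        self.refresh()

    def refresh(self) -> None:
        conv = self.config.log_star_convention
        self.counts = Counter(
            {t: c for t, c in self.encoded.vocab_counts.items() if c > 0}
        )
        self.n_tokens = sum(self.counts.values())
        self.n_distinct = len(self.counts)
        self.sum_lgamma = float(sum(gammaln(c + 1) for c in self.counts.values()))
        self.entry_costs = {
            e.codeword: substring_cost(e.expansion, self.model, conv)
            for e in self.codebook.entries
        }
        self.defs = self.codebook.definitions
        self.p1 = codebook_size_cost(len(self.codebook), conv) + sum(
            self.entry_costs.values()
        )
        self.total = self._total_from(self.n_tokens, self.n_distinct, self.sum_lgamma, self.p1)

    @staticmethod
    def _total_from(n: int, m: int, sum_lg: float, p1: float) -> float:
        p3 = (gammaln(n + 1) - sum_lg) / _LN2
        if m >= 2:
            p2 = (
                (gammaln(n + m) - gammaln(m) - sum_lg) / _LN2
                + 0.5 * math.log2((m - 1) * math.pi)
                - 0.4
            )
        else:
            p2 = 0.0
        return float(p1 + p2 + p3)

    def expansion_of(self, tokens: Sequence[str]) -> tuple[str, ...]:
        return expand(tokens, self.defs)

    def delta(self, tokens: tuple[str, ...], occ: int) -> float:
        """dM for replacing ``occ`` non-overlapping occurrences of ``tokens``
        by a fresh codeword, including nested-entry count decrements and
        removal of entries whose count reaches zero."""
        conv = self.config.log_star_convention
        mult = Counter(tokens)
        n_new = self.n_tokens - occ * (len(tokens) - 1)
        m_new = self.n_distinct + 1
        sum_lg = self.sum_lgamma + float(gammaln(occ + 1))
        p1_new = self.p1 - codebook_size_cost(len(self.codebook), conv)
        n_entries = len(self.codebook)
        for tok, k in mult.items():
            c_old = self.counts[tok]
            c_new = c_old - occ * k
            sum_lg += float(gammaln(c_new + 1) - gammaln(c_old + 1))
            if c_new == 0:
                m_new -= 1
                if tok in self.entry_costs:
                    p1_new -= self.entry_costs[tok]
                    n_entries -= 1
        expansion = self.expansion_of(tokens)
        p1_new += substring_cost(expansion, self.model, conv)
        p1_new += codebook_size_cost(n_entries + 1, conv)
        return self._total_from(n_new, m_new, sum_lg, p1_new) - self.total


def score_candidate(
    encoded: EncodedDataset,
    codebook: Codebook,
    model: SymbolModel,
    candidate: Sequence[str],
    config: SearchConfig | None = None,
) -> float:
    """Side-effect-free dM (bits) for one candidate on the given state.

    Raises if the candidate's expansion fails the validity filter or the
    candidate does not occur often enough — the search filters first.
    """
    config = config or SearchConfig()
    tokens = tuple(candidate.tokens if hasattr(candidate, "tokens") else candidate)
    scorer = _Scorer(encoded, codebook, model, config)
    expansion = scorer.expansion_of(tokens)
    if not is_valid_substring(expansion, config.forbidden):
        raise ValueError(f"candidate {detokenize(expansion)!r} fails the validity filter")
    occ = codec.count_nonoverlapping(encoded, tokens)
    if occ < config.min_occurrences:
        raise ValueError(
            f"candidate occurs {occ} time(s), fewer than min_occurrences="
            f"{config.min_occurrences}"
        )
    return scorer.delta(tokens, occ)


def _sort_key(delta: float, expansion: tuple[str, ...]) -> tuple:
    """Deterministic candidate ordering: best dM first, ties broken towards
    the longer expansion, then lexicographically on its text."""
    return (round(delta, 9), -len(expansion), detokenize(expansion))


def _best_candidate(scorer: _Scorer, config: SearchConfig):
    cands = _enumerate_candidates(scorer.encoded, config.max_substring_len)
    best = None
    for tokens, occ in cands.items():
        if occ < config.min_occurrences:
            continue
        expansion = scorer.expansion_of(tokens)
        if not is_valid_substring(expansion, config.forbidden):
            continue
        d = scorer.delta(tokens, occ)
        key = _sort_key(d, expansion)
        if best is None or key < best[0]:
            best = (key, tokens, occ, d)
    return best


class GreedySearch:
    """Step-wise driver of the greedy loop.

    Exposes the state between iterations (``encoded``, ``codebook``,
    ``trace``) so callers can decode, audit or oracle-check after every
    accepted substitution; :func:`run` is the run-to-convergence wrapper.
    """

    def __init__(
        self,
        dataset: Sequence[SymbolSequence],
        config: SearchConfig | None = None,
        model: SymbolModel | None = None,
    ):
        if not dataset:
            raise ValueError("dataset is empty")
        self.config = config or SearchConfig()
        self.model = model if model is not None else SymbolModel.from_sequences(dataset)
        self.encoded = codec.encode_identity(dataset)
        self.codebook = Codebook()
        self._scorer = _Scorer(self.encoded, self.codebook, self.model, self.config)
        self.trace = SearchTrace(initial_bits=self._scorer.total)
        self._next_id = 1

    @property
    def total_bits(self) -> float:
        return self._scorer.total

    def step(self) -> TraceRecord | None:
        """Accept the best strictly-improving candidate, or return None."""
        best = _best_candidate(self._scorer, self.config)
        if best is None:
            return None
        _, tokens, occ, delta = best
        if delta >= -ACCEPT_TOL:
            return None
        codeword = codec.make_codeword(self._next_id)
        self._next_id += 1
        codec.substitute(self.encoded, tokens, codeword, inplace=True)
        self.codebook.entries.append(
            CodebookEntry(codeword=codeword, expansion=self._scorer.expansion_of(tokens))
        )
        codec.decrement_nested(self.codebook, self.encoded)
        self._scorer.refresh()
        record = TraceRecord(
            iteration=len(self.trace.records) + 1,
            substring=detokenize(self.codebook.entries[-1].expansion),
            delta_bits=delta,
            total_bits=self._scorer.total,
            codebook_size=len(self.codebook),
        )
        self.trace.records.append(record)
        return record

    def solve(self) -> None:
        while (
            self.config.max_iterations is None
            or len(self.trace.records) < self.config.max_iterations
        ):
            if self.step() is None:
                break


def run(
    dataset: Sequence[SymbolSequence],
    config: SearchConfig | None = None,
    model: SymbolModel | None = None,
) -> tuple[Codebook, EncodedDataset, SearchTrace]:
    """The full greedy loop: enumerate, filter, score, accept while improving.

    The base-symbol model is the frozen relative-frequency code over the
    original dataset unless supplied. Returns the final codebook, the
    encoded dataset (losslessly decodable) and the per-iteration trace.
    """
    gs = GreedySearch(dataset, config, model)
    gs.solve()
    return gs.codebook, gs.encoded, gs.trace


# ---------------------------------------------------------------------------
# test oracle


def greedy_step_oracle(
    encoded: EncodedDataset,
    codebook: Codebook,
    model: SymbolModel,
    config: SearchConfig | None = None,
    max_tokens: int = 200,
):
    """Certify one greedy step by brute force.

    Exhaustively scores every valid candidate by *actually performing* the
    substitution on a copy of the state and recomputing all three message
    parts from scratch; returns ``(expansion_text, delta_bits)`` of the
    argmin under the shared tie-break, or ``None`` when no candidate
    improves. Refuses large states: this path is deliberately slow.
    """
    config = config or SearchConfig()
    if encoded.n_tokens > max_tokens:
        raise ValueError(
            f"oracle refuses states larger than {max_tokens} tokens "
            f"(got {encoded.n_tokens})"
        )
    conv = config.log_star_convention
    before = total_length(codebook, encoded, model, conv).total
    defs = codebook.definitions
    cands = _enumerate_candidates(encoded, config.max_substring_len)
    best = None
    for tokens, occ in cands.items():
        if occ < config.min_occurrences:
            continue
        expansion = expand(tokens, defs)
        if not is_valid_substring(expansion, config.forbidden):
            continue
        trial_enc = encoded.copy()
        trial_book = Codebook(
            entries=[
                CodebookEntry(e.codeword, e.expansion, e.count)
                for e in codebook.entries
            ]
        )
        codeword = codec.make_codeword(10_000)  # fresh in any test state
        codec.substitute(trial_enc, tokens, codeword, inplace=True)
        trial_book.entries.append(CodebookEntry(codeword=codeword, expansion=expansion))
        codec.decrement_nested(trial_book, trial_enc)
        delta = total_length(trial_book, trial_enc, model, conv).total - before
        key = _sort_key(delta, expansion)
        if best is None or key < best[0]:
            best = (key, expansion, delta)
    if best is None or best[2] >= -ACCEPT_TOL:
        return None
    return detokenize(best[1]), best[2]
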