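"""SMILES symbol sequences, substring enumeration and the substructure validity filter.

All downstream machinery (compression, fingerprinting) operates on *token*
sequences rather than raw character strings. Tokenization is character-level
except for the two-letter organic-subset atoms ``Cl`` and ``Br`` and for
``%nn`` ring-closure labels, each of which is a single symbol. The interiors
of bracket atoms remain character tokens: the filter rules below reason about
individual characters (brackets, digits, ``@``).
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SymbolSequence",
    "Substring",
    "tokenize",
    "detokenize",
    "canonicalize",
    "enumerate_substrings",
    "is_valid_substring",
    "expand",
    "ATOM_CHARS",
    "BOND_CHARS",
    "DEFAULT_FORBIDDEN",
]

# Characters a token may start with.  Atom tokens are alphabetic (organic and
# aromatic subset atoms, bracket-atom element letters and H); everything else
# is structural punctuation.
ATOM_CHARS = frozenset(string.ascii_letters)
BOND_CHARS = frozenset("=#-/\\")
_STEREO = "@"
_RING_DIGITS = frozenset(string.digits)
_STRUCTURAL = frozenset("()[]") | BOND_CHARS | {_STEREO, "%", "+", ".", "*", ":"}
_TWO_LETTER = ("Cl", "Br")

#: SMILES disconnection character: joins unconnected fragments, never part of
#: a substructure, hence banned from valid substrings.
DEFAULT_FORBIDDEN = frozenset(".")


@dataclass(frozen=True)
class SymbolSequence:
    """A tokenized SMILES string.

    ``"".join(tokens)`` reproduces the source text byte-for-byte.
    """

    tokens: tuple[str, ...]
    source_id: str | None = None

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)


@dataclass
class Substring:
    """A contiguous run of SMILES symbols with its dataset occurrence count."""

    tokens: tuple[str, ...]
    occurrence_count: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("a substring has at least one token")

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)


class TokenizationError(ValueError):
    """Raised when a SMILES string contains an unrecognized character."""

    def __init__(self, smiles: str, position: int):
        self.position = position
        super().__init__(
            f"unrecognized character {smiles[position]!r} at position "
            f"{position} in {smiles!r}"
        )


def tokenize(smiles: str, source_id: str | None = None) -> SymbolSequence:
    """Split a SMILES string into alphabet symbols.

    Two-letter organic-subset atoms (Cl, Br) and ``%nn`` ring labels are
    single tokens; every other recognized character is one token.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if smiles[i : i + 2] in _TWO_LETTER:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "%":
            # %nn two-digit ring closure: one symbol, else digit pairings are
            # meaningless.
            if i + 2 < n + 1 and smiles[i + 1 : i + 3].isdigit():
                tokens.append(smiles[i : i + 3])
                i += 3
            else:
                raise TokenizationError(smiles, i)
        elif ch in ATOM_CHARS or ch in _RING_DIGITS or ch in _STRUCTURAL:
            tokens.append(ch)
            i += 1
        else:
            raise TokenizationError(smiles, i)
    return SymbolSequence(tokens=tuple(tokens), source_id=source_id)


def detokenize(seq: SymbolSequence | Sequence[str]) -> str:
    tokens = seq.tokens if isinstance(seq, SymbolSequence) else seq
    return "".join(tokens)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES via RDKit; raises ValueError on unparseable input."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def enumerate_substrings(
    dataset: Iterable[SymbolSequence],
    max_len: int,
    min_len: int = 1,
) -> list[Substring]:
    """Every contiguous token run of length ``min_len..max_len``, with counts.

    Runs never span molecule boundaries. Counts are raw position counts
    (overlaps included); callers needing the non-overlapping substitution
    count recount under their own policy.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    counts: Counter[tuple[str, ...]] = Counter()
    for seq in dataset:
        toks = seq.tokens
        n = len(toks)
        for k in range(min_len, min(max_len, n) + 1):
            for i in range(n - k + 1):
                counts[toks[i : i + k]] += 1
    return [Substring(tokens=t, occurrence_count=c) for t, c in counts.items()]


def _is_atom(token: str) -> bool:
    return token[0] in ATOM_CHARS


def is_valid_substring(
    s: Substring | Sequence[str],
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN,
) -> bool:
    """Does this token run correspond to a chemically meaningful substructure?

    Rules (total function, never raises):

    1. Brackets: square brackets must pair up exactly (a truncated bracket
       atom is meaningless). A round ``)`` must close a ``(`` opened inside
       the substring; a trailing unclosed ``(`` is tolerated — a branch may
       continue past the substring's right edge — but only if the substring
       contains at least one atom.
    2. Every bond character (``= # - / \\``) and every stereocentre ``@``
       must be adjacent to at least one atom token within the substring.
    3. Every ring-closure label (digit or ``%nn``) must occur an even number
       of times, pairing its opening and closing bond. Digits inside a
       matched bracket atom (H-count, charge magnitude, isotope) are exempt.
    4. The disconnection character ``.`` is forbidden.
    """
    tokens = s.tokens if isinstance(s, Substring) else tuple(s)

    # rule 4
    if any(t in forbidden for t in tokens):
        return False

    # rule 1 — square brackets strict, round brackets right-extendable
    depth_round = 0
    depth_square = 0
    in_bracket_atom = [False] * len(tokens)
    for i, t in enumerate(tokens):
        if t == "[":
            depth_square += 1
            if depth_square > 1:
                return False
            in_bracket_atom[i] = True
        elif t == "]":
            depth_square -= 1
            if depth_square < 0:
                return False
            in_bracket_atom[i] = True
        else:
            in_bracket_atom[i] = depth_square > 0
            if t == "(":
                depth_round += 1
            elif t == ")":
                depth_round -= 1
                if depth_round < 0:
                    return False
    if depth_square != 0:
        return False
    if depth_round > 0 and not any(_is_atom(t) for t in tokens):
        return False

    # rule 2 — bond/stereo characters need an adjacent atom
    for i, t in enumerate(tokens):
        if t in BOND_CHARS or t == _STEREO:
            left_atom = i > 0 and _is_atom(tokens[i - 1])
            right_atom = i + 1 < len(tokens) and _is_atom(tokens[i + 1])
            if not (left_atom or right_atom):
                return False

    # rule 3 — ring-closure labels pair up (bracket-atom digits exempt)
    ring_counts: Counter[str] = Counter()
    for i, t in enumerate(tokens):
        if in_bracket_atom[i]:
            continue
        if t in _RING_DIGITS or t.startswith("%"):
            ring_counts[t] += 1
    if any(c % 2 for c in ring_counts.values()):
        return False

    return True


def expand(
    candidate_tokens: Sequence[str],
    definitions: dict[str, tuple[str, ...]],
) -> tuple[str, ...]:
    """Recursively replace codeword tokens by their substrings.

    ``definitions`` maps codeword token -> token tuple (which may itself
    contain codewords). The result contains only base alphabet symbols.
    Raises ``KeyError``-derived errors never; an unknown codeword-looking
    token raises ``ValueError`` naming it.
    """
    out: list[str] = []
    for tok in candidate_tokens:
        if tok in definitions:
            out.extend(expand(definitions[tok], definitions))
        elif tok.startswith("<") and tok.endswith(">"):
            raise ValueError(f"unknown codeword token {tok!r}")
        else:
            out.append(tok)
    return tuple(out)
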