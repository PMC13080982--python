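"""Codebook maintenance, occurrence substitution and lossless decoding.

The encoded dataset is a per-molecule token stream over a vocabulary of
codewords plus residual base symbols. Substitution replaces non-overlapping,
leftmost-first occurrences of a candidate with a fresh codeword; the codebook
stores each codeword's *fully expanded* base-symbol substring so that
decoding is a single replacement pass and substring transmission costs are
well defined regardless of later entry removals.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .smiles_text import SymbolSequence, detokenize, tokenize

__all__ = [
    "CodebookEntry",
    "Codebook",
    "EncodedDataset",
    "encode_identity",
    "count_nonoverlapping",
    "find_nonoverlapping",
    "substitute",
    "decrement_nested",
    "decode",
]

CODEBOOK_JSON_VERSION = 1


def make_codeword(index: int) -> str:
    """Fresh symbol outside the SMILES alphabet, serialized as ``<k>``."""
    return f"<{index}>"


def is_codeword(token: str) -> bool:
    return token.startswith("<") and token.endswith(">")


@dataclass
class CodebookEntry:
    """One discovered substructure.

    ``expansion`` is the base-symbol token tuple the codeword stands for;
    ``count`` is the number of times the codeword appears in the current
    encoded stream (the s_m of this vocabulary item).
    """

    codeword: str
    expansion: tuple[str, ...]
    count: int = 0

    @property
    def smiles(self) -> str:
        return detokenize(self.expansion)


@dataclass
class Codebook:
    """Ordered set of entries; order is discovery iteration."""

    entries: list[CodebookEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def definitions(self) -> dict[str, tuple[str, ...]]:
        return {e.codeword: e.expansion for e in self.entries}

    def entry_for(self, codeword: str) -> CodebookEntry:
        for e in self.entries:
            if e.codeword == codeword:
                return e
        raise KeyError(codeword)

    def probabilities(self, encoded: "EncodedDataset") -> dict[str, float]:
        """Multinomial probabilities over the full vocabulary (entries plus
        residual base symbols); they sum to 1 by construction."""
        n = encoded.n_tokens
        return {tok: c / n for tok, c in encoded.vocab_counts.items() if c > 0}

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, encoded: "EncodedDataset | None" = None) -> dict:
        probs = self.probabilities(encoded) if encoded is not None else {}
        return {
            "version": CODEBOOK_JSON_VERSION,
            "entries": [
                {
                    "substring": e.smiles,
                    "codeword": e.codeword,
                    "count": e.count,
                    "probability": probs.get(e.codeword),
                }
                for e in self.entries
            ],
            "base_symbol_probs": {
                tok: p for tok, p in probs.items() if not is_codeword(tok)
            },
        }

    def save(self, path, encoded: "EncodedDataset | None" = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(encoded), fh, indent=1)

    @classmethod
    def from_json(cls, obj: dict) -> "Codebook":
        entries = [
            CodebookEntry(
                codeword=e["codeword"],
                expansion=tokenize(e["substring"]).tokens,
                count=int(e["count"]),
            )
            for e in obj["entries"]
        ]
        return cls(entries=entries)

    @classmethod
    def load(cls, path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


@dataclass
class EncodedDataset:
    """Per-molecule token streams over codewords + residual base symbols."""

    molecules: list[list[str]]

    @property
    def molecule_lengths(self) -> list[int]:
        return [len(m) for m in self.molecules]

    @property
    def stream(self) -> list[str]:
        return [t for mol in self.molecules for t in mol]

    @property
    def vocab_counts(self) -> Counter[str]:
        c: Counter[str] = Counter()
        for mol in self.molecules:
            c.update(mol)
        return c

    @property
    def n_tokens(self) -> int:
        return sum(len(m) for m in self.molecules)

    @property
    def n_distinct(self) -> int:
        return len({t for mol in self.molecules for t in mol})

    def copy(self) -> "EncodedDataset":
        return EncodedDataset(molecules=[list(m) for m in self.molecules])


def encode_identity(dataset: Iterable[SymbolSequence]) -> EncodedDataset:
    """The raw tokenization: identity coding under an empty codebook."""
    return EncodedDataset(molecules=[list(seq.tokens) for seq in dataset])


def find_nonoverlapping(mol: Sequence[str], pattern: Sequence[str]) -> list[int]:
    """Leftmost-first non-overlapping start positions of ``pattern``."""
    hits: list[int] = []
    k = len(pattern)
    i = 0
    n = len(mol)
    pat = tuple(pattern)
    while i <= n - k:
        if tuple(mol[i : i + k]) == pat:
            hits.append(i)
            i += k
        else:
            i += 1
    return hits


def count_nonoverlapping(
    encoded: EncodedDataset, pattern: Sequence[str]
) -> int:
    return sum(len(find_nonoverlapping(m, pattern)) for m in encoded.molecules)


def substitute(
    encoded: EncodedDataset,
    candidate: Sequence[str],
    codeword: str,
    inplace: bool = False,
) -> EncodedDataset:
    """Replace all non-overlapping leftmost occurrences of ``candidate``.

    Raises ``ValueError`` if the candidate does not occur at all: the search
    should never propose such a candidate.
    """
    pattern = tuple(candidate.tokens if hasattr(candidate, "tokens") else candidate)
    out = encoded if inplace else encoded.copy()
    k = len(pattern)
    replaced = 0
    for mi, mol in enumerate(out.molecules):
        hits = find_nonoverlapping(mol, pattern)
        if not hits:
            continue
        new_mol: list[str] = []
        prev = 0
        for h in hits:
            new_mol.extend(mol[prev:h])
            new_mol.append(codeword)
            prev = h + k
        new_mol.extend(mol[prev:])
        out.molecules[mi] = new_mol
        replaced += len(hits)
    if replaced == 0:
        raise ValueError(f"candidate {pattern!r} does not occur in the dataset")
    return out


def decrement_nested(codebook: Codebook, encoded: EncodedDataset) -> Codebook:
    """Synchronise entry counts with the stream; drop entries at zero.

    When a newly added substring contains an existing codeword, substitution
    consumes instances of that codeword, so its stream count falls; an entry
    whose codeword no longer appears anywhere carries no information and is
    removed from the codebook (and thereby from the vocabulary). A negative
    recount is an internal-consistency error.
    """
    counts = encoded.vocab_counts
    kept: list[CodebookEntry] = []
    for e in codebook.entries:
        c = counts.get(e.codeword, 0)
        if c < 0:  # pragma: no cover - Counter never yields negatives
            raise RuntimeError(f"negative count for {e.codeword}")
        e.count = c
        if c > 0:
            kept.append(e)
    codebook.entries = kept
    return codebook


def decode(encoded: EncodedDataset, codebook: Codebook) -> list[str]:
    """Expand every codeword and rejoin molecules; exact inverse of encoding."""
    defs = codebook.definitions
    out: list[str] = []
    for mol in encoded.molecules:
        parts: list[str] = []
        for tok in mol:
            if tok in defs:
                parts.extend(defs[tok])
            elif is_codeword(tok):
                raise ValueError(f"dangling codeword {tok!r} not in codebook")
            else:
                parts.append(tok)
        out.append("".join(parts))
    return out
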