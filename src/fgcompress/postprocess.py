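"""Post-processing of discovered substrings: SMARTS conversion and
ring-label deduplication.

A discovered substring is *convertible* if it is already a valid SMARTS
pattern or becomes one by adding the any-atom wildcard ``*`` at the
beginning, the end, or both. Substrings identical up to renumbering of
ring-closure labels (c1ccccc1 vs c2ccccc2) are collapsed, keeping the
earliest-discovered representative. Semantic drift between SMILES and
SMARTS (aromatic lowercase and the like) is accepted as-is: this is a
syntactic convertibility check, not an equivalence proof.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .codec import Codebook
from .smiles_text import tokenize

__all__ = ["to_smarts", "canonical_ring_relabel", "dedup_ring_labels", "process_codebook"]

_RING_DIGITS = set("0123456789")


def to_smarts(substring_text: str) -> str | None:
    """First parseable of [s, ``*``+s, s+``*``, ``*``+s+``*``], else None."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    for variant in (
        substring_text,
        "*" + substring_text,
        substring_text + "*",
        "*" + substring_text + "*",
    ):
        if Chem.MolFromSmarts(variant) is not None:
            return variant
    return None


def canonical_ring_relabel(substring_text: str) -> str:
    """Renumber ring-closure labels in order of first appearance (1, 2, ...).

    Digits inside matched bracket atoms are left alone; labels >= 10 are
    emitted in ``%nn`` form.
    """
    tokens = tokenize(substring_text).tokens
    mapping: dict[str, str] = {}
    out: list[str] = []
    depth_sq = 0
    for t in tokens:
        if t == "[":
            depth_sq += 1
        elif t == "]":
            depth_sq = max(0, depth_sq - 1)
        is_ring = depth_sq == 0 and (t in _RING_DIGITS or t.startswith("%"))
        if is_ring:
            if t not in mapping:
                k = len(mapping) + 1
                mapping[t] = str(k) if k < 10 else f"%{k:02d}"
            out.append(mapping[t])
        else:
            out.append(t)
    return "".join(out)


def dedup_ring_labels(substrings: Sequence[str]) -> list[str]:
    """Collapse substrings identical up to ring-label renumbering.

    Earliest occurrence wins; order-stable and idempotent.
    """
    seen: set[str] = set()
    kept: list[str] = []
    for s in substrings:
        key = canonical_ring_relabel(s)
        if key not in seen:
            seen.add(key)
            kept.append(s)
    return kept


def process_codebook(codebook: Codebook, dedup: bool = True) -> pd.DataFrame:
    """Tabulate discovered substructures with SMARTS convertibility.

    Columns: rank (discovery order, 1-based), smiles_substring, smarts,
    convertible_flag. With ``dedup``, ring-relabelled duplicates are dropped
    (keeping the earliest) after the convertibility test, mirroring the
    filter-then-dedup order of the reporting pipeline.
    """
    rows = []
    seen: set[str] = set()
    for rank, entry in enumerate(codebook.entries, start=1):
        s = entry.smiles
        smarts = to_smarts(s)
        if dedup:
            key = canonical_ring_relabel(s)
            if key in seen:
                continue
            seen.add(key)
        rows.append(
            {
                "rank": rank,
                "smiles_substring": s,
                "smarts": smarts if smarts is not None else "",
                "convertible_flag": smarts is not None,
            }
        )
    return pd.DataFrame(rows, columns=["rank", "smiles_substring", "smarts", "convertible_flag"])
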