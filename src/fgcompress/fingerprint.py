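"""Count-based substructure fingerprints over a learned codebook.

A molecule maps to a fixed-length integer vector: index i holds the number
of times codebook substructure i occurs in the molecule. Counting operates
on the canonical-SMILES token stream with the same non-overlapping,
leftmost-first policy as the codec, so a singleton dataset fingerprints
exactly as the codec would substitute. The representation is lossy by
design — connectivity between substructures is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codec import Codebook, find_nonoverlapping
from .smiles_text import canonicalize, tokenize

__all__ = ["FingerprintMatrix", "fingerprint", "fingerprint_dataset"]


@dataclass
class FingerprintMatrix:
    """Molecules x substructures integer count matrix in codebook order."""

    counts: np.ndarray
    columns: list[str]
    row_ids: list[str]
    errors: list[tuple[int, str, str]]  # (row index in input, smiles, message)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, columns=self.columns, index=self.row_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def fingerprint(
    molecule_smiles: str,
    codebook: Codebook,
    canonical: bool = True,
    mode: str = "token",
) -> np.ndarray:
    """Integer count vector of codebook substructures in one molecule.

    ``mode="token"`` (default) counts SMILES-substring occurrences on the
    token stream; ``mode="smarts"`` counts RDKit substructure matches of the
    wildcard-converted SMARTS patterns instead. The two modes must never be
    mixed within one matrix.
    """
    if mode == "token":
        text = canonicalize(molecule_smiles) if canonical else molecule_smiles
        toks = tokenize(text).tokens
        return np.array(
            [len(find_nonoverlapping(toks, e.expansion)) for e in codebook.entries],
            dtype=np.int64,
        )
    elif mode == "smarts":
        from rdkit import Chem

        from .postprocess import to_smarts

        mol = Chem.MolFromSmiles(molecule_smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {molecule_smiles!r}")
        counts = []
        for e in codebook.entries:
            patt_text = to_smarts(e.smiles)
            if patt_text is None:
                counts.append(0)
                continue
            patt = Chem.MolFromSmarts(patt_text)
            counts.append(len(mol.GetSubstructMatches(patt)))
        return np.array(counts, dtype=np.int64)
    raise ValueError(f"unknown fingerprint mode {mode!r}")


def fingerprint_dataset(
    smiles_list: Sequence[str],
    codebook: Codebook,
    canonical: bool = True,
    mode: str = "token",
) -> FingerprintMatrix:
    """Fingerprint every molecule; per-molecule failures are collected and
    reported while the run continues."""
    if not smiles_list:
        raise ValueError("empty molecule list")
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    errors: list[tuple[int, str, str]] = []
    for i, smi in enumerate(smiles_list):
        try:
            rows.append(fingerprint(smi, codebook, canonical=canonical, mode=mode))
            row_ids.append(smi)
        except Exception as exc:  # noqa: BLE001 - collected, reported, run continues
            errors.append((i, smi, str(exc)))
    counts = (
        np.vstack(rows)
        if rows
        else np.zeros((0, len(codebook.entries)), dtype=np.int64)
    )
    return FingerprintMatrix(
        counts=counts,
        columns=[e.smiles for e in codebook.entries],
        row_ids=row_ids,
        errors=errors,
    )
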