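"""Model/Results surface for MML substructure discovery.

``FGCompress`` holds a SMILES dataset plus search settings; ``fit()`` runs
the greedy minimum-message-length codebook search and returns a
``CompressionResults`` object carrying the codebook, the losslessly encoded
dataset, the per-iteration trace and the message-length accounting, with
fingerprinting and substructure reporting hanging off it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import codec, search
from .codec import Codebook, EncodedDataset
from .fingerprint import FingerprintMatrix, fingerprint, fingerprint_dataset
from .message_length import MessageLength, SymbolModel, total_length
from .postprocess import process_codebook
from .search import SearchConfig, SearchTrace
from .smiles_text import DEFAULT_FORBIDDEN, SymbolSequence, canonicalize, tokenize

__all__ = ["FGCompress", "CompressionResults"]


class FGCompress:
    """Greedy MML substructure-discovery model for a SMILES dataset.

    Parameters
    ----------
    smiles : sequence of str
        One SMILES per molecule.
    canonicalize : bool
        Canonicalize inputs through RDKit before tokenization (default).
        Disable for toy or synthetic token streams whose literal text is the
        object of study.
    max_substring_len, max_iterations, min_occurrences, log_star_convention :
        Search settings; see :class:`fgcompress.search.SearchConfig`.
    """

    def __init__(
        self,
        smiles: Sequence[str],
        canonicalize: bool = True,
        max_substring_len: int = 8,
        max_iterations: int | None = None,
        min_occurrences: int = 2,
        log_star_convention: str = "anchored",
        forbidden: frozenset[str] = DEFAULT_FORBIDDEN,
    ):
        if not smiles:
            raise ValueError("empty dataset")
        self.input_smiles = list(smiles)
        self.canonical = canonicalize
        self.config = SearchConfig(
            max_substring_len=max_substring_len,
            max_iterations=max_iterations,
            min_occurrences=min_occurrences,
            log_star_convention=log_star_convention,
            forbidden=forbidden,
        )
        texts = (
            [canonicalize_smiles(s) for s in smiles] if canonicalize else self.input_smiles
        )
        self.smiles = texts
        self.dataset: list[SymbolSequence] = [
            tokenize(s, source_id=str(i)) for i, s in enumerate(texts)
        ]
        self.symbol_model = SymbolModel.from_sequences(self.dataset)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_file(cls, path, **kwargs) -> "FGCompress":
        """One SMILES per line; blank lines and ``#`` comments skipped."""
        with open(path, encoding="utf-8") as fh:
            smiles = [
                line.strip()
                for line in fh
                if line.strip() and not line.startswith("#")
            ]
        return cls(smiles, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, smiles_col: str = "smiles", **kwargs) -> "FGCompress":
        return cls(df[smiles_col].astype(str).tolist(), **kwargs)

    # -- estimation --------------------------------------------------------
    def fit(self) -> "CompressionResults":
        codebook, encoded, trace = search.run(
            self.dataset, self.config, model=self.symbol_model
        )
        return CompressionResults(self, codebook, encoded, trace)


def canonicalize_smiles(s: str) -> str:
    return canonicalize(s)


class CompressionResults:
    """Fitted codebook with its message-length accounting."""

    def __init__(
        self,
        model: FGCompress,
        codebook: Codebook,
        encoded: EncodedDataset,
        trace: SearchTrace,
    ):
        self.model = model
        self.codebook = codebook
        self.encoded = encoded
        self.trace = trace
        self.message_length: MessageLength = total_length(
            codebook, encoded, model.symbol_model, model.config.log_star_convention
        )
        self.baseline_bits: float = trace.initial_bits

    # -- headline quantities ----------------------------------------------
    @property
    def n_iterations(self) -> int:
        return len(self.trace.records)

    @property
    def total_bits(self) -> float:
        return self.message_length.total

    @property
    def compression_ratio(self) -> float:
        """Fraction of the symbol-only message length saved by the codebook."""
        return 1.0 - self.total_bits / self.baseline_bits

    @property
    def trace_frame(self) -> pd.DataFrame:
        return self.trace.to_dataframe()

    # -- downstream views --------------------------------------------------
    def decode(self) -> list[str]:
        """Reconstruct the (canonicalized) input SMILES exactly."""
        return codec.decode(self.encoded, self.codebook)

    def substructures(self, dedup: bool = True) -> pd.DataFrame:
        """Discovered substructures with SMARTS convertibility, in discovery
        order, optionally deduplicated up to ring-label renumbering."""
        return process_codebook(self.codebook, dedup=dedup)

    def fingerprint(self, molecule_smiles: str, mode: str = "token") -> np.ndarray:
        return fingerprint(
            molecule_smiles, self.codebook, canonical=self.model.canonical, mode=mode
        )

    def fingerprint_dataset(
        self, smiles_list: Sequence[str] | None = None, mode: str = "token"
    ) -> FingerprintMatrix:
        if smiles_list is None:
            smiles_list = self.model.input_smiles
        return fingerprint_dataset(
            smiles_list, self.codebook, canonical=self.model.canonical, mode=mode
        )

    def save_codebook(self, path) -> None:
        self.codebook.save(path, self.encoded)

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 15) -> str:
        ml = self.message_length
        lines = [
            "FGCompress results",
            "==================",
            f"molecules:            {len(self.model.dataset)}",
            f"iterations accepted:  {self.n_iterations}",
            f"codebook size:        {len(self.codebook)}",
            f"baseline length:      {self.baseline_bits:.4f} bits (symbols only)",
            f"message length:       {ml.total:.4f} bits "
            f"(P1={ml.p1:.4f}, P2={ml.p2:.4f}, P3={ml.p3:.4f})",
            f"compression:          {100 * self.compression_ratio:.1f}%",
        ]
        if self.codebook.entries:
            lines.append("")
            lines.append(f"top substructures (discovery order, first {top}):")
            for i, e in enumerate(self.codebook.entries[:top], start=1):
                lines.append(f"  {i:3d}. {e.smiles}  (count {e.count})")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CompressionResults: {len(self.codebook)} substructures, "
            f"{self.total_bits:.1f} bits, {100 * self.compression_ratio:.1f}% saved>"
        )
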