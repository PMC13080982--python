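"""Synthetic SMILES datasets with planted, known substructure.

Every other stage of the package is testable offline against these
generators: scaffolds are random concatenations of a small curated list of
simple valid fragments (chains, benzene, short branches), which guarantees
parseability without chemistry heuristics, and a motif of interest is
planted at fragment boundaries in a controlled fraction of molecules. The
molecules make no claim to drug-likeness; they exercise the token
machinery, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .codec import find_nonoverlapping
from .smiles_text import tokenize

__all__ = ["PlantedDataset", "generate_planted", "generate_qsar", "DEFAULT_SCAFFOLDS"]

#: Simple fragments whose concatenation in any order is a parseable SMILES.
DEFAULT_SCAFFOLDS = (
    "C",
    "N",
    "O",
    "CC",
    "CO",
    "CN",
    "CCC",
    "C(C)",
    "C(O)",
    "C(N)",
    "c1ccccc1",
    "C1CC1",
)


@dataclass
class PlantedDataset:
    """Generated molecules plus their ground truth."""

    smiles: list[str]
    motif: str
    planted: list[bool]
    insertion_fragment_index: list[int | None] = field(default_factory=list)

    @property
    def n_planted(self) -> int:
        return sum(self.planted)


def _check_parseable(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def generate_planted(
    n_molecules: int,
    motif: str = "C(=O)N",
    plant_rate: float = 0.5,
    scaffold_alphabet: tuple[str, ...] = DEFAULT_SCAFFOLDS,
    seed: int = 0,
    min_fragments: int = 2,
    max_fragments: int = 4,
    max_retries: int = 50,
    require_parseable: bool = True,
) -> PlantedDataset:
    """Reproducible dataset with the motif in exactly ``ceil(rate * n)`` molecules.

    The motif is inserted at a random fragment boundary; unplanted molecules
    are resampled (bounded retries) if they contain the motif by accident,
    so ground-truth membership is exact.
    """
    if not 0 < plant_rate <= 1:
        raise ValueError("plant_rate must be in (0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    motif_tokens = tokenize(motif).tokens
    rng = np.random.default_rng(seed)
    n_planted = ceil(plant_rate * n_molecules)
    planted_idx = set(rng.choice(n_molecules, size=n_planted, replace=False).tolist())

    smiles: list[str] = []
    planted: list[bool] = []
    positions: list[int | None] = []
    for i in range(n_molecules):
        want_motif = i in planted_idx
        for attempt in range(max_retries):
            k = int(rng.integers(min_fragments, max_fragments + 1))
            frags = [str(rng.choice(scaffold_alphabet)) for _ in range(k)]
            pos: int | None = None
            if want_motif:
                pos = int(rng.integers(0, k + 1))
                frags.insert(pos, motif)
            text = "".join(frags)
            toks = tokenize(text).tokens
            occ = len(find_nonoverlapping(toks, motif_tokens))
            ok = occ >= 1 if want_motif else occ == 0
            if ok and (not require_parseable or _check_parseable(text)):
                smiles.append(text)
                planted.append(want_motif)
                positions.append(pos)
                break
        else:
            raise RuntimeError(
                f"could not generate molecule {i} within {max_retries} retries"
            )
    return PlantedDataset(
        smiles=smiles,
        motif=motif,
        planted=planted,
        insertion_fragment_index=positions,
    )


def generate_qsar(
    n: int,
    n_features_active: int = 3,
    effect_sizes: tuple[float, ...] = (2.0, -1.0, 0.5),
    noise_sd: float = 0.1,
    seed: int = 0,
    motifs: tuple[str, ...] = ("C(=O)N", "C(=O)O", "c1ccccc1"),
    require_parseable: bool = True,
    max_retries: int = 50,
) -> tuple[list[str], np.ndarray]:
    """Molecules whose activity is a linear function of planted-motif counts.

    ``activity = sum_i beta_i * count(motif_i) + Normal(0, noise_sd)``, with
    counts measured on the emitted SMILES, so a linear model on exact motif
    counts can recover the coefficients when ``noise_sd == 0``.
    """
    if n_features_active > len(motifs):
        raise ValueError("not enough motifs for the requested active features")
    if len(effect_sizes) < n_features_active:
        raise ValueError("need one effect size per active feature")
    if not all(np.isfinite(effect_sizes)):
        raise ValueError("effect sizes must be finite")
    rng = np.random.default_rng(seed)
    active = motifs[:n_features_active]
    betas = np.asarray(effect_sizes[:n_features_active], dtype=float)
    motif_tokens = [tokenize(m).tokens for m in active]

    smiles: list[str] = []
    counts = np.zeros((n, n_features_active), dtype=np.int64)
    for i in range(n):
        for attempt in range(max_retries):
            k = int(rng.integers(2, 5))
            frags = [str(rng.choice(DEFAULT_SCAFFOLDS)) for _ in range(k)]
            for m in active:
                for _ in range(int(rng.integers(0, 3))):
                    frags.insert(int(rng.integers(0, len(frags) + 1)), m)
            text = "".join(frags)
            if not require_parseable or _check_parseable(text):
                break
        else:
            raise RuntimeError(
                f"could not generate molecule {i} within {max_retries} retries"
            )
        toks = tokenize(text).tokens
        for j, mt in enumerate(motif_tokens):
            counts[i, j] = len(find_nonoverlapping(toks, mt))
        smiles.append(text)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    activities = counts @ betas + noise
    return smiles, activities
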