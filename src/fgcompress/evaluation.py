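"""QSAR evaluation harness: ridge regression over fingerprint features.

Protocol: five random 75/25 train/test splits; on each training set the
ridge penalty alpha is selected from {0.001, 0.01, 0.1, 1} by closed-form
leave-one-out cross-validation; the reported score is mean test MSE with its
standard error over the repeats. Count features enter unscaled.
Representations are compared across datasets with two-sided Wilcoxon
signed-rank tests (exact null distribution at small n) under
Benjamini-Hochberg correction at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvalProtocol",
    "RidgeScore",
    "EvalResult",
    "ridge_eval",
    "compare_representations",
    "maccs_features",
    "morgan_features",
]


@dataclass(frozen=True)
class EvalProtocol:
    """The repeated-split ridge protocol; identical splits are applied to
    every representation within a repeat (seeds are shared)."""

    split_fraction: float = 0.75
    repeats: int = 5
    alpha_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    seed: int = 0
    significance_level: float = 0.05

    @property
    def split_seeds(self) -> list[int]:
        rng = np.random.default_rng(self.seed)
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=self.repeats)]


@dataclass
class RidgeScore:
    mean_mse: float
    se_mse: float
    per_repeat: list[float]
    alphas_chosen: list[float]

    def __str__(self) -> str:
        return f"{self.mean_mse:.3f} ± {self.se_mse:.3f}"


def ridge_eval(
    features: np.ndarray,
    targets: np.ndarray,
    protocol: EvalProtocol | None = None,
) -> RidgeScore:
    """Mean test MSE ± SE of LOO-CV-tuned ridge over repeated splits."""
    protocol = protocol or EvalProtocol()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are misaligned")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant targets are degenerate for regression")
    mses: list[float] = []
    alphas: list[float] = []
    for s in protocol.split_seeds:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=protocol.split_fraction, random_state=s
        )
        model = RidgeCV(alphas=protocol.alpha_grid)  # cv=None: closed-form LOO
        model.fit(X_tr, y_tr)
        mses.append(float(mean_squared_error(y_te, model.predict(X_te))))
        alphas.append(float(model.alpha_))
    arr = np.asarray(mses)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return RidgeScore(
        mean_mse=float(arr.mean()), se_mse=se, per_repeat=mses, alphas_chosen=alphas
    )


@dataclass
class EvalResult:
    """Pairwise comparison of representations across datasets."""

    scores: pd.DataFrame  # datasets x representations, mean MSE
    pairwise: pd.DataFrame  # rep_a, rep_b, p_value, p_adjusted, reject, wins_a, wins_b

    def summary(self) -> str:
        lines = ["Mean test MSE by dataset and representation:", self.scores.round(4).to_string(), "", "Pairwise Wilcoxon signed-rank tests (Benjamini-Hochberg adjusted):"]
        lines.append(self.pairwise.round(4).to_string(index=False))
        return "\n".join(lines)


def compare_representations(
    results_by_dataset: Mapping[str, Mapping[str, float]],
    significance_level: float = 0.05,
) -> EvalResult:
    """Paired Wilcoxon across datasets per representation pair, BH-corrected.

    ``results_by_dataset[rep][dataset]`` is that representation's mean MSE on
    that dataset; every representation must cover the same datasets.
    """
    reps = sorted(results_by_dataset)
    if len(reps) < 2:
        raise ValueError("need at least two representations")
    datasets = sorted(results_by_dataset[reps[0]])
    if len(datasets) < 5:
        raise ValueError("need at least five datasets for a paired test")
    for r in reps:
        if sorted(results_by_dataset[r]) != datasets:
            raise ValueError(f"representation {r!r} covers a different dataset set")
    scores = pd.DataFrame(
        {r: [results_by_dataset[r][d] for d in datasets] for r in reps}, index=datasets
    )
    rows = []
    for a, b in combinations(reps, 2):
        xa = scores[a].to_numpy()
        xb = scores[b].to_numpy()
        diff = xa - xb
        if np.allclose(diff, 0):
            p = 1.0
        else:
            method = "exact" if len(diff) <= 25 else "auto"
            p = float(
                stats.wilcoxon(xa, xb, alternative="two-sided", method=method).pvalue
            )
        rows.append(
            {
                "rep_a": a,
                "rep_b": b,
                "p_value": p,
                "wins_a": int(np.sum(diff < 0)),
                "wins_b": int(np.sum(diff > 0)),
            }
        )
    pairwise = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(
        pairwise["p_value"].to_numpy(), alpha=significance_level, method="fdr_bh"
    )
    pairwise["p_adjusted"] = p_adj
    pairwise["reject"] = reject
    return EvalResult(scores=scores, pairwise=pairwise)


# ---------------------------------------------------------------------------
# baseline representations (established-toolkit adapters; validated for shape
# and determinism only)


def _mols(smiles_list: Sequence[str]):
    from rdkit import Chem

    mols = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        mols.append(mol)
    return mols


def maccs_features(smiles_list: Sequence[str]) -> np.ndarray:
    """166-bit MACCS keys (the toolkit emits 167 bits; bit 0 is unused)."""
    from rdkit.Chem import MACCSkeys

    rows = [np.array(MACCSkeys.GenMACCSKeys(m), dtype=np.int64) for m in _mols(smiles_list)]
    return np.vstack(rows)[:, 1:]


def morgan_features(
    smiles_list: Sequence[str], n_bits: int, radius: int = 2
) -> np.ndarray:
    """Morgan fingerprint (given radius) hashed to ``n_bits`` — sized to
    match the corresponding codebook fingerprint length."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = [
        np.array(gen.GetFingerprint(m), dtype=np.int64) for m in _mols(smiles_list)
    ]
    return np.vstack(rows)
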