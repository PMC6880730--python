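"""Cross-validation protocols, threshold-free metrics, hit rate, and the
interaction-noise robustness experiment.

Three 5-fold protocols are supported: CV over known pairs (pair mode,
every fold's test set is its fifth of the known pairs plus ALL unknown
pairs), CV over lncRNA rows, and CV over protein columns (the zeroed
rows/columns become the test instances). Every interaction-derived
quantity is rebuilt from the masked training matrix inside each fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve

from .model import Hyperparams
from .pipeline import LPIDataset, fit_on_training_matrix

DEFAULT_SEEDS = (101, 103, 107, 109, 113)

MODES = ("pairs", "lncrnas", "proteins")


@dataclass
class CVFold:
    A_train: np.ndarray
    test_mask: np.ndarray  # boolean N_l x N_p: entries scored in this fold
    test_units: np.ndarray  # pair indices / row indices / column indices


@dataclass
class CVSplit:
    mode: str
    seed: int
    folds: list[CVFold]


def make_cv_splits(
    A: np.ndarray,
    mode: str,
    n_folds: int = 5,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
) -> list[CVSplit]:
    """One CVSplit per seed; each is a random n-fold partition of the
    units (known pairs, lncRNA rows, or protein columns) with fold sizes
    differing by at most one."""
    A = np.asarray(A, dtype=float)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "pairs":
        units = np.flatnonzero(A)
    elif mode == "lncrnas":
        units = np.arange(A.shape[0])
    else:
        units = np.arange(A.shape[1])
    if len(units) < n_folds:
        raise ValueError(
            f"only {len(units)} {mode} units; cannot make {n_folds} folds"
        )
    splits = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(units)
        folds = []
        for chunk in np.array_split(perm, n_folds):
            A_train = A.copy()
            test_mask = np.zeros(A.shape, dtype=bool)
            if mode == "pairs":
                flat = A_train.reshape(-1)
                flat[chunk] = 0.0
                test_mask |= A == 0  # all unknown pairs are test instances
                test_mask.reshape(-1)[chunk] = True
            elif mode == "lncrnas":
                A_train[chunk, :] = 0.0
                test_mask[chunk, :] = True
            else:
                A_train[:, chunk] = 0.0
                test_mask[:, chunk] = True
            folds.append(CVFold(A_train=A_train, test_mask=test_mask, test_units=chunk))
        splits.append(CVSplit(mode=mode, seed=seed, folds=folds))
    return splits


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-averaged rank statistic (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(scores)
    return float((ranks[labels > 0].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f1_max(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximum F1 over all thresholds induced by the score set, plus the
    achieving threshold."""
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1[:-1])  # last point has recall 0 and no threshold
    best = int(np.argmax(f1))
    return float(f1[best]), float(thresholds[best])


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUPR (step-interpolated PR integration), AUC (rank statistic) and
    threshold-free max-F1 with its threshold."""
    labels = np.asarray(labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("need at least one positive and one negative label")
    aupr = float(average_precision_score(labels, scores))
    auc = auc_score(scores, labels)
    f1, thr = f1_max(scores, labels)
    return {"AUPR": aupr, "AUC": auc, "F1": f1, "F1_threshold": thr}


def hit_rate(
    scores_for_protein: np.ndarray, test_lncrnas: list[int] | set[int], top_n: int
) -> float:
    """Fraction of a protein's true test lncRNAs found among its top-n
    ranked candidates."""
    test = set(int(t) for t in test_lncrnas)
    if not test:
        raise ValueError("test set must be non-empty")
    order = np.argsort(-np.asarray(scores_for_protein, dtype=float), kind="stable")
    cand = set(order[:top_n].tolist())
    return len(cand & test) / len(test)


def perturb_interactions(
    A: np.ndarray, remove_frac: float = 0.20, add_frac: float = 0.05, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Noise experiment: remove floor(remove_frac * |positives|) known
    pairs uniformly and add floor(add_frac * |positives|) uniformly
    sampled non-pairs. Returns the perturbed matrix and the removed flat
    indices (the removed positives plus all remaining unknown pairs form
    the test set)."""
    if not (0 <= remove_frac < 1 and 0 <= add_frac < 1):
        raise ValueError("fractions must lie in [0, 1)")
    A = np.asarray(A, dtype=float)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(A)
    neg = np.flatnonzero(A == 0)
    n_remove = int(np.floor(remove_frac * len(pos)))
    n_add = int(np.floor(add_frac * len(pos)))
    if n_add > len(neg):
        raise ValueError("not enough non-pairs to add the requested noise")
    removed = rng.choice(pos, size=n_remove, replace=False) if n_remove else np.array([], int)
    added = rng.choice(neg, size=n_add, replace=False) if n_add else np.array([], int)
    out = A.copy().reshape(-1)
    out[removed] = 0.0
    out[added] = 1.0
    return out.reshape(A.shape), removed


@dataclass
class MetricsReport:
    mode: str
    records: pd.DataFrame  # columns: seed, fold, AUPR, AUC, F1
    hit_rates: dict[int, float] = field(default_factory=dict)

    @property
    def means(self) -> dict[str, float]:
        return {k: float(self.records[k].mean()) for k in ("AUPR", "AUC", "F1")}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "means": self.means,
            "per_fold": self.records.to_dict(orient="records"),
            "hit_rates": {str(k): v for k, v in self.hit_rates.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def run_cv_pipeline(
    dataset: LPIDataset,
    hp: Hyperparams | None = None,
    mode: str = "pairs",
    n_folds: int = 5,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
) -> MetricsReport:
    """Full cross-validation: per fold, rebuild every interaction-derived
    quantity from the masked training matrix only, fit, complete latents,
    score the fold's test entries, and aggregate metrics over folds and
    seeds."""
    splits = make_cv_splits(dataset.A, mode, n_folds=n_folds, seeds=seeds)
    rows = []
    for split in splits:
        for f_idx, fold in enumerate(split.folds):
            _, Y = fit_on_training_matrix(dataset, fold.A_train, hp=hp, seed=split.seed)
            labels = dataset.A[fold.test_mask]
            scores = Y[fold.test_mask]
            m = compute_metrics(scores, labels)
            rows.append(
                dict(seed=split.seed, fold=f_idx, AUPR=m["AUPR"], AUC=m["AUC"], F1=m["F1"])
            )
    return MetricsReport(mode=mode, records=pd.DataFrame(rows))
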