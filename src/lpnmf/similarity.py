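"""Similarity networks for the two sides of the bipartite problem.

lncRNA side: alignment-free d2* sequence similarity plus kernel
neighborhood similarity (KSNS) over the expression and pseudo-composition
views and over the completed interaction profile. Protein side: graph-based
GO semantic similarity plus KSNS over the sequence views and the completed
profile. Each side's networks are fused (diffusion + averaging), and fused
networks are sparsified to K-nearest neighborhoods before Laplacian
regularization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationMap, OntologyGraph, SequenceRecordSet

EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SimilarityMatrix:
    entity_ids: list[str]
    S: np.ndarray
    kind: str = "raw"  # raw | sparsified | fused

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.entity_ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix must be square over entity_ids")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("similarity matrix contains non-finite entries")
        if self.kind in ("raw", "fused"):
            if np.abs(self.S - self.S.T).max() > 1e-10:
                raise ValueError("raw/fused similarity must be symmetric")
            if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
                raise ValueError("raw/fused similarity entries must lie in [0, 1]")
            if np.abs(np.diag(self.S) - 1).max() > 1e-12:
                raise ValueError("raw/fused similarity must have unit diagonal")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.S, index=self.entity_ids, columns=self.entity_ids).to_csv(
            path, sep="\t"
        )


def _kmer_counts(seq: str, k: int, index: dict[str, int]) -> np.ndarray:
    counts = np.zeros(len(index))
    for i in range(len(seq) - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return counts


def _word_background(seq: str, k: int, words: list[str]) -> np.ndarray:
    """Order-0 Markov word probabilities from the sequence's own
    mononucleotide frequencies."""
    mono = {c: seq.count(c) / len(seq) for c in "ACGT"}
    return np.array([math.prod(mono[c] for c in w) for w in words])


def d2star_similarity(seqs: SequenceRecordSet, k: int = 6) -> SimilarityMatrix:
    """Alignment-free d2* similarity between nucleotide sequences.

    For sequences of lengths m, n with k-tuple counts X_w, Y_w and order-0
    background probabilities p_w, the centered counts are
    X'_w = X_w - m_bar * p_w with m_bar = m - k. The D2* statistic
    sum_w X'_w Y'_w / sqrt(m_bar p_w^X n_bar p_w^Y) is normalized by the
    geometric mean of sum_w X'^2_w/(m_bar p_w^X) and the Y analogue, giving
    a correlation in [-1, 1]; the dissimilarity is (1 - corr)/2 and the
    similarity 1 minus that. Words with zero background probability in
    either sequence contribute nothing.
    """
    words = ["".join(t) for t in product("ACGT", repeat=k)]
    index = {w: i for i, w in enumerate(words)}
    n = len(seqs)
    counts, backgrounds, mbars = [], [], []
    for rid, s in seqs:
        if len(s) <= k:
            raise ValueError(f"sequence {rid!r} shorter than k+1={k + 1}")
        counts.append(_kmer_counts(s, k, index))
        backgrounds.append(_word_background(s, k, words))
        mbars.append(len(s) - k)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pX, pY = backgrounds[i], backgrounds[j]
            valid = (pX > 0) & (pY > 0)
            Xc = counts[i][valid] - mbars[i] * pX[valid]
            Yc = counts[j][valid] - mbars[j] * pY[valid]
            wx = mbars[i] * pX[valid]
            wy = mbars[j] * pY[valid]
            num = np.sum(Xc * Yc / np.sqrt(wx * wy))
            dx = np.sum(Xc**2 / wx)
            dy = np.sum(Yc**2 / wy)
            corr = num / np.sqrt(dx * dy) if dx > 0 and dy > 0 else 0.0
            sim = 1.0 - 0.5 * (1.0 - corr)
            S[i, j] = S[j, i] = min(max(sim, 0.0), 1.0)
    return SimilarityMatrix(list(seqs.ids), S, kind="raw")


def _svalues(term: str, ontology: OntologyGraph) -> dict[str, float]:
    """Semantic contributions of a term's ancestor closure: S(term)=1 and
    S(parent) = max over child edges of edge_weight * S(child)."""
    if term not in ontology:
        raise KeyError(f"unknown ontology term {term!r}")
    S = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for parent, etype in ontology.parents(t):
                cand = EDGE_WEIGHTS[etype] * S[t]
                if cand > S.get(parent, 0.0):
                    S[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return S


def go_term_similarity(a: str, b: str, ontology: OntologyGraph) -> float:
    """Graph-based semantic similarity of two ontology terms:
    sum over shared ancestors of (S_a(t) + S_b(t)), divided by
    SV(a) + SV(b) where SV is the sum of all S-values."""
    Sa = _svalues(a, ontology)
    Sb = _svalues(b, ontology)
    shared = set(Sa) & set(Sb)
    num = sum(Sa[t] + Sb[t] for t in shared)
    return num / (sum(Sa.values()) + sum(Sb.values()))


def protein_semantic_similarity(
    annot: AnnotationMap, ontology: OntologyGraph, protein_ids: list[str]
) -> SimilarityMatrix:
    """Pairwise protein similarity by best-match-average (BMA) over the
    proteins' term sets. Unannotated proteins get similarity 0 to all
    others and self-similarity 1."""
    term_sets = {p: sorted(annot.annotations.get(p, ())) for p in protein_ids}
    used = sorted({t for ts in term_sets.values() for t in ts})
    t_index = {t: i for i, t in enumerate(used)}
    T = np.eye(len(used))
    svals = {t: _svalues(t, ontology) for t in used}
    svs = {t: sum(v.values()) for t, v in svals.items()}
    for i, ti in enumerate(used):
        for j in range(i + 1, len(used)):
            tj = used[j]
            shared = set(svals[ti]) & set(svals[tj])
            num = sum(svals[ti][t] + svals[tj][t] for t in shared)
            T[i, j] = T[j, i] = num / (svs[ti] + svs[tj])
    n = len(protein_ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ta = [t_index[t] for t in term_sets[protein_ids[i]]]
            tb = [t_index[t] for t in term_sets[protein_ids[j]]]
            if not ta or not tb:
                continue
            block = T[np.ix_(ta, tb)]
            bma = 0.5 * (block.max(axis=1).mean() + block.max(axis=0).mean())
            S[i, j] = S[j, i] = bma
    return SimilarityMatrix(list(protein_ids), S, kind="raw")


def _top_neighbors(sim_row: np.ndarray, self_idx: int, K: int) -> np.ndarray:
    """Indices of the K most similar entities, self excluded; ties broken
    by ascending index (stable sort on negated similarity)."""
    order = np.argsort(-sim_row, kind="stable")
    order = order[order != self_idx]
    return order[:K]


def wknnp_complete(
    A: np.ndarray,
    sim_lnc: np.ndarray | None,
    sim_prot: np.ndarray | None,
    K: int | None = None,
    decay: float = 0.8,
) -> np.ndarray:
    """Weighted K-nearest-neighbor-profile completion of the interaction
    matrix.

    Each row (column) is replaced by the decay- and similarity-weighted
    convex combination of its K most similar rows (columns): the t-th
    nearest neighbor contributes decay^(t-1) * s_t, normalized by the sum
    of those weights. The final completion is the elementwise max of A and
    the mean of the enabled row/column completions, clipped to [0, 1];
    known interactions are never erased. Pass None for a side's similarity
    to disable that side.
    """
    A = np.asarray(A, dtype=float)
    parts = []
    if sim_lnc is not None:
        parts.append(_wknnp_one_side(A, np.asarray(sim_lnc, float), K, decay))
    if sim_prot is not None:
        parts.append(_wknnp_one_side(A.T, np.asarray(sim_prot, float), K, decay).T)
    if not parts:
        raise ValueError("at least one side's similarity must be provided")
    completed = np.mean(parts, axis=0)
    return np.clip(np.maximum(A, completed), 0.0, 1.0)


def _wknnp_one_side(
    A: np.ndarray, sim: np.ndarray, K: int | None, decay: float
) -> np.ndarray:
    n = A.shape[0]
    if sim.shape != (n, n):
        raise ValueError("similarity shape does not match the interaction side")
    k_eff = int(np.ceil(0.3 * n)) if K is None else K
    if k_eff > n - 1:
        warnings.warn(
            f"K={k_eff} exceeds the {n - 1} available neighbors; using all",
            stacklevel=3,
        )
        k_eff = n - 1
    out = np.zeros_like(A)
    for i in range(n):
        nbrs = _top_neighbors(sim[i], i, k_eff)
        w = decay ** np.arange(len(nbrs)) * sim[i, nbrs]
        total = w.sum()
        if total > 0:
            out[i] = w @ A[nbrs] / total
    return out


def ksns(
    X: np.ndarray,
    K: int | None = None,
    hierarchy_penalty: float = 10.0,
    bandwidth: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> SimilarityMatrix | np.ndarray:
    """Kernel neighborhood similarity.

    Each sample i is reconstructed in Gaussian-kernel feature space by a
    simplex-constrained non-negative combination of the other samples,
    with weights on non-neighbors (outside the K nearest by kernel value)
    ridge-penalized by `hierarchy_penalty`. Solved per sample by projected
    gradient descent with exact Euclidean projection onto the simplex. The
    weight matrix is symmetrized, S = (W + W^T)/2, and the diagonal set
    to 1.

    Accepts a plain array (rows = samples) and returns a plain array; the
    higher-level helpers wrap ids around it.
    """
    W = ksns_weights(
        X, K=K, hierarchy_penalty=hierarchy_penalty, bandwidth=bandwidth,
        max_iter=max_iter, tol=tol,
    )
    S = 0.5 * (W + W.T)
    np.fill_diagonal(S, 1.0)
    return np.clip(S, 0.0, 1.0)


def ksns_weights(
    X: np.ndarray,
    K: int | None = None,
    hierarchy_penalty: float = 10.0,
    bandwidth: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Row-stochastic non-negative reconstruction weights W (diagonal 0)
    underlying the kernel neighborhood similarity; each row solves the
    per-sample simplex-constrained kernel reconstruction program."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    if bandwidth is None:
        off = sq[~np.eye(n, dtype=bool)]
        bandwidth = float(np.median(off))
    if bandwidth <= 0:
        # all-identical samples: degenerate kernel, fall back to uniform
        Kmat = np.ones((n, n))
    else:
        Kmat = np.exp(-sq / bandwidth)
    k_eff = int(np.ceil(0.3 * n)) if K is None else min(K, n - 1)
    W = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        k_i = Kmat[i, others]
        G = Kmat[np.ix_(others, others)].copy()
        nbrs = set(_top_neighbors(Kmat[i], i, k_eff).tolist())
        penal = np.array([hierarchy_penalty if j not in nbrs else 0.0 for j in others])
        G[np.diag_indices_from(G)] += penal
        # minimize w'Gw - 2 k_i'w over the probability simplex
        step = 1.0 / (2.0 * max(np.linalg.norm(G, 2), 1e-12))
        w = np.full(len(others), 1.0 / len(others))
        for _ in range(max_iter):
            grad = 2.0 * (G @ w - k_i)
            w_new = _project_simplex(w - step * grad)
            if np.abs(w_new - w).max() < tol:
                w = w_new
                break
            w = w_new
        W[i, others] = w
    return W


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w : w >= 0, sum w = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def ksns_similarity(
    entity_ids: list[str], X: np.ndarray, **kwargs
) -> SimilarityMatrix:
    return SimilarityMatrix(list(entity_ids), ksns(X, **kwargs), kind="raw")


def neighborhood_sparsify(
    S: SimilarityMatrix | np.ndarray, K: int | None = None
) -> SimilarityMatrix | np.ndarray:
    """Keep S_ij iff j is among i's K nearest neighbors OR i among j's
    (an OR rule, hence symmetric); zero elsewhere, diagonal kept.
    Default K = ceil(0.3 * N)."""
    arr = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if np.abs(arr - arr.T).max() > 1e-10:
        raise ValueError("sparsification expects a symmetric matrix")
    n = arr.shape[0]
    k_eff = int(np.ceil(0.3 * n)) if K is None else K
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        keep[i, _top_neighbors(arr[i], i, k_eff)] = True
    keep = keep | keep.T
    np.fill_diagonal(keep, True)
    out = np.where(keep, arr, 0.0)
    if isinstance(S, SimilarityMatrix):
        return SimilarityMatrix(S.entity_ids, out, kind="sparsified")
    return out


def fuse_similarities(
    mats: list[SimilarityMatrix] | list[np.ndarray],
    restart_prob: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> SimilarityMatrix | np.ndarray:
    """Fuse several similarity networks over the same entities.

    Each network is row-normalized into a transition matrix P and smoothed
    by a random walk with restart, X <- (1 - p_r) X P + p_r P, iterated to
    convergence (with p_r = 1 this is no diffusion and X = P). The smoothed
    networks are averaged, symmetrized, min-max rescaled to [0, 1], and the
    diagonal set to 1.
    """
    if not mats:
        raise ValueError("need at least one similarity network to fuse")
    first = mats[0]
    ids = first.entity_ids if isinstance(first, SimilarityMatrix) else None
    arrays = [m.S if isinstance(m, SimilarityMatrix) else np.asarray(m, float) for m in mats]
    n = arrays[0].shape[0]
    if any(a.shape != (n, n) for a in arrays):
        raise ValueError("all networks must share the same entity order")
    smoothed = []
    for a in arrays:
        rowsum = a.sum(axis=1, keepdims=True)
        P = np.divide(a, rowsum, out=np.zeros_like(a), where=rowsum > 0)
        X = P.copy()
        for _ in range(max_iter):
            X_new = (1.0 - restart_prob) * X @ P + restart_prob * P
            if np.abs(X_new - X).sum() < tol:
                X = X_new
                break
            X = X_new
        smoothed.append(X)
    fused = np.mean(smoothed, axis=0)
    fused = 0.5 * (fused + fused.T)
    span = fused.max() - fused.min()
    if span > 0:
        fused = (fused - fused.min()) / span
    np.fill_diagonal(fused, 1.0)
    if ids is not None:
        return SimilarityMatrix(ids, fused, kind="fused")
    return fused
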