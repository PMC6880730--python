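"""Weighted graph-regularized NMF with multi-view feature projection.

The model approximates the (neighbor-completed) interaction matrix A_bar by
U V^T with non-negative latent factors, while each feature view FL_i (FP_j)
is tied to the latent space through a non-negative projection PL_i (PP_j)
so that FL_i PL_i^T ~ U. The objective is

    1/2 ||C . (A_bar - U V^T)||_F^2
  + 1/2 sum_i alpha_i^eta ||FL_i PL_i^T - U||_F^2
  + 1/2 sum_j beta_j^eta  ||FP_j PP_j^T - V||_F^2
  + lambda/2 (tr(U^T L_l U) + tr(V^T L_p V))
  + mu/2 (sum_i ||PL_i||_{1,2}^2 + sum_j ||PP_j||_{1,2}^2)
  + gamma/2 (||U||_F^2 + ||V||_F^2)

with simplex-constrained view weights alpha, beta (projection index eta),
importance matrix C (delta on known interactions, 1 elsewhere), and
neighborhood graph Laplacians L built from the sparsified fused similarity
networks. It is minimized by alternating multiplicative factor sweeps and
closed-form view-weight updates. Entities with no training interaction are
scored after fitting by borrowing latent vectors from their most similar
interacting neighbors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .similarity import SimilarityMatrix, neighborhood_sparsify

_EPS = 1e-12  # multiplicative-update denominator floor


@dataclass
class Hyperparams:
    """Solver hyperparameters.

    eta: projection index (> 1), sharpness of the view weighting.
    mu: projection-matrix l_{1,2} regularizer.
    lam: neighborhood Laplacian regularizer.
    gamma: latent-factor Frobenius regularizer.
    delta: importance level of observed interactions (>= 1).
    d: latent dimension (capped at min(N_l, N_p) at fit time).
    """

    eta: float = 5.0
    mu: float = 100.0
    lam: float = 1.0
    gamma: float = 1.0
    delta: float = 2.0
    d: int = 100
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 1:
            raise ValueError("eta must be > 1")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        for name in ("mu", "lam", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("eta", "mu", "lam", "gamma", "delta", "d", "max_iter", "tol", "seed")
        }


def build_importance(A: np.ndarray, delta: float) -> np.ndarray:
    """Importance matrix C: delta where A_ij = 1, else 1."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    A = np.asarray(A, dtype=float)
    return np.where(A > 0, float(delta), 1.0)


def laplacian(S_bar: np.ndarray, atol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix D (diagonal of row sums) and Laplacian L = D - S_bar.
    Rows of L sum to zero."""
    S_bar = np.asarray(S_bar, dtype=float)
    if np.abs(S_bar - S_bar.T).max() > atol:
        raise ValueError("Laplacian requires a symmetric matrix")
    D = np.diag(S_bar.sum(axis=1))
    return D, D - S_bar


def _as_array(view) -> np.ndarray:
    return view.values if isinstance(view, FeatureMatrix) else np.asarray(view, float)


def _residuals(views: list[np.ndarray], Ps: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    return np.array([np.sum((F @ P.T - X) ** 2) for F, P in zip(views, Ps)])


def update_view_weights(residuals: np.ndarray, eta: float) -> np.ndarray:
    """Closed-form simplex weights alpha_i proportional to
    (1/a_i)^(1/(eta-1)). Views with (numerically) zero residual share the
    whole mass uniformly, the eta limit of the closed form."""
    a = np.asarray(residuals, dtype=float)
    if a.size == 0:
        return np.zeros(0)
    zero = a < _EPS
    if zero.any():
        w = np.where(zero, 1.0, 0.0)
        return w / w.sum()
    w = (1.0 / a) ** (1.0 / (eta - 1.0))
    return w / w.sum()


def objective(
    U: np.ndarray,
    V: np.ndarray,
    PLs: list[np.ndarray],
    PPs: list[np.ndarray],
    alpha: np.ndarray,
    beta: np.ndarray,
    A_bar: np.ndarray,
    C: np.ndarray,
    lnc_views: list[np.ndarray],
    prot_views: list[np.ndarray],
    L_l: np.ndarray,
    L_p: np.ndarray,
    hp: Hyperparams,
) -> float:
    J = 0.5 * np.sum((C * (A_bar - U @ V.T)) ** 2)
    for a_i, F, P in zip(alpha, lnc_views, PLs):
        J += 0.5 * a_i**hp.eta * np.sum((F @ P.T - U) ** 2)
    for b_j, F, P in zip(beta, prot_views, PPs):
        J += 0.5 * b_j**hp.eta * np.sum((F @ P.T - V) ** 2)
    J += 0.5 * hp.lam * (np.trace(U.T @ L_l @ U) + np.trace(V.T @ L_p @ V))
    for P in PLs:
        J += 0.5 * hp.mu * np.sum(np.abs(P).sum(axis=1) ** 2)
    for P in PPs:
        J += 0.5 * hp.mu * np.sum(np.abs(P).sum(axis=1) ** 2)
    J += 0.5 * hp.gamma * (np.sum(U**2) + np.sum(V**2))
    return float(J)


def update_factors(
    U: np.ndarray,
    V: np.ndarray,
    PLs: list[np.ndarray],
    PPs: list[np.ndarray],
    alpha: np.ndarray,
    beta: np.ndarray,
    A_bar: np.ndarray,
    C: np.ndarray,
    lnc_views: list[np.ndarray],
    prot_views: list[np.ndarray],
    S_l: np.ndarray,
    S_p: np.ndarray,
    D_l: np.ndarray,
    D_p: np.ndarray,
    hp: Hyperparams,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """One sequential multiplicative sweep over U, V and the projections.

    Numerators/denominators follow the KKT-derived ratio form; denominators
    are floored at 1e-12. Zero entries are fixed points of the update.
    """
    ae = alpha**hp.eta if alpha.size else alpha
    be = beta**hp.eta if beta.size else beta

    num_U = (C * A_bar) @ V + hp.lam * (S_l @ U)
    for a_i, F, P in zip(ae, lnc_views, PLs):
        num_U = num_U + a_i * (F @ P.T)
    den_U = (C * (U @ V.T)) @ V + (ae.sum() + hp.gamma) * U + hp.lam * (D_l @ U)
    U = U * num_U / np.maximum(den_U, _EPS)

    num_V = (C.T * A_bar.T) @ U + hp.lam * (S_p @ V)
    for b_j, F, P in zip(be, prot_views, PPs):
        num_V = num_V + b_j * (F @ P.T)
    den_V = (C.T * (V @ U.T)) @ U + (be.sum() + hp.gamma) * V + hp.lam * (D_p @ V)
    V = V * num_V / np.maximum(den_V, _EPS)

    new_PLs = []
    for a_i, F, P in zip(ae, lnc_views, PLs):
        num = a_i * (U.T @ F)
        den = a_i * (P @ (F.T @ F)) + hp.mu * P.sum(axis=1, keepdims=True)
        new_PLs.append(P * num / np.maximum(den, _EPS))
    new_PPs = []
    for b_j, F, P in zip(be, prot_views, PPs):
        num = b_j * (V.T @ F)
        den = b_j * (P @ (F.T @ F)) + hp.mu * P.sum(axis=1, keepdims=True)
        new_PPs.append(P * num / np.maximum(den, _EPS))

    for name, M in (("U", U), ("V", V)):
        if not np.all(np.isfinite(M)):
            raise FloatingPointError(f"NaN/Inf produced in {name} update")
    return U, V, new_PLs, new_PPs


def complete_latent(
    U: np.ndarray,
    V: np.ndarray,
    A: np.ndarray,
    SL: np.ndarray,
    SP: np.ndarray,
    K: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cold-start completion of latent vectors.

    Rows of U (V) for entities with at least one known interaction in the
    binary A are kept; rows for interaction-free entities are replaced by
    the similarity-weighted average of the K most similar *interacting*
    entities' latent vectors, normalized by the summed similarities.
    Default K = max(5, floor(0.1 * N)) per side.
    """
    U_t = _complete_side(U, A.sum(axis=1) > 0, np.asarray(SL, float), K)
    V_t = _complete_side(V, A.sum(axis=0) > 0, np.asarray(SP, float), K)
    return U_t, V_t


def _complete_side(
    X: np.ndarray, has_interaction: np.ndarray, S: np.ndarray, K: int | None
) -> np.ndarray:
    n = X.shape[0]
    k_eff = max(5, int(np.floor(0.1 * n))) if K is None else K
    donors = np.nonzero(has_interaction)[0]
    out = X.copy()
    cold = np.nonzero(~has_interaction)[0]
    if cold.size and donors.size == 0:
        raise ValueError("no interacting entities to borrow latent vectors from")
    for i in cold:
        sims = S[i, donors]
        order = np.argsort(-sims, kind="stable")[:k_eff]
        chosen = donors[order]
        w = S[i, chosen]
        Q = w.sum()
        if Q > 0:
            out[i] = w @ X[chosen] / Q
        else:
            out[i] = X[donors].mean(axis=0)
    return out


@dataclass
class TrainingTrace:
    objective: list[float] = field(default_factory=list)
    alpha: list[np.ndarray] = field(default_factory=list)
    beta: list[np.ndarray] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.objective)


class ProjectedGraphNMF:
    """Projection-based neighborhood NMF model for bipartite link
    prediction.

    Parameters
    ----------
    A : binary interaction matrix, N_l x N_p.
    A_bar : neighbor-completed interaction matrix (defaults to A).
    lnc_views, prot_views : lists of normalized FeatureMatrix/arrays.
    SL, SP : fused similarity matrices per side; sparsified internally to
        K = ceil(0.3 N) neighborhoods before the Laplacians are built, and
        used as-is for cold-start latent completion.
    hyperparams : Hyperparams (defaults eta=5, mu=100, lam=1, gamma=1,
        d=100, delta=2).
    """

    def __init__(
        self,
        A: np.ndarray,
        lnc_views: list,
        prot_views: list,
        SL: np.ndarray | SimilarityMatrix,
        SP: np.ndarray | SimilarityMatrix,
        A_bar: np.ndarray | None = None,
        hyperparams: Hyperparams | None = None,
        lncrna_ids: list[str] | None = None,
        protein_ids: list[str] | None = None,
    ) -> None:
        self.A = np.asarray(A, dtype=float)
        self.A_bar = self.A if A_bar is None else np.asarray(A_bar, dtype=float)
        self.lnc_views = [_as_array(v) for v in lnc_views]
        self.prot_views = [_as_array(v) for v in prot_views]
        self.SL = SL.S if isinstance(SL, SimilarityMatrix) else np.asarray(SL, float)
        self.SP = SP.S if isinstance(SP, SimilarityMatrix) else np.asarray(SP, float)
        self.hp = hyperparams or Hyperparams()
        n_l, n_p = self.A.shape
        self.lncrna_ids = lncrna_ids or [f"l{i + 1}" for i in range(n_l)]
        self.protein_ids = protein_ids or [f"p{j + 1}" for j in range(n_p)]
        for v in self.lnc_views:
            if v.shape[0] != n_l:
                raise ValueError("lncRNA view row count does not match A")
        for v in self.prot_views:
            if v.shape[0] != n_p:
                raise ValueError("protein view row count does not match A")
        self.C = build_importance(self.A, self.hp.delta)
        self.SL_bar = neighborhood_sparsify(self.SL)
        self.SP_bar = neighborhood_sparsify(self.SP)
        self.D_l, self.L_l = laplacian(self.SL_bar)
        self.D_p, self.L_p = laplacian(self.SP_bar)

    @classmethod
    def from_dataframes(
        cls,
        interactions: pd.DataFrame,
        lnc_views: list[pd.DataFrame],
        prot_views: list[pd.DataFrame],
        SL: pd.DataFrame,
        SP: pd.DataFrame,
        **kwargs,
    ) -> "ProjectedGraphNMF":
        """Build from pandas DataFrames; the interaction frame's index/
        columns fix the global entity order and all other frames are
        reindexed to it."""
        lids = [str(i) for i in interactions.index]
        pids = [str(c) for c in interactions.columns]
        return cls(
            interactions.to_numpy(dtype=float),
            [v.reindex(lids).to_numpy(dtype=float) for v in lnc_views],
            [v.reindex(pids).to_numpy(dtype=float) for v in prot_views],
            SL.reindex(index=lids, columns=lids).to_numpy(dtype=float),
            SP.reindex(index=pids, columns=pids).to_numpy(dtype=float),
            lncrna_ids=lids,
            protein_ids=pids,
            **kwargs,
        )

    def fit(self, seed: int | None = None) -> "ProjectedGraphNMFResults":
        """Alternate multiplicative factor sweeps and view-weight updates
        until the relative objective change drops below tol (or max_iter).

        Factors and projections are initialized i.i.d. Uniform(0,1) from a
        single seeded generator drawn in a fixed order (U, V, PL_1.., PP_1..),
        and the view weights start from the initial residuals.
        """
        hp = self.hp
        n_l, n_p = self.A.shape
        d = min(hp.d, n_l, n_p)
        rng = np.random.default_rng(hp.seed if seed is None else seed)
        U = rng.uniform(size=(n_l, d))
        V = rng.uniform(size=(n_p, d))
        PLs = [rng.uniform(size=(d, F.shape[1])) for F in self.lnc_views]
        PPs = [rng.uniform(size=(d, F.shape[1])) for F in self.prot_views]
        alpha = update_view_weights(_residuals(self.lnc_views, PLs, U), hp.eta)
        beta = update_view_weights(_residuals(self.prot_views, PPs, V), hp.eta)

        trace = TrainingTrace()
        prev = None
        for _ in range(hp.max_iter):
            U, V, PLs, PPs = update_factors(
                U, V, PLs, PPs, alpha, beta, self.A_bar, self.C,
                self.lnc_views, self.prot_views,
                self.SL_bar, self.SP_bar, self.D_l, self.D_p, hp,
            )
            alpha = update_view_weights(_residuals(self.lnc_views, PLs, U), hp.eta)
            beta = update_view_weights(_residuals(self.prot_views, PPs, V), hp.eta)
            J = objective(
                U, V, PLs, PPs, alpha, beta, self.A_bar, self.C,
                self.lnc_views, self.prot_views, self.L_l, self.L_p, hp,
            )
            if not np.isfinite(J):
                raise FloatingPointError(
                    f"objective diverged at iteration {trace.n_iter}: {J}"
                )
            trace.objective.append(J)
            trace.alpha.append(alpha.copy())
            trace.beta.append(beta.copy())
            if prev is not None and abs(prev - J) < hp.tol * max(abs(prev), 1e-30):
                trace.converged = True
                break
            prev = J
        return ProjectedGraphNMFResults(self, U, V, PLs, PPs, alpha, beta, trace)


class ProjectedGraphNMFResults:
    """Fitted factors, projections, adaptive view weights and trace."""

    def __init__(self, model, U, V, PLs, PPs, alpha, beta, trace) -> None:
        self.model = model
        self.U = U
        self.V = V
        self.PLs = PLs
        self.PPs = PPs
        self.alpha = alpha
        self.beta = beta
        self.trace = trace

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def n_iter(self) -> int:
        return self.trace.n_iter

    @property
    def final_objective(self) -> float:
        return self.trace.objective[-1]

    def reconstruction_error(self) -> float:
        """Unweighted RMS error of A_bar - U V^T."""
        R = self.model.A_bar - self.U @ self.V.T
        return float(np.sqrt(np.mean(R**2)))

    def complete(self, K: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Cold-start-completed (U~, V~) using the fused similarities and
        the binary training A."""
        return complete_latent(
            self.U, self.V, self.model.A, self.model.SL, self.model.SP, K=K
        )

    def predict(self, complete: bool = True, K: int | None = None) -> np.ndarray:
        """Score matrix Y_bar = U~ V~^T (N_l x N_p, non-negative)."""
        if complete:
            U_t, V_t = self.complete(K=K)
        else:
            U_t, V_t = self.U, self.V
        return U_t @ V_t.T

    def summary(self) -> str:
        hp = self.model.hp
        lines = [
            "Projection-based neighborhood NMF",
            "=" * 46,
            f"lncRNAs x proteins      {self.U.shape[0]} x {self.V.shape[0]}",
            f"latent dimension        {self.U.shape[1]}",
            f"known interactions      {int(self.model.A.sum())}",
            f"iterations              {self.n_iter} (converged={self.converged})",
            f"final objective         {self.final_objective:.6g}",
            f"reconstruction RMSE     {self.reconstruction_error():.6g}",
            f"hyperparameters         eta={hp.eta} mu={hp.mu} lam={hp.lam} "
            f"gamma={hp.gamma} delta={hp.delta}",
            "lncRNA view weights     "
            + " ".join(f"{a:.4f}" for a in self.alpha),
            "protein view weights    "
            + " ".join(f"{b:.4f}" for b in self.beta),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """TSV bundle for the factor/projection matrices plus a JSON
        sidecar with hyperparameters, weights and the objective trace."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        m = self.model
        pd.DataFrame(self.U, index=m.lncrna_ids).to_csv(outdir / "U.tsv", sep="\t")
        pd.DataFrame(self.V, index=m.protein_ids).to_csv(outdir / "V.tsv", sep="\t")
        for i, P in enumerate(self.PLs):
            pd.DataFrame(P).to_csv(outdir / f"PL{i + 1}.tsv", sep="\t")
        for j, P in enumerate(self.PPs):
            pd.DataFrame(P).to_csv(outdir / f"PP{j + 1}.tsv", sep="\t")
        sidecar = {
            "hyperparams": m.hp.to_dict(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "objective_trace": self.trace.objective,
            "converged": self.converged,
        }
        (outdir / "model.json").write_text(json.dumps(sidecar, indent=2))
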