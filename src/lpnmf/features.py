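"""Sequence and expression descriptors for lncRNAs and proteins.

lncRNA side: pseudo-k-tuple nucleotide composition (PseKNC), parallel-
correlation pseudo dinucleotide composition (PCPseDNC), and the raw tissue
expression profile. Protein side: amphiphilic pseudo amino-acid composition
(APseAAC) and the conjoint-triad descriptor (CTriad). High-dimensional
descriptors are PCA-reduced, and every feature matrix handed to the solver
is column-wise min-max normalized so all entries lie in [0, 1].

The pseudo-composition tier correlations use physicochemical property
tables shipped as package data (unified nearest-neighbor thermodynamic
scales for DNA dinucleotides; hydrophobicity/hydrophilicity scales for
amino acids), z-normalized across the alphabet before use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import SequenceRecordSet

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FeatureMatrix:
    """entity x dimension real matrix with an explicit row-order contract."""

    entity_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.entity_ids):
            raise ValueError("row count does not match entity ids")

    @property
    def dims(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _load_table(fname: str) -> pd.DataFrame:
    with resources.files("lpnmf.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, index_col=0)


@lru_cache(maxsize=1)
def dinucleotide_properties() -> dict[str, np.ndarray]:
    """Z-normalized property vectors per dinucleotide (16 x n_props)."""
    df = _load_table("dinucleotide_thermo.csv")
    vals = df.to_numpy(dtype=float)
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    return {str(dn): z[i] for i, dn in enumerate(df.index)}


@lru_cache(maxsize=1)
def amino_acid_scales() -> tuple[dict[str, float], dict[str, float]]:
    """Z-normalized (hydrophobicity, hydrophilicity) per residue."""
    df = _load_table("aa_scales.csv")
    out = []
    for col in ("hydrophobicity", "hydrophilicity"):
        v = df[col].to_numpy(dtype=float)
        z = (v - v.mean()) / v.std()
        out.append({str(r): z[i] for i, r in enumerate(df.index)})
    return out[0], out[1]


@lru_cache(maxsize=1)
def conjoint_triad_classes() -> dict[str, int]:
    """Residue -> class index (0..6) for the 7-class dipole/side-chain-volume
    partition used by the conjoint-triad descriptor."""
    df = _load_table("ctriad_classes.csv")
    mapping: dict[str, int] = {}
    for idx, (_, row) in enumerate(df.iterrows()):
        for res in str(row["residues"]):
            mapping[res] = idx
    return mapping


def minmax_normalize(F: FeatureMatrix | np.ndarray) -> FeatureMatrix | np.ndarray:
    """Column-wise (x - min) / (max - min); constant columns map to zeros
    (the formula is 0/0 there, and zeros keep the matrix finite and
    non-negative without dropping columns)."""
    arr = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    bad = ~np.all(np.isfinite(arr), axis=0)
    if bad.any():
        raise ValueError(f"non-finite entries in column(s) {np.nonzero(bad)[0].tolist()}")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    out = np.zeros_like(arr, dtype=float)
    ok = span > 0
    out[:, ok] = (arr[:, ok] - lo[ok]) / span[ok]
    if isinstance(F, FeatureMatrix):
        return replace(F, values=out, normalized=True)
    return out


def ctriad(seq: str) -> np.ndarray:
    """Conjoint-triad descriptor: frequencies of the 343 class triads over
    all overlapping length-3 windows, min-max rescaled across the 343
    entries. All-equal frequencies map to all-zeros."""
    if len(seq) < 3:
        raise ValueError("sequence must have length >= 3 for the triad descriptor")
    classes = conjoint_triad_classes()
    try:
        encoded = [classes[r] for r in seq]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    f = np.zeros(343)
    for a, b, c in zip(encoded, encoded[1:], encoded[2:]):
        f[a * 49 + b * 7 + c] += 1
    span = f.max() - f.min()
    if span == 0:
        return np.zeros(343)
    return (f - f.min()) / span


def _kmer_frequencies(seq: str, k: int, alphabet: str = NUCLEOTIDES) -> np.ndarray:
    index = {w: i for i, w in enumerate("".join(t) for t in product(alphabet, repeat=k))}
    counts = np.zeros(len(index))
    for i in range(len(seq) - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return counts / counts.sum()


def _dinucleotide_theta(seq: str, lam: int) -> np.ndarray:
    """Tier correlation factors theta_1..theta_lam: mean squared property
    distance between dinucleotides `j` apart."""
    props = dinucleotide_properties()
    P = np.array([props[seq[i : i + 2]] for i in range(len(seq) - 1)])
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = P[:-j] - P[j:]
        thetas[j - 1] = np.mean(diff**2)
    return thetas


def pseknc(seq: str, k: int = 3, lam: int = 10, w: float = 0.05) -> np.ndarray:
    """Pseudo-k-tuple nucleotide composition (type-1 / parallel correlation).

    First 4^k entries are pseudo-normalized k-mer frequencies; last `lam`
    entries are w-weighted tier correlations of dinucleotide property
    profiles. The full vector sums to 1.
    """
    if lam < 0 or not 0 <= w <= 1:
        raise ValueError("require lam >= 0 and 0 <= w <= 1")
    if len(seq) <= k + lam:
        raise ValueError(
            f"sequence length {len(seq)} too short for k={k}, lam={lam}"
        )
    f = _kmer_frequencies(seq, k)
    if lam == 0:
        return f
    theta = _dinucleotide_theta(seq, lam)
    denom = 1.0 + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


def pcpsednc(seq: str, lam: int = 10, w: float = 0.05) -> np.ndarray:
    """Parallel-correlation pseudo dinucleotide composition: the k=2 case
    of the pseudo-k-tuple construction (16 + lam dims)."""
    return pseknc(seq, k=2, lam=lam, w=w)


def apseaac(seq: str, lam: int = 15, w: float = 0.05) -> np.ndarray:
    """Amphiphilic pseudo amino-acid composition (20 + 2*lam dims).

    The first 20 entries are pseudo-normalized residue frequencies; the last
    2*lam alternate hydrophobicity / hydrophilicity sequence-correlation
    factors tau, weighted by w. The vector sums to 1.
    """
    if lam < 0 or not 0 <= w <= 1:
        raise ValueError("require lam >= 0 and 0 <= w <= 1")
    if len(seq) <= lam:
        raise ValueError(f"sequence length {len(seq)} too short for lam={lam}")
    h1_map, h2_map = amino_acid_scales()
    try:
        h1 = np.array([h1_map[r] for r in seq])
        h2 = np.array([h2_map[r] for r in seq])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    freqs = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    freqs /= freqs.sum()
    if lam == 0:
        return freqs
    taus = np.empty(2 * lam)
    for j in range(1, lam + 1):
        taus[2 * (j - 1)] = np.mean(h1[:-j] * h1[j:])
        taus[2 * (j - 1) + 1] = np.mean(h2[:-j] * h2[j:])
    denom = 1.0 + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


def pca_reduce(
    F: FeatureMatrix,
    n_components: int | None = None,
    variance: float = 0.95,
    max_components: int = 200,
    normalize: bool = True,
) -> FeatureMatrix:
    """Centered PCA scores, by default followed by min-max normalization
    (solver-ready non-negative output); pass normalize=False for the raw
    rotation scores (which preserve pairwise distances at full rank).
    Deterministic sign convention: the largest-magnitude loading of each
    component is made positive. If `n_components` is None, retain
    components explaining `variance` of the variance, capped at
    `max_components`."""
    limit = min(F.values.shape)
    if n_components is not None and n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, dims)={limit}"
        )
    if np.allclose(F.values.std(axis=0), 0):
        # identical rows: zero variance, zero scores
        k = n_components or 1
        return FeatureMatrix(
            F.entity_ids, np.zeros((len(F.entity_ids), k)), normalized=True,
            name=f"{F.name}_pca",
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(F.values)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance) + 1)
        k = min(k, max_components, scores.shape[1])
        scores = scores[:, :k]
        components = pca.components_[:k]
    else:
        components = pca.components_
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    out = FeatureMatrix(F.entity_ids, scores, name=f"{F.name}_pca")
    return minmax_normalize(out) if normalize else out


def featurize_lncrnas(
    seqs: SequenceRecordSet,
    expression: np.ndarray | None = None,
    k: int = 3,
    lam_pseknc: int = 10,
    lam_pcpsednc: int = 10,
    w: float = 0.05,
    reduce: bool = True,
) -> list[FeatureMatrix]:
    """The three lncRNA views: expression profile (if given), PseKNC and
    PCPseDNC, each min-max normalized (PCA-reduced first when `reduce`)."""
    views: list[FeatureMatrix] = []
    if expression is not None:
        views.append(
            minmax_normalize(FeatureMatrix(seqs.ids, expression, name="expression"))
        )
    pk = FeatureMatrix(
        seqs.ids, np.array([pseknc(s, k, lam_pseknc, w) for s in seqs.sequences]),
        name="pseknc",
    )
    pc = FeatureMatrix(
        seqs.ids, np.array([pcpsednc(s, lam_pcpsednc, w) for s in seqs.sequences]),
        name="pcpsednc",
    )
    for fm in (pk, pc):
        views.append(pca_reduce(fm) if reduce else minmax_normalize(fm))
    return views


def featurize_proteins(
    seqs: SequenceRecordSet,
    lam_apseaac: int = 15,
    w: float = 0.05,
    reduce: bool = True,
) -> list[FeatureMatrix]:
    """The two protein views: APseAAC and CTriad, min-max normalized
    (PCA-reduced first when `reduce`)."""
    ap = FeatureMatrix(
        seqs.ids, np.array([apseaac(s, lam_apseaac, w) for s in seqs.sequences]),
        name="apseaac",
    )
    ct = FeatureMatrix(
        seqs.ids, np.array([ctriad(s) for s in seqs.sequences]), name="ctriad"
    )
    return [pca_reduce(fm) if reduce else minmax_normalize(fm) for fm in (ap, ct)]
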