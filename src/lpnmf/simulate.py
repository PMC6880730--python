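"""Synthetic fixture generator.

Emulates the statistical structure the predictor assumes: random nucleotide
and amino-acid sequences, a skewed non-negative expression matrix over
tissues, a rooted typed ontology DAG with per-protein term sets, and a
binary interaction matrix planted from low-rank non-negative factors.
Everything is a pure function of the arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    AnnotationMap,
    ExpressionMatrix,
    InteractionTable,
    OntologyGraph,
    SequenceRecordSet,
)

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Planted low-rank ground truth behind a synthetic interaction matrix."""

    U_true: np.ndarray
    V_true: np.ndarray
    A: np.ndarray
    mask: list[tuple[int, int]]  # held-out positive coordinates
    seed: int


@dataclass
class FixtureBundle:
    lncrna_seqs: SequenceRecordSet
    protein_seqs: SequenceRecordSet
    expression: ExpressionMatrix
    ontology: OntologyGraph
    annotations: AnnotationMap
    interactions: InteractionTable
    truth: SyntheticTruth
    params: dict = field(default_factory=dict)


def _random_sequences(
    rng: np.random.Generator,
    prefix: str,
    n: int,
    alphabet: str,
    length_range: tuple[int, int],
) -> SequenceRecordSet:
    letters = np.array(list(alphabet))
    ids, seqs = [], []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seqs.append("".join(rng.choice(letters, size=length)))
        ids.append(f"{prefix}{i + 1}")
    tag = "nucleotide" if set(alphabet) <= set(NUCLEOTIDES) else "protein"
    return SequenceRecordSet(ids=ids, sequences=seqs, alphabet=tag)


def _random_ontology(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Rooted random DAG: each non-root term gets 1-2 parents among
    earlier-created terms; edges are is_a with probability 0.8, else part_of."""
    terms = [f"T{i:04d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 if (i == 1 or rng.random() < 0.5) else 2
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in np.atleast_1d(parents):
            etype = "is_a" if rng.random() < 0.8 else "part_of"
            edges.append((terms[i], terms[int(p)], etype))
    return OntologyGraph.from_edges(edges, terms=terms)


def generate_fixture(
    n_lncrna: int = 40,
    n_protein: int = 12,
    d_true: int = 4,
    density: float = 0.15,
    noise_rate: float = 0.0,
    n_tissues: int = 24,
    n_terms: int = 30,
    seed: int = 0,
    mask_frac: float = 0.15,
    lncrna_length: tuple[int, int] = (200, 1000),
    protein_length: tuple[int, int] = (50, 500),
) -> FixtureBundle:
    """Generate a complete synthetic dataset with a planted interaction
    structure.

    The interaction matrix is 1 on the top `density` fraction of entries of
    ``U_true @ V_true.T`` with the factors i.i.d. Uniform(0,1) of rank
    `d_true`; each entry is then flipped with probability `noise_rate`. A
    `mask_frac` fraction of the resulting positives is recorded (not
    removed) as a held-out set for transductive ranking checks.
    """
    if d_true < 1:
        raise ValueError("d_true must be >= 1")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must be in [0, 1)")
    n_entries = n_lncrna * n_protein
    n_ones = int(np.floor(density * n_entries))
    if n_ones < 1:
        raise ValueError(
            f"density {density} yields no positive entries on a "
            f"{n_lncrna}x{n_protein} matrix"
        )

    rng = np.random.default_rng(seed)
    lnc = _random_sequences(rng, "L", n_lncrna, NUCLEOTIDES, lncrna_length)
    prot = _random_sequences(rng, "P", n_protein, AMINO_ACIDS, protein_length)

    expr = ExpressionMatrix(
        lncrna_ids=lnc.ids,
        tissue_ids=[f"tissue{t + 1}" for t in range(n_tissues)],
        values=rng.lognormal(mean=0.0, sigma=1.0, size=(n_lncrna, n_tissues)),
    )

    onto = _random_ontology(rng, n_terms)
    annotations = {
        pid: set(
            rng.choice(onto.terms, size=int(rng.integers(1, 6)), replace=False)
        )
        for pid in prot.ids
    }
    annot = AnnotationMap(annotations={k: {str(t) for t in v} for k, v in annotations.items()})

    U_true = rng.uniform(size=(n_lncrna, d_true))
    V_true = rng.uniform(size=(n_protein, d_true))
    scores = U_true @ V_true.T
    flat = np.argsort(scores, axis=None)[::-1]
    A = np.zeros(n_entries)
    A[flat[:n_ones]] = 1.0
    A = A.reshape(n_lncrna, n_protein)
    if noise_rate > 0:
        flips = rng.random(A.shape) < noise_rate
        A = np.where(flips, 1.0 - A, A)

    pos = list(zip(*np.nonzero(A)))
    n_mask = int(np.floor(mask_frac * len(pos)))
    mask_idx = rng.choice(len(pos), size=n_mask, replace=False) if n_mask else []
    mask = [(int(pos[k][0]), int(pos[k][1])) for k in np.sort(mask_idx)]

    truth = SyntheticTruth(U_true=U_true, V_true=V_true, A=A, mask=mask, seed=seed)
    interactions = InteractionTable(lnc.ids, prot.ids, A)
    params = dict(
        n_lncrna=n_lncrna,
        n_protein=n_protein,
        d_true=d_true,
        density=density,
        noise_rate=noise_rate,
        n_tissues=n_tissues,
        n_terms=n_terms,
        seed=seed,
        mask_frac=mask_frac,
    )
    return FixtureBundle(
        lncrna_seqs=lnc,
        protein_seqs=prot,
        expression=expr,
        ontology=onto,
        annotations=annot,
        interactions=interactions,
        truth=truth,
        params=params,
    )
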