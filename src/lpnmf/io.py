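"""Readers/writers for the external formats and the in-memory containers.

All matrix-valued containers follow one ordering contract: row/column order
is the order of the id lists they carry, and every downstream module
preserves it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALPHABETS = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}


@dataclass
class SequenceRecordSet:
    """An ordered set of sequences over a declared alphabet."""

    ids: list[str]
    sequences: list[str]
    alphabet: str  # "nucleotide" | "protein"

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet tag {self.alphabet!r}")
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sequence id {dup!r}")
        allowed = _ALPHABETS[self.alphabet]
        for rid, seq in zip(self.ids, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"record {rid!r} contains characters outside the "
                    f"{self.alphabet} alphabet: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


def read_fasta(path: str | Path, alphabet: str) -> SequenceRecordSet:
    """Read a FASTA file, uppercasing sequences and rejecting characters
    outside the declared alphabet (no silent conversion, e.g. U -> T)."""
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceRecordSet(ids=ids, sequences=seqs, alphabet=alphabet)


def write_fasta(records: SequenceRecordSet, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=i, description="") for i, s in records),
        str(path),
        "fasta",
    )


@dataclass
class ExpressionMatrix:
    lncrna_ids: list[str]
    tissue_ids: list[str]
    values: np.ndarray  # lncRNA x tissue, non-negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_ids), len(self.tissue_ids)):
            raise ValueError("expression matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("expression values must be finite and >= 0")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: header row of tissues, first column lncRNA id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        lncrna_ids=[str(i) for i in df.index],
        tissue_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        expr.values, index=expr.lncrna_ids, columns=expr.tissue_ids
    ).to_csv(path, sep="\t")


EDGE_TYPES = ("is_a", "part_of")


@dataclass
class OntologyGraph:
    """A rooted DAG of terms with typed edges (child -> parent)."""

    graph: nx.DiGraph = field(repr=False)
    terms: list[str] = field(default_factory=list)
    roots: list[str] = field(default_factory=list)

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str, str]], terms: list[str] | None = None
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        if terms:
            g.add_nodes_from(terms)
        for child, parent, etype in edges:
            if etype not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {etype!r}")
            g.add_edge(child, parent, etype=etype)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology edges contain a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        return cls(graph=g, terms=list(g.nodes), roots=roots)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, edge_type) pairs of a term."""
        return [(p, self.graph.edges[term, p]["etype"]) for p in self.graph.successors(term)]


def read_ontology(path: str | Path) -> OntologyGraph:
    """Read an ontology from OBO (via obonet) or a 3-column TSV
    (child, parent, edge_type)."""
    path = Path(path)
    if path.suffix == ".obo":
        import obonet

        g = obonet.read_obo(str(path))
        edges = []
        for child, parent, key in g.edges(keys=True):
            if key in EDGE_TYPES:
                edges.append((child, parent, key))
        return OntologyGraph.from_edges(edges, terms=list(g.nodes))
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent", "etype"])
    return OntologyGraph.from_edges(
        [(str(r.child), str(r.parent), str(r.etype)) for r in df.itertuples()]
    )


def write_ontology(onto: OntologyGraph, path: str | Path) -> None:
    rows = [
        (c, p, onto.graph.edges[c, p]["etype"]) for c, p in onto.graph.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class AnnotationMap:
    """protein id -> non-empty set of ontology term ids; proteins known to
    the dataset but lacking annotation are listed in `unannotated`."""

    annotations: dict[str, set[str]]
    unannotated: list[str] = field(default_factory=list)

    def validate(self, ontology: OntologyGraph) -> None:
        for pid, terms in self.annotations.items():
            if not terms:
                raise ValueError(f"protein {pid!r} has an empty annotation set")
            missing = [t for t in terms if t not in ontology]
            if missing:
                raise ValueError(
                    f"protein {pid!r} annotated with unknown terms {missing}"
                )


def read_annotations(
    path: str | Path, protein_ids: list[str] | None = None
) -> AnnotationMap:
    """Two-column TSV of (protein_id, term_id) pairs, no header."""
    df = pd.read_csv(path, sep="\t", header=None)
    annotations: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        annotations.setdefault(str(row[0]), set()).add(str(row[1]))
    unannotated = (
        [p for p in protein_ids if p not in annotations] if protein_ids else []
    )
    return AnnotationMap(annotations=annotations, unannotated=unannotated)


def write_annotations(annot: AnnotationMap, path: str | Path) -> None:
    rows = [(p, t) for p, terms in annot.annotations.items() for t in sorted(terms)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class InteractionTable:
    lncrna_ids: list[str]
    protein_ids: list[str]
    A: np.ndarray  # binary, N_l x N_p

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.lncrna_ids), len(self.protein_ids)):
            raise ValueError("interaction matrix shape does not match id lists")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        for name, ids in (("lncrna", self.lncrna_ids), ("protein", self.protein_ids)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} ids")


def read_interactions(
    path: str | Path, lncrna_ids: list[str], protein_ids: list[str]
) -> InteractionTable:
    """Two-column TSV of (lncrna_id, protein_id) pairs; an optional third
    column (e.g. a score) is ignored. Duplicate pairs collapse to one 1."""
    A = np.zeros((len(lncrna_ids), len(protein_ids)))
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return InteractionTable(lncrna_ids, protein_ids, A)
    l_index = {v: i for i, v in enumerate(lncrna_ids)}
    p_index = {v: j for j, v in enumerate(protein_ids)}
    bad_rows = []
    for k, row in enumerate(df.itertuples(index=False)):
        lid, pid = str(row[0]), str(row[1])
        if lid not in l_index or pid not in p_index:
            bad_rows.append((k, lid, pid))
            continue
        A[l_index[lid], p_index[pid]] = 1.0
    if bad_rows:
        raise ValueError(
            "interaction rows reference unknown ids: "
            + "; ".join(f"row {k}: ({l}, {p})" for k, l, p in bad_rows)
        )
    return InteractionTable(lncrna_ids, protein_ids, A)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    rows = [
        (table.lncrna_ids[i], table.protein_ids[j])
        for i, j in zip(*np.nonzero(table.A))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_matrix_tsv(
    M: np.ndarray, row_ids: list[str], col_ids: list[str], path: str | Path
) -> None:
    pd.DataFrame(M, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
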