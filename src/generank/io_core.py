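"""Input parsing, validation and preprocessing.

Handles three kinds of inputs:

* two-class expression matrices (genes in rows, samples in columns) from
  delimited text, with class labels taken either from a designated label row
  or from a sidecar file;
* ontologies from a subset of the OBO 1.2 format (``[Term]`` stanzas with
  ``id``, ``name``, ``namespace``, ``is_a``, ``is_obsolete`` and optionally
  ``relationship: part_of``);
* gene→term annotation tables (two-column delimited text or GAF-style rows).

Preprocessing follows the two steps used on the microarray datasets: an
optional base-10 log transform followed by standardizing each *sample*
(column) to zero mean and unit variance.  Standard deviations use the n−1
estimator throughout the package.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "OntologyDAG",
    "AnnotationMap",
    "read_expression_table",
    "read_obo",
    "write_obo",
    "read_annotations",
    "preprocess",
    "DDOF",
]

#: Delta-degrees-of-freedom used by every variance/SD in the package.
DDOF = 1

POSITIVE = 1
NEGATIVE = -1


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes × samples real matrix with binary sample labels.

    ``labels`` holds +1 (positive class, e.g. tumor) / −1 (negative class)
    per sample; ``class_names`` maps those codes back to the original label
    strings.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: dict[int, str] = field(
        default_factory=lambda: {POSITIVE: "positive", NEGATIVE: "negative"}
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if n_samples != len(self.sample_ids):
            raise ValueError("column count does not match number of sample ids")
        if len(self.labels) != n_samples:
            raise ValueError("labels length does not match number of samples")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifier")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample identifier")
        bad = set(np.unique(self.labels)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"labels must be +1/-1, got {sorted(bad)}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """samples × genes view for classifiers."""
        return self.values.T

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx, :],
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels[idx],
        )

    def require_two_classes(self, min_per_class: int = 2) -> None:
        """Raise unless both classes have at least ``min_per_class`` samples."""
        n_pos = int(np.sum(self.labels == POSITIVE))
        n_neg = int(np.sum(self.labels == NEGATIVE))
        if n_pos < min_per_class or n_neg < min_per_class:
            raise ValueError(
                f"need >= {min_per_class} samples per class "
                f"(got {n_pos} positive, {n_neg} negative)"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _encode_labels(
    raw: Sequence[str], positive_label: str | None
) -> tuple[np.ndarray, dict[int, str]]:
    raw = [str(v).strip() for v in raw]
    uniq = sorted(set(raw))
    if len(uniq) != 2:
        raise ValueError(
            f"binary classification requires exactly 2 distinct labels, got {uniq}"
        )
    if positive_label is None:
        positive_label = uniq[1]  # deterministic: lexicographically larger
    elif positive_label not in uniq:
        raise ValueError(f"unknown label value {positive_label!r}; labels are {uniq}")
    negative_label = next(u for u in uniq if u != positive_label)
    labels = np.array([POSITIVE if v == positive_label else NEGATIVE for v in raw])
    return labels, {POSITIVE: positive_label, NEGATIVE: negative_label}


def read_expression_table(
    path: str | Path | io.TextIOBase,
    dialect: str = "tsv",
    label_row: str = "label",
    labels_path: str | Path | None = None,
    positive_label: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes × samples table with a header of sample ids.

    The first column holds gene identifiers (trimmed, matched
    case-sensitively).  Class labels come either from the table row whose id
    equals ``label_row``, or from a 2-column sidecar file ``labels_path``
    (sample id, label).  Exactly two distinct label values are required; the
    positive class defaults to the lexicographically larger one.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    if df.columns.size == 0 or df.index.size == 0:
        raise ValueError("malformed header: no samples or no genes found")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    if labels_path is not None:
        sidecar = pd.read_csv(labels_path, sep=sep, header=None, dtype=str)
        if sidecar.shape[1] < 2:
            raise ValueError("label sidecar must have 2 columns: sample_id, label")
        mapping = dict(
            zip(sidecar.iloc[:, 0].str.strip(), sidecar.iloc[:, 1].str.strip())
        )
        missing = [s for s in df.columns if s not in mapping]
        if missing:
            raise ValueError(f"label sidecar missing samples: {missing[:5]}")
        raw_labels = [mapping[s] for s in df.columns]
    else:
        if label_row not in df.index:
            raise ValueError(
                f"label row {label_row!r} not found and no sidecar labels given"
            )
        raw_labels = df.loc[label_row].tolist()
        df = df.drop(index=label_row)

    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier: {dupes[:5]}")

    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in expression table: {exc}") from None

    labels, class_names = _encode_labels(raw_labels, positive_label)
    m = ExpressionMatrix(
        gene_ids=df.index.tolist(),
        sample_ids=df.columns.tolist(),
        values=values,
        labels=labels,
        class_names=class_names,
    )
    m.require_two_classes()
    return m


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

@dataclass
class OntologyDAG:
    """Term DAG with child→parent ``is_a`` edges.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child to
    parent, so the ancestors of a term are its graph descendants.
    """

    terms: dict[str, dict]  # term id -> {"name": str, "namespace": str}
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u not in self.terms or v not in self.terms:
                raise ValueError(f"edge endpoint not a known term: {u} -> {v}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("cyclic is_a structure: ontology is not a DAG")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str, inclusive: bool = True) -> set[str]:
        """Inclusive (by default) ancestor set of ``term``."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        anc = nx.descendants(self.graph, term)  # edges run child -> parent
        if inclusive:
            anc = anc | {term}
        return anc

    def descendants(self, term: str, inclusive: bool = True) -> set[str]:
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        des = nx.ancestors(self.graph, term)
        if inclusive:
            des = des | {term}
        return des

    def namespace(self, term: str) -> str:
        return self.terms[term].get("namespace", "")

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if self.graph.out_degree(t) == 0}


def _open_text(path: str | Path | io.TextIOBase):
    if isinstance(path, io.TextIOBase):
        return path, False
    return open(path, "r", encoding="utf-8"), True


def read_obo(
    path: str | Path | io.TextIOBase, include_part_of: bool = False
) -> OntologyDAG:
    """Parse the OBO 1.2 subset: [Term] stanzas with id/name/namespace/is_a.

    Obsolete terms are dropped, as are edges whose endpoint was dropped or
    never defined.  ``part_of`` relationships are ignored unless
    ``include_part_of`` is set, in which case they count as ancestry.
    """
    handle, close = _open_text(path)
    stanzas: list[dict] = []
    current: dict | None = None
    try:
        for line in handle:
            line = line.split("!", 1)[0].strip()
            if line == "[Term]":
                current = {"is_a": [], "part_of": [], "obsolete": False}
                stanzas.append(current)
                continue
            if line.startswith("[") and line.endswith("]"):
                current = None  # e.g. [Typedef]
                continue
            if current is None or ":" not in line:
                continue
            key, value = (s.strip() for s in line.split(":", 1))
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "namespace":
                current["namespace"] = value
            elif key == "is_a":
                current["is_a"].append(value.split()[0])
            elif key == "relationship":
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    current["part_of"].append(parts[1])
            elif key == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
    finally:
        if close:
            handle.close()

    terms: dict[str, dict] = {}
    for st in stanzas:
        if "id" not in st:
            raise ValueError("[Term] stanza missing id")
        if st["obsolete"]:
            continue
        terms[st["id"]] = {
            "name": st.get("name", st["id"]),
            "namespace": st.get("namespace", ""),
        }

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    n_dropped = 0
    for st in stanzas:
        if st.get("obsolete") or st.get("id") not in terms:
            continue
        parents = list(st["is_a"])
        if include_part_of:
            parents += st["part_of"]
        for parent in parents:
            if parent in terms:
                graph.add_edge(st["id"], parent)
            else:
                n_dropped += 1
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} is_a edge(s) to unknown/obsolete terms")
    return OntologyDAG(terms=terms, graph=graph)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialize the interpreted OBO subset (used for round-trip checks)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.terms):
        meta = dag.terms[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {meta['name']}")
        if meta.get("namespace"):
            lines.append(f"namespace: {meta['namespace']}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """gene → set of ontology term ids; genes may be absent (GO is incomplete)."""

    genes: dict[str, set[str]]
    n_skipped: int = 0  # annotations to unknown terms, dropped at read time

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def get(self, gene: str) -> set[str]:
        return self.genes.get(gene, set())

    def __len__(self) -> int:
        return len(self.genes)

    def items(self):
        return self.genes.items()

    def validate_against(self, dag: OntologyDAG) -> None:
        for gene, terms in self.genes.items():
            unknown = terms - dag.terms.keys()
            if unknown:
                raise ValueError(
                    f"gene {gene!r} annotated to unknown term(s) {sorted(unknown)}"
                )


def read_annotations(
    path: str | Path | io.TextIOBase,
    format: str = "two_column",
    dag: OntologyDAG | None = None,
    dialect: str = "tsv",
) -> AnnotationMap:
    """Read gene→term annotations.

    ``format='two_column'`` expects (gene_id, term_id) rows; ``format='gaf'``
    uses GAF 2.x columns 3 (object symbol) and 5 (term id), skipping ``!``
    comment lines.  Rows referencing terms absent from ``dag`` (when given)
    are skipped and counted in ``n_skipped``.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    handle, close = _open_text(path)
    genes: dict[str, set[str]] = {}
    n_skipped = 0
    try:
        for line in handle:
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if format == "two_column":
                if len(fields) < 2:
                    raise ValueError(f"malformed annotation row: {line!r}")
                gene, term = fields[0], fields[1]
            elif format == "gaf":
                if len(fields) < 5:
                    raise ValueError(f"malformed GAF row: {line!r}")
                gene, term = fields[2], fields[4]
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            if dag is not None and term not in dag:
                n_skipped += 1
                continue
            genes.setdefault(gene, set()).add(term)
    finally:
        if close:
            handle.close()
    if not genes:
        raise ValueError("empty annotation map")
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} annotation(s) to unknown terms")
    return AnnotationMap(genes=genes, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    m: ExpressionMatrix,
    log10_transform: bool = False,
    impute: bool = False,
    offset: float = 0.0,
    axis: str = "sample",
) -> ExpressionMatrix:
    """Impute (per-gene mean) → optional log10 → standardize each sample.

    ``axis='sample'`` (default) standardizes each sample column to mean 0 and
    unit variance with the package's n−1 SD estimator; ``axis='gene'`` is the
    non-default per-row alternative.  Under ``log10_transform`` all values
    (after adding ``offset``) must be strictly positive.
    """
    values = m.values.copy()

    if impute:
        gene_means = np.nanmean(values, axis=1)
        if np.isnan(gene_means).any():
            bad = [m.gene_ids[i] for i in np.flatnonzero(np.isnan(gene_means))]
            raise ValueError(f"gene(s) with all values missing: {bad[:5]}")
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = gene_means[nan_r]
    elif np.isnan(values).any():
        raise ValueError("missing values present; pass impute=True")

    if log10_transform:
        shifted = values + offset
        if np.any(shifted <= 0):
            raise ValueError(
                "non-positive value under log10 transform; supply an offset"
            )
        values = np.log10(shifted)

    ax = {"sample": 0, "gene": 1}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'sample' or 'gene', got {axis!r}")
    mean = values.mean(axis=ax, keepdims=True)
    sd = values.std(axis=ax, ddof=DDOF, keepdims=True)
    if np.any(sd == 0) or np.any(np.isnan(sd)):
        which = "sample column" if axis == "sample" else "gene row"
        raise ValueError(f"zero-variance {which}: cannot standardize")
    values = (values - mean) / sd

    return replace(m, values=values)
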