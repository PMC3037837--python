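"""Information-content based semantic similarity over an ontology DAG.

The frequency of a term is the number of gene→term annotation instances
citing the term or any of its descendants: each instance increments the
annotated term and every ancestor exactly once (duplicate DAG paths do not
double count).  Probabilities are frequencies over the corpus-wide maximum
frequency, information content is the negative natural log of the
probability, pairwise term similarity follows Lin (twice the IC of the most
informative common ancestor over the summed term ICs), and gene-level
similarity aggregates term pairs within a shared namespace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import AnnotationMap, OntologyDAG

__all__ = [
    "ICTable",
    "concept_frequency",
    "information_content",
    "shared_information",
    "lin_similarity",
    "gene_semantic_similarity",
    "semantic_similarity_matrix",
    "AGGREGATIONS",
]

AGGREGATIONS = ("best_match_average", "max", "average")


@dataclass
class ICTable:
    """Per-term annotation frequency, probability and information content.

    Terms with zero frequency carry undefined (NaN) IC and are rejected by
    similarity computations.
    """

    freq: dict[str, int]
    max_freq: int
    prob: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)

    def has_ic(self, term: str) -> bool:
        return math.isfinite(self.ic.get(term, math.nan))

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["term\tfreq\tprob\tic"]
        for term in sorted(self.freq):
            f = self.freq[term]
            p = self.prob.get(term, float("nan"))
            ic = self.ic.get(term, float("nan"))
            lines.append(f"{term}\t{f}\t{p:.10g}\t{ic:.10g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_annotations(cls, dag: OntologyDAG, ann: AnnotationMap) -> "ICTable":
        return information_content(concept_frequency(dag, ann))


def concept_frequency(dag: OntologyDAG, ann: AnnotationMap) -> ICTable:
    """Count annotation instances per term, propagated to all ancestors.

    Each (gene, term) annotation instance contributes 1 to the term itself
    and to each of its ancestors (inclusive ancestor set, so multiple DAG
    paths count once).  Returns an :class:`ICTable` with only the frequency
    part filled in; feed it to :func:`information_content`.
    """
    freq: dict[str, int] = {t: 0 for t in dag.terms}
    anc_cache: dict[str, set[str]] = {}
    total = 0
    for gene, terms in ann.items():
        for term in terms:
            if term not in dag:
                raise ValueError(f"annotation to unknown term {term!r} (gene {gene!r})")
            anc = anc_cache.get(term)
            if anc is None:
                anc = anc_cache[term] = dag.ancestors(term, inclusive=True)
            for a in anc:
                freq[a] += 1
            total += 1
    if total == 0:
        raise ValueError("empty annotation corpus: no term has nonzero frequency")
    return ICTable(freq=freq, max_freq=max(freq.values()))


def information_content(table: ICTable) -> ICTable:
    """Fill probabilities and natural-log IC into a frequency table."""
    if table.max_freq < 1:
        raise ValueError("max_freq must be >= 1")
    prob: dict[str, float] = {}
    ic: dict[str, float] = {}
    for term, f in table.freq.items():
        if f == 0:
            prob[term] = 0.0
            ic[term] = float("nan")  # undefined, excluded from similarities
        else:
            p = f / table.max_freq
            prob[term] = p
            ic[term] = -math.log(p)
    table.prob = prob
    table.ic = ic
    return table


def _require_ic(ic: ICTable, term: str) -> float:
    value = ic.ic.get(term)
    if value is None:
        raise KeyError(f"term {term!r} not in IC table")
    if not math.isfinite(value):
        raise ValueError(f"term {term!r} has undefined information content")
    return value


def shared_information(c1: str, c2: str, dag: OntologyDAG, ic: ICTable) -> float:
    """IC of the most informative common ancestor (self counts as ancestor).

    Returns 0 with a warning when the terms share no ancestor with defined
    IC (e.g. a multi-root ontology).
    """
    common = dag.ancestors(c1) & dag.ancestors(c2)
    defined = [ic.ic[a] for a in common if ic.has_ic(a)]
    if not defined:
        warnings.warn(f"no common ancestor with defined IC for {c1!r}, {c2!r}")
        return 0.0
    return max(defined)


def lin_similarity(c1: str, c2: str, dag: OntologyDAG, ic: ICTable) -> float:
    """Lin similarity 2·Share(c1,c2)/(IC(c1)+IC(c2)) in [0, 1].

    Defined as 0 when both terms have zero IC (probability-1 terms share no
    discriminating information; avoids 0/0).
    """
    ic1 = _require_ic(ic, c1)
    ic2 = _require_ic(ic, c2)
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    sim = 2.0 * shared_information(c1, c2, dag, ic) / denom
    return min(max(sim, 0.0), 1.0)


def _aggregate(pair_matrix: np.ndarray, aggregation: str) -> float:
    if aggregation == "max":
        return float(pair_matrix.max())
    if aggregation == "average":
        return float(pair_matrix.mean())
    if aggregation == "best_match_average":
        # mean of each row's best match and each column's best match
        return float(
            (pair_matrix.max(axis=1).mean() + pair_matrix.max(axis=0).mean()) / 2.0
        )
    raise ValueError(f"unknown aggregation {aggregation!r}; use one of {AGGREGATIONS}")


def _term_pair_matrix(
    terms1: list[str], terms2: list[str], dag: OntologyDAG, ic: ICTable
) -> np.ndarray:
    mat = np.zeros((len(terms1), len(terms2)))
    for i, t1 in enumerate(terms1):
        ns1 = dag.namespace(t1)
        for j, t2 in enumerate(terms2):
            if ns1 == dag.namespace(t2):
                mat[i, j] = lin_similarity(t1, t2, dag, ic)
            # cross-namespace pairs contribute 0 (no shared ancestry)
    return mat


def gene_semantic_similarity(
    g1: str,
    g2: str,
    ann: AnnotationMap,
    dag: OntologyDAG,
    ic: ICTable,
    aggregation: str = "best_match_average",
) -> float | None:
    """Aggregate term-level Lin similarity over two genes' annotation sets.

    Returns ``None`` (UNDEFINED) when either gene has no usable annotation —
    the caller is expected to fall back to expression similarity alone.
    """
    terms1 = sorted(t for t in ann.get(g1) if ic.has_ic(t))
    terms2 = sorted(t for t in ann.get(g2) if ic.has_ic(t))
    if not terms1 or not terms2:
        return None
    mat = _term_pair_matrix(terms1, terms2, dag, ic)
    return _aggregate(mat, aggregation)


def semantic_similarity_matrix(
    genes: list[str],
    ann: AnnotationMap,
    dag: OntologyDAG,
    ic: ICTable,
    aggregation: str = "best_match_average",
) -> np.ndarray:
    """Pairwise gene semantic similarity; NaN marks UNDEFINED entries.

    Genes sharing an annotation signature are scored once (annotation sets
    in toy and real corpora repeat heavily), so this stays fast for the
    few-hundred-gene lists produced by the filtering stage.
    """
    sigs = [tuple(sorted(t for t in ann.get(g) if ic.has_ic(t))) for g in genes]
    uniq = sorted(set(sigs))
    sig_index = {s: i for i, s in enumerate(uniq)}
    cache: dict[tuple[int, int], float] = {}

    def sig_sim(a: int, b: int) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            sa, sb = uniq[key[0]], uniq[key[1]]
            if not sa or not sb:
                cache[key] = float("nan")
            else:
                cache[key] = _aggregate(
                    _term_pair_matrix(list(sa), list(sb), dag, ic), aggregation
                )
        return cache[key]

    n = len(genes)
    out = np.full((n, n), np.nan)
    idx = [sig_index[s] for s in sigs]
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = sig_sim(idx[i], idx[j])
    return out
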