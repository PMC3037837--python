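"""Redundancy reduction (stage 2): combined similarity and greedy pruning.

The pairwise gene similarity averages an expression part (Pearson
correlation across samples, |r| by default) with a semantic part (gene-level
Lin similarity from the ontology).  When the semantic part is UNDEFINED for
a pair — annotation missing for either gene — the similarity falls back to
the expression part alone and the pair's provenance records that.

The greedy pass walks a ranking from most to least discriminative, keeps the
current head and deletes every later gene whose similarity to it reaches the
threshold ``ts``; all surviving pairs end up strictly below ``ts``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .fisher_filter import GeneRanking
from .go_semantics import ICTable, semantic_similarity_matrix
from .io_core import AnnotationMap, ExpressionMatrix, OntologyDAG

__all__ = [
    "SimilarityModel",
    "expression_similarity",
    "combined_similarity",
    "greedy_reduce",
    "tune_threshold",
    "default_threshold_grid",
    "DEFAULT_TS",
]

#: Empirically tuned default similarity threshold.
DEFAULT_TS = 0.8

EXPRESSION_ONLY = "expression_only"
COMBINED = "combined"


def expression_similarity(
    x: np.ndarray, y: np.ndarray, absolute: bool = True
) -> float:
    """Pearson correlation of two expression vectors; |r| by default.

    Strong negative correlation still signals redundancy, hence the
    absolute-value default; ``absolute=False`` returns the raw signed r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need >= 3 samples for a meaningful correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero-variance expression vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(max(r, -1.0), 1.0)
    return abs(r) if absolute else r


@dataclass
class SimilarityModel:
    """Materialized pairwise similarity over an ordered gene list.

    ``matrix[i, j]`` is the similarity used by the greedy pass;
    ``expression_only[i, j]`` is True where the semantic part was UNDEFINED
    and the value degraded to expression similarity alone.
    """

    gene_ids: list[str]
    matrix: np.ndarray
    expression_only: np.ndarray
    ts: float = DEFAULT_TS
    mode: str = COMBINED

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not (0.0 <= self.ts <= 1.0):
            raise ValueError("ts must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def similarity(self, g1: str, g2: str) -> float:
        return float(self.matrix[self._index[g1], self._index[g2]])

    def provenance(self, g1: str, g2: str) -> str:
        return (
            EXPRESSION_ONLY
            if self.expression_only[self._index[g1], self._index[g2]]
            else COMBINED
        )

    @classmethod
    def build(
        cls,
        expr: ExpressionMatrix,
        genes: Sequence[str] | None = None,
        mode: str = COMBINED,
        pearson: str = "abs",
        aggregation: str = "best_match_average",
        dag: OntologyDAG | None = None,
        ann: AnnotationMap | None = None,
        ic: ICTable | None = None,
        ts: float = DEFAULT_TS,
    ) -> "SimilarityModel":
        """Build the dense pairwise model for ``genes`` (default: all).

        ``mode`` selects what feeds the matrix: ``'combined'`` averages
        expression and semantic parts (with expression-only fallback),
        ``'expression'`` uses Pearson alone, ``'semantic'`` uses the
        semantic part alone (0 where UNDEFINED, flagged in provenance).
        """
        gene_list = list(genes) if genes is not None else list(expr.gene_ids)
        sub = expr.subset_genes(gene_list)
        if np.any(sub.values.std(axis=1) == 0.0):
            flat = [g for g, s in zip(gene_list, sub.values.std(axis=1)) if s == 0.0]
            raise ValueError(f"zero-variance gene(s): {flat[:5]}")
        r = np.corrcoef(sub.values)
        r = np.clip(r, -1.0, 1.0)
        if pearson == "abs":
            s_exp = np.abs(r)
        elif pearson == "raw":
            s_exp = r
        else:
            raise ValueError(f"pearson must be 'abs' or 'raw', got {pearson!r}")

        if mode == "expression":
            matrix = s_exp
            expr_only = np.ones_like(s_exp, dtype=bool)
        elif mode in (COMBINED, "semantic"):
            if dag is None or ann is None:
                raise ValueError(f"mode {mode!r} requires an ontology and annotations")
            if len(ann) == 0:
                # fully unannotated corpus: semantic part UNDEFINED everywhere
                s_sem = np.full_like(s_exp, np.nan)
            else:
                if ic is None:
                    ic = ICTable.from_annotations(dag, ann)
                s_sem = semantic_similarity_matrix(gene_list, ann, dag, ic, aggregation)
            undefined = np.isnan(s_sem)
            if mode == COMBINED:
                matrix = np.where(undefined, s_exp, (s_exp + s_sem) / 2.0)
            else:
                matrix = np.where(undefined, 0.0, s_sem)
            expr_only = undefined
        else:
            raise ValueError(
                f"mode must be 'combined', 'expression' or 'semantic', got {mode!r}"
            )
        return cls(
            gene_ids=gene_list,
            matrix=matrix,
            expression_only=expr_only,
            ts=ts,
            mode=mode,
        )


def combined_similarity(
    g_i: str,
    g_j: str,
    expr: ExpressionMatrix,
    dag: OntologyDAG | None = None,
    ann: AnnotationMap | None = None,
    ic: ICTable | None = None,
    pearson: str = "abs",
    aggregation: str = "best_match_average",
) -> tuple[float, str]:
    """Similarity of one gene pair: (S_exp + S_sem)/2, or S_exp on fallback.

    Returns ``(similarity, provenance)`` with provenance ``'combined'`` or
    ``'expression_only'``.
    """
    from .go_semantics import gene_semantic_similarity

    xi = expr.values[expr.gene_index([g_i])[0]]
    xj = expr.values[expr.gene_index([g_j])[0]]
    s_exp = expression_similarity(xi, xj, absolute=(pearson == "abs"))
    s_sem = None
    if dag is not None and ann is not None:
        if ic is None:
            ic = ICTable.from_annotations(dag, ann)
        s_sem = gene_semantic_similarity(g_i, g_j, ann, dag, ic, aggregation)
    if s_sem is None:
        return s_exp, EXPRESSION_ONLY
    return (s_exp + s_sem) / 2.0, COMBINED


def greedy_reduce(
    ranked: GeneRanking, ts: float, sim: SimilarityModel
) -> GeneRanking:
    """Greedy pruning of a descending ranking against similarity threshold.

    Repeatedly keeps the list head and deletes every later gene with
    similarity >= ``ts`` to it.  Output preserves input order; every kept
    pair satisfies similarity < ``ts``.
    """
    if not (0.0 <= ts <= 1.0):
        raise ValueError(f"ts must lie in [0, 1], got {ts}")
    scores = {g: s for g, s in ranked}
    alive = list(ranked.gene_ids)
    kept: list[str] = []
    while alive:
        head, rest = alive[0], alive[1:]
        kept.append(head)
        alive = [g for g in rest if sim.similarity(head, g) < ts]
    return GeneRanking(kept, np.array([scores[g] for g in kept]))


def default_threshold_grid() -> np.ndarray:
    """The tuning grid 0.10, 0.15, …, 0.95 (18 values)."""
    return np.round(0.10 + 0.05 * np.arange(18), 2)


def tune_threshold(
    expr: ExpressionMatrix,
    variant: str = "fisher_rg_svmrfe",
    config=None,
    grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    whole_data: bool = False,
) -> tuple[float, dict[float, float]]:
    """Pick the grid threshold maximizing mean CV accuracy.

    By default each candidate is scored with external CV (selection redone
    inside training folds).  ``whole_data=True`` scores with the biased
    internal protocol instead — explicitly labelled as biased; use only for
    demonstrations.  Ties break toward the larger threshold (fewer
    removals).
    """
    from .evaluation_cv import PipelineConfig, external_cv, internal_cv_biased

    if grid is None:
        grid = default_threshold_grid()
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("empty threshold grid")
    if config is None:
        config = PipelineConfig()
    if whole_data:
        warnings.warn("whole-data threshold tuning is subject to selection bias")
    runner = internal_cv_biased if whole_data else external_cv
    accuracies: dict[float, float] = {}
    for ts in grid:
        report = runner(
            expr, variant, config=replace(config, ts=ts), folds=folds, seed=seed
        )
        accuracies[ts] = report.accuracy
    best = max(accuracies.values())
    best_ts = max(t for t, a in accuracies.items() if a == best)
    return best_ts, accuracies
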