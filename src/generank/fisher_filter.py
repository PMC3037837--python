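"""Fisher-criterion gene ranking (stage 1).

Scores each gene by (m1 − m2)² / (s1² + s2²), the squared between-class mean
difference over the summed within-class variances, and keeps the top ``k``
genes for the downstream stages.  Variances use the package-wide n−1
estimator.  Genes whose within-class variances are both zero score +inf when
the means differ (perfect separation) and 0 when they coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import DDOF, NEGATIVE, POSITIVE, ExpressionMatrix

__all__ = ["GeneRanking", "fisher_score", "rank_genes", "DEFAULT_K"]

#: Default number of genes kept by the filtering stage.
DEFAULT_K = 500


@dataclass
class GeneRanking:
    """Genes ordered by non-increasing score; ties keep input gene order."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene id in ranking")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(zip(self.gene_ids, self.scores))

    def head(self, k: int) -> "GeneRanking":
        return GeneRanking(self.gene_ids[:k], self.scores[:k])

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{g}\t{s:.10g}" for g, s in self]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def fisher_score(
    values_class1: np.ndarray, values_class2: np.ndarray, ddof: int = DDOF
) -> float:
    """Fisher criterion for one gene given its per-class expression vectors."""
    v1 = np.asarray(values_class1, dtype=float)
    v2 = np.asarray(values_class2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise ValueError("each class needs >= 2 samples for the Fisher score")
    num = (v1.mean() - v2.mean()) ** 2
    den = v1.var(ddof=ddof) + v2.var(ddof=ddof)
    if den == 0.0:
        return float("inf") if num > 0.0 else 0.0
    return float(num / den)


def _scores_vectorized(m: ExpressionMatrix) -> np.ndarray:
    pos = m.values[:, m.labels == POSITIVE]
    neg = m.values[:, m.labels == NEGATIVE]
    num = (pos.mean(axis=1) - neg.mean(axis=1)) ** 2
    den = pos.var(axis=1, ddof=DDOF) + neg.var(axis=1, ddof=DDOF)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num == 0)] = 0.0
    scores[(den == 0) & (num > 0)] = np.inf
    return scores


def rank_genes(m: ExpressionMatrix, k: int = DEFAULT_K) -> GeneRanking:
    """Rank all genes by Fisher score and keep the top ``min(k, n_genes)``.

    Descending order, stable tie-break by original gene order.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    m.require_two_classes()
    scores = _scores_vectorized(m)
    order = np.argsort(-scores, kind="stable")
    order = order[: min(k, m.n_genes)]
    return GeneRanking(
        gene_ids=[m.gene_ids[i] for i in order], scores=scores[order]
    )
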