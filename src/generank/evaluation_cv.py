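"""External cross-validation, confusion metrics and the variant registry.

External CV reruns the *entire* selection pipeline (filter → redundancy →
RFE) inside each training fold, so held-out samples never influence which
genes are selected — the protocol that avoids selection bias.  The biased
internal protocol (selection once on all data, CV only on the classifier) is
kept solely to demonstrate the optimism it produces.

Variants compose the three stages; ``fisher_rg_svmrfe`` is the full
pipeline: Fisher top-k filter, greedy redundancy reduction with combined
expression + GO-semantic similarity, then SVM-RFE with best-subset
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .fisher_filter import DEFAULT_K, GeneRanking, rank_genes
from .go_semantics import ICTable
from .io_core import NEGATIVE, POSITIVE, AnnotationMap, ExpressionMatrix, OntologyDAG
from .redundancy import DEFAULT_TS, SimilarityModel, greedy_reduce
from .svmrfe import rfe_ranking, select_best_subset, train_linear_svm

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "CVReport",
    "PipelineConfig",
    "VARIANTS",
    "metrics",
    "fold_assignments",
    "select_genes",
    "external_cv",
    "internal_cv_biased",
    "run_variant",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
            tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
            fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
            fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
        )


def metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(accuracy, sensitivity, specificity); ``None`` on a zero denominator."""
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return accuracy, sensitivity, specificity


# ---------------------------------------------------------------------------
# Configuration and variants
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Knobs shared by all pipeline variants.

    The ontology context (``dag``/``ann``/``ic``) is only consulted by
    variants whose redundancy stage uses semantic similarity; ``ic`` is
    derived from the annotation corpus once if not supplied.
    """

    filter_k: int = DEFAULT_K
    ts: float = DEFAULT_TS
    sim_mode: str = "combined"  # for the *_rg variants
    pearson: str = "abs"
    aggregation: str = "best_match_average"
    svm_c: float = 1.0
    rfe_step: int | float = 1
    inner_folds: int = 5
    dag: OntologyDAG | None = None
    ann: AnnotationMap | None = None
    ic: ICTable | None = None

    def resolved_ic(self) -> ICTable | None:
        if (
            self.ic is None
            and self.dag is not None
            and self.ann is not None
            and len(self.ann) > 0
        ):
            self.ic = ICTable.from_annotations(self.dag, self.ann)
        return self.ic


@dataclass(frozen=True)
class _Variant:
    fisher: bool
    redundancy: str | None  # None | "expression" | "combined"
    rfe: bool


#: Stage composition per variant name; fisher_rg_svmrfe is the full pipeline.
VARIANTS: dict[str, _Variant] = {
    "none": _Variant(fisher=False, redundancy=None, rfe=False),
    "fisher": _Variant(fisher=True, redundancy=None, rfe=False),
    "svmrfe": _Variant(fisher=False, redundancy=None, rfe=True),
    "fisher_r": _Variant(fisher=True, redundancy="expression", rfe=False),
    "fisher_rg": _Variant(fisher=True, redundancy="combined", rfe=False),
    "svmrfe_r": _Variant(fisher=False, redundancy="expression", rfe=True),
    "svmrfe_rg": _Variant(fisher=False, redundancy="combined", rfe=True),
    "fisher_svmrfe": _Variant(fisher=True, redundancy=None, rfe=True),
    "fisher_r_svmrfe": _Variant(fisher=True, redundancy="expression", rfe=True),
    "fisher_rg_svmrfe": _Variant(fisher=True, redundancy="combined", rfe=True),
}


def _resolve_variant(name: str) -> _Variant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
        ) from None


def select_genes(
    train: ExpressionMatrix,
    variant_name: str,
    config: PipelineConfig,
    seed: int = 0,
) -> list[str]:
    """Run one variant's selection stages on (training) data only."""
    variant = _resolve_variant(variant_name)

    if variant.fisher:
        ranking = rank_genes(train, k=config.filter_k)
    elif variant.redundancy is not None or variant.rfe:
        if variant.redundancy is not None and not variant.fisher:
            # svmrfe_r / svmrfe_rg: greedy needs a discriminative ranking;
            # derive it from a full RFE pass (survivors first).
            order = rfe_ranking(
                train.X,
                train.labels,
                step=config.rfe_step,
                C=config.svm_c,
                feature_ids=train.gene_ids,
            )
            scores = np.arange(len(order), dtype=float)[::-1]
            ranking = GeneRanking(order.survival_order(), scores)
        else:
            ranking = GeneRanking(
                list(train.gene_ids), np.zeros(train.n_genes)
            )
    else:
        return list(train.gene_ids)

    if variant.redundancy is not None:
        mode = variant.redundancy
        sim = SimilarityModel.build(
            train,
            genes=ranking.gene_ids,
            mode=mode,
            pearson=config.pearson,
            aggregation=config.aggregation,
            dag=config.dag if mode == "combined" else None,
            ann=config.ann if mode == "combined" else None,
            ic=config.resolved_ic() if mode == "combined" else None,
            ts=config.ts,
        )
        ranking = greedy_reduce(ranking, config.ts, sim)

    if not variant.rfe:
        return list(ranking.gene_ids)

    sub = train.subset_genes(ranking.gene_ids)
    order = rfe_ranking(
        sub.X,
        train.labels,
        step=config.rfe_step,
        C=config.svm_c,
        feature_ids=sub.gene_ids,
    )
    feature_index = {g: i for i, g in enumerate(sub.gene_ids)}
    return select_best_subset(
        order,
        sub.X,
        train.labels,
        inner_folds=config.inner_folds,
        C=config.svm_c,
        seed=seed,
        feature_index=feature_index,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    test_sample_ids: list[str]
    selected_genes: list[str]
    confusion: ConfusionCounts


@dataclass
class CVReport:
    fold_results: list[FoldResult]
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    seed: int
    variant: str
    mode: str  # "external" or "internal_biased"
    folds: int

    def selection_frequency(self) -> dict[str, float]:
        counts: dict[str, int] = {}
        for fr in self.fold_results:
            for g in fr.selected_genes:
                counts[g] = counts.get(g, 0) + 1
        n = len(self.fold_results)
        return {g: c / n for g, c in sorted(counts.items())}

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "mode": self.mode,
            "folds": self.folds,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold": [
                {
                    "fold": fr.fold,
                    "test_samples": fr.test_sample_ids,
                    "selected_genes": fr.selected_genes,
                    "confusion": {
                        "tp": fr.confusion.tp,
                        "tn": fr.confusion.tn,
                        "fp": fr.confusion.fp,
                        "fn": fr.confusion.fn,
                    },
                }
                for fr in self.fold_results
            ],
        }


def fold_assignments(
    labels: np.ndarray, folds: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Deterministic fold index per sample given (labels, folds, seed)."""
    labels = np.asarray(labels)
    n = len(labels)
    min_class = int(np.min(np.bincount((labels == labels.max()).astype(int))))
    if stratified and folds > min_class:
        stratified = False  # cannot stratify; caller is warned by _run_cv
    if stratified:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)), labels)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)))
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = fold
    return assignment


def _mean_or_none(values: list[float | None], name: str) -> float | None:
    defined = [v for v in values if v is not None]
    if len(defined) < len(values):
        warnings.warn(
            f"{len(values) - len(defined)} fold(s) had undefined {name}; "
            "excluded from the mean"
        )
    return float(np.mean(defined)) if defined else None


def _run_cv(
    expr: ExpressionMatrix,
    variant_name: str,
    config: PipelineConfig,
    folds: int,
    seed: int,
    stratified: bool,
    preselected: list[str] | None,
    mode: str,
) -> CVReport:
    _resolve_variant(variant_name)
    expr.require_two_classes()
    min_class = int(min(np.sum(expr.labels == POSITIVE), np.sum(expr.labels == NEGATIVE)))
    if folds > min_class:
        warnings.warn(
            f"folds={folds} exceeds the smaller class size {min_class}; "
            "some folds may lack a class"
        )
    assignment = fold_assignments(expr.labels, folds, seed, stratified)

    fold_results: list[FoldResult] = []
    accs: list[float | None] = []
    sens: list[float | None] = []
    specs: list[float | None] = []
    for fold in range(folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train = expr.subset_samples(train_idx)
        test = expr.subset_samples(test_idx)
        if len(np.unique(train.labels)) < 2:
            raise ValueError(f"fold {fold}: training data contains a single class")

        selected = (
            preselected
            if preselected is not None
            else select_genes(train, variant_name, config, seed=seed)
        )
        model = train_linear_svm(
            train.subset_genes(selected).X, train.labels, C=config.svm_c
        )
        y_pred = model.predict(test.subset_genes(selected).X)
        confusion = ConfusionCounts.from_predictions(test.labels, y_pred)
        a, sn, sp = metrics(confusion)
        accs.append(a)
        sens.append(sn)
        specs.append(sp)
        fold_results.append(
            FoldResult(
                fold=fold,
                test_sample_ids=list(test.sample_ids),
                selected_genes=list(selected),
                confusion=confusion,
            )
        )

    return CVReport(
        fold_results=fold_results,
        accuracy=_mean_or_none(accs, "accuracy"),
        sensitivity=_mean_or_none(sens, "sensitivity"),
        specificity=_mean_or_none(specs, "specificity"),
        seed=seed,
        variant=variant_name,
        mode=mode,
        folds=folds,
    )


def external_cv(
    expr: ExpressionMatrix,
    variant: str,
    config: PipelineConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVReport:
    """Selection-bias-free CV: the whole pipeline reruns per training fold."""
    config = config or PipelineConfig()
    return _run_cv(
        expr, variant, config, folds, seed, stratified, preselected=None,
        mode="external",
    )


def internal_cv_biased(
    expr: ExpressionMatrix,
    variant: str,
    config: PipelineConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVReport:
    """Biased protocol: genes selected ONCE on all data, CV on the classifier.

    Kept only to demonstrate the optimism of internal CV; never use its
    numbers as performance estimates.
    """
    config = config or PipelineConfig()
    selected = select_genes(expr, variant, config, seed=seed)
    return _run_cv(
        expr, variant, config, folds, seed, stratified, preselected=selected,
        mode="internal_biased",
    )


def run_variant(
    expr: ExpressionMatrix,
    variant_name: str,
    config: PipelineConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[list[str], CVReport]:
    """External CV report plus a whole-data selection (labelled as such).

    The whole-data gene list is what a practitioner would report as the
    final candidate set; per-fold selection frequencies live in the report.
    """
    config = config or PipelineConfig()
    report = external_cv(expr, variant_name, config=config, folds=folds, seed=seed)
    final_selection = select_genes(expr, variant_name, config, seed=seed)
    return final_selection, report
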