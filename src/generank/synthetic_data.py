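"""Synthetic two-class expression data with planted structure.

Generates genes × samples matrices with class-independent Gaussian
background, planted differential genes (mean shift in within-class SD
units), planted redundant near-copy groups, and a matching toy ontology
whose annotations mirror the redundancy structure: every redundancy group
shares a leaf term (high semantic similarity within the group) while other
genes scatter across distinct subtrees.  All randomness is driven by the
spec's seed.

Values are emitted on the post-preprocessing scale (≈ standard normal per
sample) by default; ``raw_intensity=True`` exponentiates to a lognormal
scale for exercising the preprocessing path.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .io_core import (
    NEGATIVE,
    POSITIVE,
    AnnotationMap,
    ExpressionMatrix,
    OntologyDAG,
    read_obo,
)

__all__ = [
    "RedundantGroup",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticBundle",
    "generate_expression",
    "generate_ontology",
    "make_bundle",
    "make_fixture",
    "write_bundle",
    "FIXTURES",
]


@dataclass(frozen=True)
class RedundantGroup:
    """``n_copies`` noisy duplicates of the ``source``-th informative gene."""

    source: int  # index into the informative genes
    n_copies: int
    copy_noise_sd: float


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 1000
    n_samples_per_class: int = 20
    n_informative: int = 20
    effect_size: float = 2.0
    redundant_groups: tuple[RedundantGroup, ...] = (
        RedundantGroup(0, 5, 0.3),
        RedundantGroup(1, 5, 0.3),
        RedundantGroup(2, 5, 0.3),
        RedundantGroup(3, 5, 0.3),
        RedundantGroup(4, 5, 0.3),
    )
    ontology_depth: int = 3
    ontology_branching: int = 3
    unannotated_fraction: float = 0.3
    multi_parent: bool = False
    raw_intensity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total_copies = sum(g.n_copies for g in self.redundant_groups)
        if self.n_informative + total_copies > self.n_genes:
            raise ValueError("n_informative + total copies exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_samples_per_class < 2:
            raise ValueError("need >= 2 samples per class")
        for g in self.redundant_groups:
            if not (0 <= g.source < max(self.n_informative, 1)):
                raise ValueError(f"group source {g.source} is not informative")
            if g.n_copies < 1 or g.copy_noise_sd < 0:
                raise ValueError("invalid redundant group parameters")


@dataclass
class GroundTruth:
    informative: list[str]
    groups: dict[str, list[str]]  # group name -> [source, copies...]
    annotations: dict[str, list[str]]
    unannotated: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative": self.informative,
                "groups": self.groups,
                "annotations": self.annotations,
                "unannotated": self.unannotated,
            },
            indent=2,
            sort_keys=True,
        )


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]


def _layout(spec: SyntheticSpec) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Deterministic gene layout: informative first, then copies, then noise."""
    ids = _gene_ids(spec)
    informative = ids[: spec.n_informative]
    groups: dict[str, list[str]] = {}
    cursor = spec.n_informative
    for gi, grp in enumerate(spec.redundant_groups):
        members = [informative[grp.source]]
        members += ids[cursor : cursor + grp.n_copies]
        cursor += grp.n_copies
        groups[f"group{gi}"] = members
    return ids, informative, groups


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Planted-signal matrix; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    ids, informative, groups = _layout(spec)
    n = spec.n_samples_per_class
    labels = np.array([POSITIVE] * n + [NEGATIVE] * n)
    sample_ids = [f"s{i:03d}" for i in range(1, 2 * n + 1)]

    values = rng.standard_normal((spec.n_genes, 2 * n))
    values[: spec.n_informative, :n] += spec.effect_size

    index = {g: i for i, g in enumerate(ids)}
    for grp, members in zip(spec.redundant_groups, groups.values()):
        src = values[index[members[0]]]
        for copy_id in members[1:]:
            values[index[copy_id]] = src + grp.copy_noise_sd * rng.standard_normal(
                2 * n
            )
    if spec.raw_intensity:
        values = np.power(10.0, values + 3.0)  # lognormal-ish raw intensities

    _, _, ann, unannotated = _ontology_parts(spec)
    truth = GroundTruth(
        informative=informative,
        groups=groups,
        annotations={g: sorted(t) for g, t in sorted(ann.genes.items())},
        unannotated=unannotated,
    )
    expr = ExpressionMatrix(
        gene_ids=ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        class_names={POSITIVE: "tumor", NEGATIVE: "normal"},
    )
    return expr, truth


def _ontology_parts(
    spec: SyntheticSpec,
) -> tuple[str, OntologyDAG, AnnotationMap, list[str]]:
    """Balanced is_a tree + annotations mirroring the redundancy structure."""
    depth, branching = spec.ontology_depth, spec.ontology_branching
    if depth < 2 or branching < 2:
        raise ValueError("ontology needs depth >= 2 and branching >= 2")

    terms: list[str] = []
    parents: dict[str, str] = {}
    levels: list[list[str]] = [["T000000"]]
    terms.append("T000000")
    counter = 1
    for _ in range(depth):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                tid = f"T{counter:06d}"
                counter += 1
                terms.append(tid)
                parents[tid] = parent
                level.append(tid)
        levels.append(level)
    leaves = levels[-1]

    extra_edges: list[tuple[str, str]] = []
    if spec.multi_parent and len(levels) >= 3 and len(levels[-2]) >= 2:
        # give the first leaf a second parent to exercise true-DAG ancestry
        second = levels[-2][1] if parents[leaves[0]] != levels[-2][1] else levels[-2][0]
        extra_edges.append((leaves[0], second))

    lines = ["format-version: 1.2", ""]
    for tid in terms:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: synthetic term {tid}")
        lines.append("namespace: biological_process")
        if tid in parents:
            lines.append(f"is_a: {parents[tid]}")
        for child, parent in extra_edges:
            if child == tid:
                lines.append(f"is_a: {parent}")
        lines.append("")
    obo_text = "\n".join(lines)
    dag = read_obo(io.StringIO(obo_text))

    # annotations: one shared leaf per redundancy group; everything else
    # scattered over the remaining leaves; a fraction of the background
    # genes stays unannotated (GO is incomplete).
    rng = np.random.default_rng(spec.seed + 1)
    ids, informative, groups = _layout(spec)
    genes_ann: dict[str, set[str]] = {}
    leaf_pool = list(leaves)
    group_leaves = leaf_pool[: len(groups)]
    other_leaves = leaf_pool[len(groups) :] or leaf_pool

    grouped_genes: set[str] = set()
    for leaf, members in zip(group_leaves, groups.values()):
        for g in members:
            genes_ann[g] = {leaf}
            grouped_genes.add(g)

    # fraction applies to genes outside redundancy groups; group members stay
    # annotated so the semantics mirror the planted redundancy structure
    unannotated: list[str] = []
    for g in ids:
        if g in grouped_genes:
            continue
        if rng.random() < spec.unannotated_fraction:
            unannotated.append(g)
            continue
        genes_ann[g] = {other_leaves[rng.integers(len(other_leaves))]}
    ann = AnnotationMap(genes=genes_ann)
    return obo_text, dag, ann, unannotated


def generate_ontology(spec: SyntheticSpec) -> tuple[str, AnnotationMap]:
    """OBO text for the toy ontology plus the matching annotation map."""
    obo_text, _, ann, _ = _ontology_parts(spec)
    return obo_text, ann


# ---------------------------------------------------------------------------
# Bundles and fixtures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    spec: SyntheticSpec | None
    expr: ExpressionMatrix | None
    truth: GroundTruth | None
    obo_text: str
    dag: OntologyDAG
    ann: AnnotationMap


def make_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    expr, truth = generate_expression(spec)
    obo_text, dag, ann, _ = _ontology_parts(spec)
    return SyntheticBundle(
        spec=spec, expr=expr, truth=truth, obo_text=obo_text, dag=dag, ann=ann
    )


_GO_FIXTURE_OBO = """\
format-version: 1.2

[Term]
id: R
name: root
namespace: biological_process

[Term]
id: A
name: branch a
namespace: biological_process
is_a: R

[Term]
id: B
name: branch b
namespace: biological_process
is_a: R

[Term]
id: A1
name: leaf a1
namespace: biological_process
is_a: A

[Term]
id: A2
name: leaf a2
namespace: biological_process
is_a: A
"""

#: gene -> annotated term for the 5-term oracle DAG
_GO_FIXTURE_ANN = {"g1": {"A1"}, "g2": {"A2"}, "g3": {"B"}, "g4": {"A"}, "g5": {"R"}}

FIXTURES = ("tiny_separable", "duplicates_heavy", "pure_noise", "go_fixture")


def make_fixture(name: str, seed: int = 0) -> SyntheticBundle:
    """Deterministic packaged instances used across the test suite."""
    if name == "tiny_separable":
        spec = SyntheticSpec(
            n_genes=50,
            n_samples_per_class=10,
            n_informative=3,
            effect_size=3.0,
            redundant_groups=(),
            ontology_depth=2,
            ontology_branching=2,
            unannotated_fraction=0.5,
            seed=seed,
        )
        return make_bundle(spec)
    if name == "duplicates_heavy":
        spec = SyntheticSpec(
            n_genes=100,
            n_samples_per_class=10,
            n_informative=10,
            effect_size=2.0,
            redundant_groups=tuple(RedundantGroup(i, 5, 0.2) for i in range(5)),
            ontology_depth=3,
            ontology_branching=3,
            unannotated_fraction=0.3,
            seed=seed,
        )
        return make_bundle(spec)
    if name == "pure_noise":
        spec = SyntheticSpec(
            n_genes=500,
            n_samples_per_class=15,
            n_informative=0,
            effect_size=0.0,
            redundant_groups=(),
            ontology_depth=2,
            ontology_branching=2,
            unannotated_fraction=0.5,
            seed=seed,
        )
        return make_bundle(spec)
    if name == "go_fixture":
        dag = read_obo(io.StringIO(_GO_FIXTURE_OBO))
        ann = AnnotationMap(genes={g: set(t) for g, t in _GO_FIXTURE_ANN.items()})
        return SyntheticBundle(
            spec=None, expr=None, truth=None,
            obo_text=_GO_FIXTURE_OBO, dag=dag, ann=ann,
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write expr.tsv, labels.tsv, go.obo, ann.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle.expr is not None:
        bundle.expr.to_frame().to_csv(outdir / "expr.tsv", sep="\t")
        with open(outdir / "labels.tsv", "w", encoding="utf-8") as fh:
            for sid, lab in zip(bundle.expr.sample_ids, bundle.expr.labels):
                fh.write(f"{sid}\t{bundle.expr.class_names[int(lab)]}\n")
    (outdir / "go.obo").write_text(bundle.obo_text, encoding="utf-8")
    with open(outdir / "ann.tsv", "w", encoding="utf-8") as fh:
        for gene, terms in sorted(bundle.ann.items()):
            for term in sorted(terms):
                fh.write(f"{gene}\t{term}\n")
    if bundle.truth is not None:
        (outdir / "truth.json").write_text(bundle.truth.to_json(), encoding="utf-8")
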