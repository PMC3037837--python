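import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from generank.go_semantics import (
    ICTable,
    concept_frequency,
    gene_semantic_similarity,
    information_content,
    lin_similarity,
    semantic_similarity_matrix,
    shared_information,
)
from generank.io_core import AnnotationMap, OntologyDAG, read_obo


# ---------------------------------------------------------------------------
# Independent oracles (brute force over explicit ancestor sets)
# ---------------------------------------------------------------------------

def brute_freq(dag, ann):
    instances = [(g, t) for g, ts in ann.items() for t in ts]
    return {
        term: sum(1 for _, t in instances if t in dag.descendants(term))
        for term in dag.terms
    }


def brute_share(dag, ic, c1, c2):
    common = dag.ancestors(c1) & dag.ancestors(c2)
    defined = [ic.ic[a] for a in common if math.isfinite(ic.ic[a])]
    return max(defined) if defined else 0.0


def brute_lin(dag, ic, c1, c2):
    denom = ic.ic[c1] + ic.ic[c2]
    return 0.0 if denom == 0 else 2 * brute_share(dag, ic, c1, c2) / denom


def make_dag(edges, terms=None, namespaces=None):
    terms = terms or sorted({t for e in edges for t in e})
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    meta = {
        t: {"name": t, "namespace": (namespaces or {}).get(t, "bp")} for t in terms
    }
    return OntologyDAG(terms=meta, graph=g)


# ---------------------------------------------------------------------------
# concept_frequency
# ---------------------------------------------------------------------------

def test_frequency_two_leaf_example():
    # root with children A, B; g1→A, g2→B  ⇒  A=1, B=1, root=2, maxFreq=2
    dag = make_dag([("A", "root"), ("B", "root")])
    ann = AnnotationMap(genes={"g1": {"A"}, "g2": {"B"}})
    table = concept_frequency(dag, ann)
    assert table.freq == {"A": 1, "B": 1, "root": 2}
    assert table.max_freq == 2


def test_frequency_go_fixture_hand_counts(go_bundle):
    table = concept_frequency(go_bundle.dag, go_bundle.ann)
    assert table.freq == {"R": 5, "A": 3, "B": 1, "A1": 1, "A2": 1}
    assert table.max_freq == 5
    assert table.freq == brute_freq(go_bundle.dag, go_bundle.ann)


def test_empty_corpus_rejected():
    dag = make_dag([("A", "root")])
    with pytest.raises(ValueError, match="empty annotation corpus"):
        concept_frequency(dag, AnnotationMap(genes={"g1": set()}))


def test_root_only_annotation():
    dag = make_dag([("A", "root"), ("B", "root")])
    table = concept_frequency(dag, AnnotationMap(genes={"g1": {"root"}}))
    assert table.freq == {"root": 1, "A": 0, "B": 0}


def test_unknown_term_defensive_error():
    dag = make_dag([("A", "root")])
    with pytest.raises(ValueError, match="unknown term"):
        concept_frequency(dag, AnnotationMap(genes={"g1": {"ZZZ"}}))


def test_duplicate_paths_count_once():
    # diamond: L is_a P1, L is_a P2, both is_a root; one instance at L
    dag = make_dag([("L", "P1"), ("L", "P2"), ("P1", "root"), ("P2", "root")])
    table = concept_frequency(dag, AnnotationMap(genes={"g": {"L"}}))
    assert table.freq["root"] == 1  # not 2, despite two paths


# ---------------------------------------------------------------------------
# information_content
# ---------------------------------------------------------------------------

def test_ic_values(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert ic.ic["R"] == pytest.approx(0.0)  # freq = maxFreq → prob 1 → ic 0
    assert ic.ic["A"] == pytest.approx(-math.log(3 / 5))
    assert ic.ic["B"] == pytest.approx(-math.log(1 / 5))


def test_ic_half_max_is_ln2():
    dag = make_dag([("A", "root"), ("B", "root")])
    ann = AnnotationMap(genes={"g1": {"A"}, "g2": {"B"}})
    ic = ICTable.from_annotations(dag, ann)
    assert ic.ic["A"] == pytest.approx(math.log(2))


def test_zero_freq_term_ic_undefined():
    dag = make_dag([("A", "root"), ("B", "root")])
    ic = ICTable.from_annotations(dag, AnnotationMap(genes={"g1": {"A"}}))
    assert not ic.has_ic("B")
    assert math.isnan(ic.ic["B"])


def test_ic_monotone_along_ancestry(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    for child, parent in dag.graph.edges():
        assert ic.ic[child] >= ic.ic[parent] - 1e-12


def test_ic_tsv_export(tmp_path, go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    path = tmp_path / "ic.tsv"
    ic.to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "term\tfreq\tprob\tic"
    assert len(lines) == 6


# ---------------------------------------------------------------------------
# shared_information / lin_similarity
# ---------------------------------------------------------------------------

def test_share_self_is_own_ic(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert shared_information("A1", "A1", go_bundle.dag, ic) == pytest.approx(
        ic.ic["A1"]
    )


def test_share_root_only_common_ancestor_is_zero(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    # A1 and B only share the root R, whose ic is 0
    assert shared_information("A1", "B", go_bundle.dag, ic) == pytest.approx(0.0)


def test_share_equals_bruteforce_on_fixture(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    for c1, c2 in itertools.combinations_with_replacement(sorted(dag.terms), 2):
        assert shared_information(c1, c2, dag, ic) == pytest.approx(
            brute_share(dag, ic, c1, c2)
        )


def test_share_no_common_ancestor_warns():
    g = nx.DiGraph()
    g.add_nodes_from(["X", "Y"])
    dag = OntologyDAG(terms={t: {"name": t, "namespace": "bp"} for t in "XY"}, graph=g)
    ic = ICTable.from_annotations(dag, AnnotationMap(genes={"g1": {"X"}, "g2": {"Y"}}))
    with pytest.warns(UserWarning, match="no common ancestor"):
        assert shared_information("X", "Y", dag, ic) == 0.0


def test_lin_identity_is_one(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert lin_similarity("A1", "A1", go_bundle.dag, ic) == pytest.approx(1.0)


def test_lin_root_pair_defined_zero(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert lin_similarity("R", "R", go_bundle.dag, ic) == 0.0  # 0/0 → 0 by contract


def test_lin_fixture_hand_value(go_bundle):
    # Share(A1,A2)=ic(A)=ln(5/3); lin = 2·ln(5/3)/(2·ln5) ≈ 0.3173938055
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert lin_similarity("A1", "A2", go_bundle.dag, ic) == pytest.approx(
        math.log(5 / 3) / math.log(5)
    )
    assert lin_similarity("A1", "A2", go_bundle.dag, ic) == pytest.approx(
        0.3173938055, abs=1e-9
    )


def test_lin_undefined_ic_errors():
    dag = make_dag([("A", "root"), ("B", "root")])
    ic = ICTable.from_annotations(dag, AnnotationMap(genes={"g1": {"A"}}))
    with pytest.raises(ValueError, match="'B'"):
        lin_similarity("A", "B", dag, ic)


def test_lin_symmetric_and_bounded(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    for c1, c2 in itertools.combinations(sorted(dag.terms), 2):
        s12 = lin_similarity(c1, c2, dag, ic)
        assert s12 == lin_similarity(c2, c1, dag, ic)
        assert 0.0 <= s12 <= 1.0


# ---------------------------------------------------------------------------
# gene-level similarity
# ---------------------------------------------------------------------------

def test_same_single_term_gives_one(go_bundle):
    dag, ic = go_bundle.dag, ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    ann = AnnotationMap(genes={"x": {"A1"}, "y": {"A1"}})
    for agg in ("best_match_average", "max", "average"):
        assert gene_semantic_similarity("x", "y", ann, dag, ic, agg) == pytest.approx(
            1.0
        )


def test_unannotated_gene_undefined(go_bundle):
    ic = ICTable.from_annotations(go_bundle.dag, go_bundle.ann)
    assert (
        gene_semantic_similarity("g1", "nobody", go_bundle.ann, go_bundle.dag, ic)
        is None
    )


def test_two_term_pairs_match_bruteforce(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    ann = AnnotationMap(genes={"x": {"A1", "B"}, "y": {"A2", "A"}})
    pairs = np.array(
        [
            [brute_lin(dag, ic, t1, t2) for t2 in sorted(ann.get("y"))]
            for t1 in sorted(ann.get("x"))
        ]
    )
    expect = {
        "max": pairs.max(),
        "average": pairs.mean(),
        "best_match_average": (pairs.max(axis=1).mean() + pairs.max(axis=0).mean())
        / 2,
    }
    for agg, want in expect.items():
        got = gene_semantic_similarity("x", "y", ann, dag, ic, agg)
        assert got == pytest.approx(want), agg


def test_cross_namespace_pairs_contribute_zero():
    dag = make_dag(
        [("A", "root"), ("B", "root")],
        namespaces={"A": "molecular_function", "B": "biological_process",
                    "root": "biological_process"},
    )
    ann = AnnotationMap(genes={"x": {"A"}, "y": {"B"}})
    ic = ICTable.from_annotations(dag, ann)
    assert gene_semantic_similarity("x", "y", ann, dag, ic) == 0.0


def test_symmetry_gene_level(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    for g1, g2 in itertools.combinations(sorted(go_bundle.ann.genes), 2):
        a = gene_semantic_similarity(g1, g2, go_bundle.ann, dag, ic)
        b = gene_semantic_similarity(g2, g1, go_bundle.ann, dag, ic)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0


def test_similarity_matrix_matches_pairwise(go_bundle):
    dag = go_bundle.dag
    ic = ICTable.from_annotations(dag, go_bundle.ann)
    genes = sorted(go_bundle.ann.genes) + ["unannotated_gene"]
    mat = semantic_similarity_matrix(genes, go_bundle.ann, dag, ic)
    for i, g1 in enumerate(genes):
        for j, g2 in enumerate(genes):
            want = gene_semantic_similarity(g1, g2, go_bundle.ann, dag, ic)
            if want is None:
                assert math.isnan(mat[i, j])
            else:
                assert mat[i, j] == pytest.approx(want)


# ---------------------------------------------------------------------------
# property: random small DAGs vs brute force
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None)
@given(st.data())
def test_share_bruteforce_on_random_dags(data):
    n_terms = data.draw(st.integers(3, 30))
    terms = [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = data.draw(st.integers(1, min(2, i)))
        parents = data.draw(
            st.lists(st.integers(0, i - 1), min_size=n_parents,
                     max_size=n_parents, unique=True)
        )
        edges.extend((terms[i], terms[p]) for p in parents)
    dag = make_dag(edges, terms=terms)
    n_genes = data.draw(st.integers(1, 8))
    genes = {
        f"g{k}": {terms[data.draw(st.integers(0, n_terms - 1))]}
        for k in range(n_genes)
    }
    ann = AnnotationMap(genes=genes)
    ic = ICTable.from_annotations(dag, ann)
    annotated = sorted({t for ts in genes.values() for t in ts})
    for c1 in annotated:
        for c2 in annotated:
            got = shared_information(c1, c2, dag, ic)
            assert got == pytest.approx(brute_share(dag, ic, c1, c2))
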