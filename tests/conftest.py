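import numpy as np
import pytest

import generank.svmrfe
from generank.io_core import ExpressionMatrix
from generank.synthetic_data import make_fixture


@pytest.fixture(autouse=True)
def verify_kkt_everywhere(monkeypatch):
    """Every SVM trained anywhere in the suite gets its dual identities checked."""
    monkeypatch.setattr(generank.svmrfe, "VERIFY_KKT", True)


@pytest.fixture(scope="session")
def go_bundle():
    return make_fixture("go_fixture")


@pytest.fixture(scope="session")
def tiny_bundle():
    return make_fixture("tiny_separable", seed=1)


@pytest.fixture(scope="session")
def dup_bundle():
    return make_fixture("duplicates_heavy", seed=3)


def small_matrix(values, labels, gene_prefix="g", class_names=None):
    """Build an ExpressionMatrix from a plain nested list + ±1 labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    kwargs = {}
    if class_names is not None:
        kwargs["class_names"] = class_names
    return ExpressionMatrix(
        gene_ids=[f"{gene_prefix}{i + 1}" for i in range(n_genes)],
        sample_ids=[f"s{j + 1}" for j in range(n_samples)],
        values=values,
        labels=np.asarray(labels, dtype=int),
        **kwargs,
    )
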