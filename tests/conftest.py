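import numpy as np
import pytest

from vcmnet import coexpr, modules, simulate


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic 4-stage study, shared across tests."""
    return simulate.simulate_expression(simulate.ExpressionSimConfig(seed=11))


def run_module_pipeline(matrix, beta=9.0, mode="one_minus_tom", **cut_kwargs):
    """Correlation -> power adjacency -> TOM -> dissimilarity -> tree cut."""
    corr = coexpr.pairwise_correlation(matrix)
    adj = coexpr.adjacency(corr, beta, matrix.gene_ids)
    sim = coexpr.topological_overlap(adj) if mode == "one_minus_tom" else adj
    d = coexpr.dissimilarity(sim, mode)
    dend = modules.hierarchical_cluster(d, gene_ids=matrix.gene_ids)
    return modules.tree_cut(dend, **cut_kwargs)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index by the standard pair-counting formula."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = comb2(a.size)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def planted_ari(study, assignment) -> float:
    """ARI between recovered and planted labels over the planted module genes."""
    truth = np.asarray(study.modules.labels)
    found = np.asarray(assignment.labels)
    mask = truth != modules.GREY
    return adjusted_rand_index(truth[mask], found[mask])
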