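"""Variance filter, sample distances, complete linkage vs a naive oracle."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

import seedarray as sa
from seedarray.clustering import distance_matrix, hierarchical_cluster


def _matrix(data, columns):
    return pd.DataFrame(data, columns=columns)


# ---------------------------------------------------------- variance filter

def test_variance_filter_identity_at_full_fraction(rng):
    m = _matrix(rng.normal(size=(10, 4)), list("abcd"))
    pd.testing.assert_frame_equal(sa.variance_filter(m, 1.0), m)


def test_variance_filter_sort_and_cut_oracle():
    m = pd.DataFrame(
        {
            "s1": [1.0, 1.0, 1.0, 1.0],
            "s2": [1.0, 2.0, 3.0, 4.0],
            "s3": [1.0, 3.0, 5.0, 7.0],
        },
        index=["g0", "g1", "g2", "g3"],
    )
    kept = sa.variance_filter(m, 0.5)
    assert list(kept.index) == ["g2", "g3"]  # the two highest-variance genes


def test_constant_gene_removed_first(rng):
    m = _matrix(rng.normal(size=(5, 4)), list("abcd"))
    m.iloc[2] = 3.14
    assert 2 not in sa.variance_filter(m, 0.8).index


def test_variance_filter_errors(rng):
    with pytest.raises(ValueError):
        sa.variance_filter(pd.DataFrame(), 0.5)
    with pytest.raises(ValueError):
        sa.variance_filter(_matrix(rng.normal(size=(3, 2)), list("ab")), 0.0)


# -------------------------------------------------------------- distances

def test_distance_identities(rng):
    x = rng.normal(size=20)
    assert sa.sample_distance(x, x, "pearson") == pytest.approx(0.0, abs=1e-12)
    assert sa.sample_distance(x, -x, "pearson") == pytest.approx(2.0)
    assert sa.sample_distance(x, 2 * x, "cosine") == pytest.approx(0.0, abs=1e-12)
    assert sa.sample_distance(x, x, "covariance", cov_offset=5.0) == pytest.approx(
        5.0 - np.var(x, ddof=1)
    )


def test_pearson_rejects_constant_profile():
    with pytest.raises(ValueError):
        sa.sample_distance(np.ones(5), np.arange(5.0), "pearson")
    with pytest.raises(ValueError):
        sa.sample_distance(np.arange(3.0), np.arange(4.0), "pearson")


# ------------------------------------------------------------- agglomeration

def test_closest_pair_merges_first():
    # 3 samples with pairwise pearson distances ~ (small, small, large)
    m = pd.DataFrame(
        {"a": [0.0, 1, 2, 3], "b": [0.1, 1, 2, 3.1], "c": [3.0, 1, -2, 0]}
    )
    dend = hierarchical_cluster(m, "pearson")
    left, right = dend.depth1_bipartition()
    assert {frozenset(left), frozenset(right)} == {
        frozenset({"a", "b"}),
        frozenset({"c"}),
    }


def _naive_complete_linkage_cophenetic(dm: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration oracle returning the cophenetic matrix."""
    n = dm.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dm[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    return coph


@pytest.mark.parametrize("metric", ["pearson", "covariance", "cosine"])
def test_dendrogram_matches_naive_agglomeration(metric, rng):
    m = _matrix(rng.normal(size=(30, 8)), [f"s{i}" for i in range(8)])
    dend = hierarchical_cluster(m, metric)
    dm = distance_matrix(m[sorted(m.columns)], metric)
    oracle = _naive_complete_linkage_cophenetic(dm.to_numpy())
    got = dend.cophenetic().loc[dm.index, dm.columns].to_numpy()
    np.testing.assert_allclose(got, oracle, atol=1e-10)


def test_cophenetic_dominates_pairwise(rng):
    m = _matrix(rng.normal(size=(25, 7)), [f"s{i}" for i in range(7)])
    dend = hierarchical_cluster(m, "pearson")
    dm = distance_matrix(m[sorted(m.columns)], "pearson")
    coph = dend.cophenetic().loc[dm.index, dm.columns]
    assert ((coph.to_numpy() - dm.to_numpy()) > -1e-10).all()


def test_dendrogram_invariant_to_column_order(rng):
    m = _matrix(rng.normal(size=(30, 6)), [f"s{i}" for i in range(6)])
    shuffled = m[list(np.array(m.columns)[rng.permutation(6)])]
    assert (
        hierarchical_cluster(m, "pearson").to_newick()
        == hierarchical_cluster(shuffled, "pearson").to_newick()
    )


def test_two_identical_samples_merge_at_zero(rng):
    x = rng.normal(size=15)
    m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=15)})
    dend = hierarchical_cluster(m, "pearson")
    assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_single_sample_is_an_error(rng):
    with pytest.raises(ValueError):
        hierarchical_cluster(_matrix(rng.normal(size=(5, 1)), ["a"]), "pearson")


def test_newick_output_parses_with_all_leaves(rng):
    m = _matrix(rng.normal(size=(20, 5)), [f"s{i}" for i in range(5)])
    tree = Phylo.read(StringIO(hierarchical_cluster(m, "pearson").to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(m.columns)


# --------------------------------------------------------------------- PCA

def test_pca_duplicated_sample_identical_scores(rng):
    x = rng.normal(size=(40, 3))
    m = pd.DataFrame(np.column_stack([x, x[:, 0]]), columns=["a", "b", "c", "a2"])
    scores = sa.principal_components(m)
    np.testing.assert_allclose(scores.loc["a"], scores.loc["a2"], atol=1e-10)


def test_pca_rank_one_matrix_loads_pc1(rng):
    g = rng.normal(size=30)
    m = pd.DataFrame({"a": g, "b": 2 * g, "c": -g})
    scores = sa.principal_components(m)
    assert np.allclose(scores["PC2"], 0.0, atol=1e-8)
    assert not np.allclose(scores["PC1"], 0.0)
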