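"""Fisher exact enrichment vs exhaustive hypergeometric enumeration."""

import numpy as np
import pytest
from scipy.stats import hypergeom

import seedarray as sa


def _hypergeom_two_sided(k, n, big_k, big_n) -> float:
    """Sum of hypergeometric probabilities of all tables at least as
    extreme (pmf <= observed, canonical 1+1e-7 relative slack)."""
    lo = max(0, n + big_k - big_n)
    hi = min(n, big_k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, big_n, big_k, n)
    obs = hypergeom.pmf(k, big_n, big_k, n)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


def test_fisher_p_matches_hypergeometric_oracle(rng):
    for _ in range(150):
        big_n = int(rng.integers(5, 200))
        big_k = int(rng.integers(0, big_n + 1))
        n = int(rng.integers(1, big_n + 1))
        k = int(rng.integers(max(0, n + big_k - big_n), min(n, big_k) + 1))
        _, p = sa.term_test(k, n, big_k, big_n)
        assert p == pytest.approx(_hypergeom_two_sided(k, n, big_k, big_n), abs=1e-12)


def test_term_test_study_scale_example():
    direction, p = sa.term_test(9, 302, 26, 11091)
    assert direction == "over"
    assert p < 1e-5


def test_equal_proportions_tie_to_over_with_p_one():
    direction, p = sa.term_test(5, 10, 10, 20)
    assert direction == "over"
    assert p == pytest.approx(1.0)


def test_absent_term_is_under():
    direction, p = sa.term_test(0, 50, 3, 10000)
    assert direction == "under"
    assert p > 0.9


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        sa.term_test(5, 4, 10, 100)
    with pytest.raises(ValueError):
        sa.term_test(2, 10, 1, 100)
    with pytest.raises(ValueError):
        sa.term_test(0, 90, 95, 100)


def test_direction_flips_between_list_and_complement(rng):
    for _ in range(50):
        big_n = int(rng.integers(10, 100))
        big_k = int(rng.integers(1, big_n))
        n = int(rng.integers(1, big_n))
        k = int(rng.integers(max(0, n + big_k - big_n), min(n, big_k) + 1))
        d1, p1 = sa.term_test(k, n, big_k, big_n)
        d2, p2 = sa.term_test(big_k - k, big_n - n, big_k, big_n)
        assert p1 == pytest.approx(p2, abs=1e-12)
        if k / n != big_k / big_n and (big_k - k) / (big_n - n) != big_k / big_n:
            assert {d1, d2} == {"over", "under"}


# --------------------------------------------------------------------- BH

def test_bh_known_values():
    assert sa.bh_adjust([0.2]) == [pytest.approx(0.2)]
    assert sa.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert sa.bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    assert sa.bh_adjust([]) == []


def test_bh_never_below_raw_and_order_invariant(rng):
    p = rng.uniform(size=25)
    adj = np.array(sa.bh_adjust(list(p)))
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    perm = rng.permutation(25)
    adj_perm = np.array(sa.bh_adjust(list(p[perm])))
    np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        sa.bh_adjust([0.5, 1.5])


# ----------------------------------------------------------------- report

def _world(rng, n_bg=600, n_list=60, enriched_frac_list=0.5, enriched_frac_bg=0.05):
    bg = [f"g{i}" for i in range(n_bg)]
    listed = bg[:n_list]
    gene_terms = {}
    for i, g in enumerate(bg):
        terms = {"GO:base"}
        in_list = i < n_list
        frac = enriched_frac_list if in_list else enriched_frac_bg
        if rng.uniform() < frac:
            terms.add("GO:planted")
        if rng.uniform() < 0.3:
            terms.add("GO:noise")
        gene_terms[g] = terms
    return listed, bg, gene_terms


def test_empty_list_gives_empty_report():
    rep = sa.enrichment_report([], ["a", "b"], {"a": {"t"}, "b": {"t"}})
    assert rep.empty


def test_planted_enrichment_detected(rng):
    listed, bg, gene_terms = _world(rng)
    rep = sa.enrichment_report(listed, bg, gene_terms)
    planted = rep[rep["term_id"] == "GO:planted"]
    assert len(planted) == 1
    assert planted.iloc[0]["direction"] == "over"
    assert planted.iloc[0]["p_adjusted"] < 0.05


def test_background_equal_to_list_has_no_signal(rng):
    listed, bg, gene_terms = _world(rng)
    rep = sa.enrichment_report(listed, listed, gene_terms)
    assert rep.empty


def test_list_must_be_subset_of_background():
    with pytest.raises(ValueError):
        sa.enrichment_report(["x"], ["a"], {"a": {"t"}})


def test_unannotated_genes_excluded_from_margins(rng):
    listed, bg, gene_terms = _world(rng)
    gene_terms = dict(gene_terms)
    for g in bg[100:150]:
        gene_terms[g] = set()
    rep = sa.enrichment_report(listed, bg, gene_terms, alpha=1.1)
    assert (rep["n_background_annotated"] == len(bg) - 50).all()
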