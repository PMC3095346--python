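"""Term over/under-representation in a gene list vs the present background.

For each annotation term a 2x2 table contrasts the gene list against the
rest of the annotated background (genes carrying at least one term);
significance is a two-sided Fisher exact test with Benjamini-Hochberg
correction across terms.  Direction is 'over' when the list fraction
exceeds the background fraction, 'under' otherwise (ties break to over).
The term table is taken as already propagated through any hierarchy.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def term_test(
    n_list_with_term: int,
    n_list: int,
    n_background_with_term: int,
    n_background: int,
) -> tuple[str, float]:
    """Two-sided Fisher exact P for one term; returns (direction, p_raw).

    The background includes the list; the 2x2 table contrasts list vs
    complement.
    """
    k, n, big_k, big_n = n_list_with_term, n_list, n_background_with_term, n_background
    if not (0 <= k <= min(n, big_k) and n <= big_n and big_k <= big_n):
        raise ValueError("inconsistent enrichment counts")
    if (big_k - k) > (big_n - n):
        raise ValueError("inconsistent enrichment counts")
    table = [[k, n - k], [big_k - k, (big_n - n) - (big_k - k)]]
    _, p = fisher_exact(table, alternative="two-sided")
    list_frac = k / n if n else 0.0
    bg_frac = big_k / big_n if big_n else 0.0
    direction = "over" if list_frac >= bg_frac else "under"
    return direction, float(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    if len(p_values) == 0:
        return []
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("P-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(p) for p in adj]


def enrichment_report(
    gene_list: Sequence[str],
    background: Sequence[str],
    gene_terms: Mapping[str, Set[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Terms enriched or depleted in ``gene_list`` at adjusted P < alpha.

    ``gene_terms`` maps gene -> set of term ids; genes without terms are
    excluded from both margins (only the annotated background counts).
    Rows are sorted by adjusted then raw P.
    """
    bg = set(background)
    listed = set(gene_list)
    if not listed <= bg:
        raise ValueError("gene list must be a subset of the background")

    annotated_bg = {g for g in bg if gene_terms.get(g)}
    annotated_list = listed & annotated_bg
    if not annotated_list:
        return _empty_report()

    terms: dict[str, tuple[int, int]] = {}
    term_bg: dict[str, int] = {}
    term_list: dict[str, int] = {}
    for g in annotated_bg:
        for t in gene_terms[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in annotated_list:
                term_list[t] = term_list.get(t, 0) + 1

    rows = []
    n_list, n_bg = len(annotated_list), len(annotated_bg)
    for t in sorted(term_bg):
        k = term_list.get(t, 0)
        direction, p = term_test(k, n_list, term_bg[t], n_bg)
        rows.append(
            {
                "term_id": t,
                "n_list_with_term": k,
                "n_list_annotated": n_list,
                "n_background_with_term": term_bg[t],
                "n_background_annotated": n_bg,
                "direction": direction,
                "p_raw": p,
            }
        )
    report = pd.DataFrame(rows)
    report["p_adjusted"] = bh_adjust(report["p_raw"].tolist())
    report = report[report["p_adjusted"] < alpha]
    return report.sort_values(
        ["p_adjusted", "p_raw", "term_id"], ignore_index=True
    )


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term_id",
            "n_list_with_term",
            "n_list_annotated",
            "n_background_with_term",
            "n_background_annotated",
            "direction",
            "p_raw",
            "p_adjusted",
        ]
    )
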