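"""Pfaffl relative expression and microarray-vs-qPCR concordance.

Computes efficiency-corrected expression ratios for a few reactions,
calls them with the +/-0.6 log2 rule, and scores agreement with
microarray calls the way the study's validation table does.
"""

import seedarray as sa
from seedarray.qpcr import mean_ratio, reaction_ratio

reactions = [
    sa.QpcrReaction("At1g65330", "2xX4x", 1.9, 2.0, 2.0, 1.0),   # PHE1-like, up
    sa.QpcrReaction("At1g65330", "2xX4x", 1.9, 2.0, 2.2, 1.1),
    sa.QpcrReaction("At4g25530", "4xX2x", 2.0, 2.0, -1.5, 0.0),  # FWA-like, down
    sa.QpcrReaction("At5g10440", "6xX2x", 2.0, 2.0, 0.2, 0.1),   # unchanged
]

print("Pfaffl ratios (E_t^dCT_t / E_r^dCT_r):")
qpcr_calls = {}
for key in {(r.cross_label, r.gene_id) for r in reactions}:
    ratios = [
        reaction_ratio(r)
        for r in reactions
        if (r.cross_label, r.gene_id) == key
    ]
    m = mean_ratio(ratios)
    qpcr_calls[key] = sa.qpcr_call(m)
    print(f"  {key[1]} in {key[0]}: mean ratio {m:.3f} -> {qpcr_calls[key]}")

microarray = {
    ("affymetrix", "2xX4x", "At1g65330"): "up",
    ("affymetrix", "4xX2x", "At4g25530"): "down",
    ("affymetrix", "6xX2x", "At5g10440"): "up",  # one deliberate disagreement
}
genes = sorted({g for _, _, g in microarray})
cells = sorted({(p, c) for p, c, _ in microarray})
table, overall = sa.concordance(microarray, qpcr_calls, genes, cells)
print("\nPer-cell agreement:")
print(table.to_string(index=False))
print(
    f"\nOverall: {overall['n_agree']}/{overall['n_tested']} calls agree "
    f"({overall['percent']}%). A call agrees when microarray and qPCR both"
    "\nsay up, down, or unchanged for the same gene, cross and platform."
)
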