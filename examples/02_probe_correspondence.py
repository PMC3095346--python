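"""Pair Affymetrix-style probe sets with 60-mer probes via transcripts.

Builds a miniature probe/transcript world, applies the 9-of-11 PM rule
and the Q >= 5/6 ungapped-identity rule, and collapses pairs to one
probe pair per gene.
"""

import random

import seedarray as sa

rng = random.Random(5)
transcripts, probe_sets, long_probes = {}, [], []
for i in range(8):
    gene = f"At1g{(i + 1) * 10:05d}"
    seq = "".join(rng.choice("ACGT") for _ in range(250))
    transcripts[gene] = seq
    offsets = rng.sample(range(226), 11)
    probe_sets.append(
        sa.ProbeSetRecord(f"ps{i:03d}_at", [seq[o : o + 25] for o in offsets], seq)
    )
    start = rng.randrange(190)
    long_probes.append(sa.LongProbeRecord(f"crs{i:03d}", seq[start : start + 60]))

pairs = sa.build_correspondence(probe_sets, long_probes, transcripts)
gene_map = sa.collapse_to_genes(pairs)

print(f"{len(pairs)} correspondence pairs from {len(transcripts)} transcripts:")
for p in pairs:
    print(f"  {p.probe_set_id} <-> {p.probe_id}  gene={p.at_id}  Q={p.q:.3f} ({p.strand})")
print(f"\nCollapsed to {len(gene_map)} unique genes (one probe pair each).")
print(
    "A pair means the probe set (>= 9 of 11 exact PM 25-mer hits) and the"
    "\n60-mer (>= 50/60 matching positions, best sense match per transcript)"
    "\nreport on the same transcript, so their platform measurements are"
    "\ncomparable gene by gene."
)
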