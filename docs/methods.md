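# Methods

This note records the models, numerical choices and open design
decisions behind `seedarray`, in the spirit of a methods appendix.

## Study design encoded in `designs`

Seven 'crosses' are profiled against the balanced 2xX2x control:
interploidy crosses 2xX4x, 2xX6x (paternal excess), 4xX2x, 6xX2x
(maternal excess), fertilized *fis1*X2x, and unfertilized (autonomous)
*msi1*. Endosperm maternal:paternal genome counts are 2:1 (balanced and
fis1X2x), 2:2, 2:3, 4:1, 6:1 and 2:0 (msi1). All sexual crosses have
two biological replicates; msi1 has one. Affymetrix covers all six
experimental crosses; Agilent covers the five sexual ones. Each
Affymetrix experimental replicate is compared to both control
replicates, giving four (SLR, change-P) comparisons per probe set per
two-replicate cross and two for msi1.

## pSLR weighting

The change P-value follows the MAS5 convention: near 0 means confident
increase, near 1 confident decrease, 0.5 no evidence. We fold it to
p\* = 2·min(P, 1−P) and weight the SLR by the logistic
w(p\*) = 1/(1 + exp((2p\* − 1)/0.01)). The weight is within 1e-40 of 1
for p\* < 0.49 and below 1e-40 at p\* = 1, so confident SLRs pass
through essentially unchanged (deviation < 1e-6 at P = 1e-9 from either
tail) while no-evidence SLRs vanish (|pSLR| < 1e-10 at P = 0.5). The
sharpness constant 0.01 places the transition in a narrow band around
p\* = 0.5; pSLR is sign-preserving, never exceeds |SLR|, and is
monotone non-increasing in p\* for positive SLR. The published formula
for this weighting is typographically garbled (unbalanced parentheses);
the form above is the unique reconstruction satisfying every behavioural
statement made about it, and those statements are what the test suite
asserts.

## Agilent ratios and the presence rule

Per array, expression is log2(s′/s) with s′ the experimental channel
and s the control channel regardless of dye; averaging the two
swapped-dye arrays cancels any additive per-probe dye bias exactly. A
gene's probe pair is 'present' iff (a) some cross has Cy3+Cy5 strictly
above 50 on both arrays of its dye swap and (b) some Affymetrix array
has detection P ≤ 0.06 — the complement of 'absent (P > 0.06) on every
array'. Non-positive two-dye signals raise rather than being floored:
the generator never produces them, and silent flooring would hide
corrupt real data (the CLI layer is the place to add a floor-at-1
option if needed). Whether the > 50 rule should apply before or after
any between-array normalization is not specified for the original data;
it is applied to raw simulated signals here.

## Calls, consensus, contrast algebra

Thresholds are inclusive: up at value ≥ 0.6 (≈ 50% expression change),
down at ≤ −0.6, not_up at ≤ 0.3 (≈ 20%), not_down at ≥ −0.3; a value in
[−0.3, 0.3] is both not_up and not_down. The not_down cutoff is read as
≥ −0.3, the mirror of the explicitly inclusive not_up rule. Consensus
up/down requires both platforms; consensus not_up/not_down requires
both values at or below 0.3 (at or above −0.3). msi1, lacking Agilent
data, is called on its single platform for both calls and flags, and
its Agilent/overlap count cells are reported as missing. Contrast sets
are conjunctions over consensus calls and flags; seven built-in recipes
cover the seed-class lists (large-seed: up in paternal-excess crosses
and not up in maternal excess, or down in maternal excess and not down
in paternal excess; small-seed mirrored; FIS-up: up in both FIS-class
mutants), plus the two headline two-cross recipes. Agreement between
two gene sets is 100·overlap/min(|A|,|B|) — the smaller set is the
maximum possible agreement — half-up rounded to one decimal (integer
for annotation fractions where the convention is integer percent).

## Probe correspondence

The matcher replaces genome-scale gapped alignment (BLAT fastMap) with
exact 25-mer lookup for PM probes and exact-k-mer seeding (k = 12)
plus full ungapped scanning of candidate transcripts for 60-mers, both
strands. The Q = matches/60 threshold is read as ≥ 5/6 (exactly 50
matching positions accepted): a pure-equality reading would discard
perfect matches, contradicting best-match retention. PM probes match
sense-strand only, as they are designed sense to the transcript.
Fidelity limits, stated plainly: seeded mode can miss a passing
alignment whose ≥ 10 mismatches break every exact 12-mer
(`exhaustive=True` scans everything and is what the oracle-equivalence
tests certify); there is no gapped or intron-aware alignment. Per
transcript only the best sense 60-mer is retained before pairing;
direct probe-to-target matches are added unfiltered ('correspond to
each other'). The gene key of a direct-only pair is the smallest
transcript its probe set matched, else the probe-set id itself. The
collapse to one probe pair per gene — needed because pairs can outnumber
genes — uses a deterministic tie rule (highest Q, then largest mean
two-dye signal when available, then lexicographic ids); the original
analysis does not state its rule, so this is an artifact decision made
for reproducibility, not an inference about the original intent.

## Clustering

Profiles are one column per cross per platform (11 columns in the full
design, msi1 contributing Affymetrix only); genes missing any retained
column are dropped, then the ⌈0.5·n⌉ highest-variance genes are kept.
Distances: Pearson 1−r, cosine 1−cos, and covariance rescaled as
max_pairwise_cov − cov(x,y) — raw covariance is a similarity and the
original tool's exact covariance-distance formula is undocumented, so
this standard rescaling is a flagged reconstruction. Agglomeration is
complete linkage via scipy; columns are sorted lexicographically
beforehand, which makes the dendrogram independent of input column
order (with continuous data, exact distance ties have measure zero
under the generator, so no further tie rule is needed). Newick export
uses merge-height differences as branch lengths. PCA is SVD on
gene-centred samples (covariance PCA), with each component's sign fixed
by its largest-magnitude score. KNN imputation is unnecessary for the
simulator's complete matrices and is not implemented; incomplete rows
are dropped instead.

## Enrichment

Each term is tested with a two-sided Fisher exact test on list vs
complement within the annotated background (genes carrying ≥ 1 term;
unannotated genes leave both margins). Direction compares list and
background fractions, ties to 'over'. BH step-up correction runs across
all tested terms; the report keeps rows with adjusted P below the 0.05
default. Fisher is used at every table size for determinism even where
a chi-square approximation would be customary; term-hierarchy
propagation is assumed done upstream.

## qRT-PCR

Pfaffl ratios E_t^ΔCTt / E_r^ΔCTr with ΔCT = control − experimental
threshold cycle; replicate reactions are averaged on the ratio scale
before calling. The qPCR call threshold is not dictated by the
validation design, so the microarray ±0.6 log2 rule is mirrored by
default and exposed as a parameter. Concordance counts a call as
agreeing when microarray and qPCR both say up, down or unchanged for
the same gene/cross/platform; missing calls count as not tested.

## Synthetic data: what it emulates and what it does not

`generate_truth` plants exact class counts (round(fraction·n), assigned
along a seeded shuffle, so tests are deterministic): 5% large-seed, 5%
small-seed, 2% FIS-up, 5% low-expression by default on 2,000 genes.
Class genes draw a base effect uniform in [0.8, 2.0] log2 units with
±5% per-cross jitter — correlated across a class's associated crosses,
comfortably above the 0.6 threshold — and sit within ±0.15 elsewhere;
background genes stay within ±0.15 everywhere. Each large-seed or
small-seed gene is deterministically alternated between an
up-in-associated-crosses and a down-in-opposite-crosses variant so that
all seven contrast recipes, including the down-direction ones, have
non-empty planted truth. Affymetrix SLR noise and Agilent log-ratio
noise are i.i.d. Gaussian, SD 0.15 log2 units (a typical replicate SD
for processed array log-ratios); change P-values are 0.5 for unchanged
genes and uniform in [0, 0.001] / [0.999, 1] for true increases /
decreases, following the MAS5 tail convention. Two-dye baselines are
log-normal around a median of 500 (log-SD 0.5, floored at 30 so real
signal always clears the sum-50 rule); per-gene dye bias (SD 0.1) flips
sign with orientation. Low-expression genes get 5–25 units per channel
and detection P in (0.06, 1] on every array, so they fail both presence
conditions by construction.

Not emulated: probe-level intensity data and the MAS5 algorithm itself
(its outputs are this pipeline's inputs), between-array normalization
artifacts, correlated or intensity-dependent noise, cross-hybridization
between paralogues, partial platform disagreement, and genome-scale
transcript complexity (one transcript and probe pair per gene unless
`multi_probe_fraction` adds degraded duplicates). Passing tests
therefore certify the algebra and statistics of the pipeline under its
stated assumptions, not robustness to the full messiness of real array
data; the published genome-scale counts (20,442 pairs, 14,944 present
AtIds, per-cross call totals) require the original arrays and are
deliberately out of reach.

## Problem sizes and determinism

Default test and acceptance runs use 2,000 genes for end-to-end
identity, 300–1,000 genes for unit-level fixtures, ten seeds for the
stochastic recovery checks, and ≤ 50 transcripts / ≤ 200-margin tables
/ 8 samples for the brute-force oracle comparisons — sizes chosen so
the planted structure is well-resolved while the whole suite stays
quick. Every random draw flows from a single configured seed through
per-stage `numpy` generator streams, so identical configurations give
byte-identical outputs, including written tables (floats serialized at
%.17g and parsed with round-trip precision).
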