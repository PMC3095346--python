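"""Cross-platform probe correspondence.

Pairs Affymetrix probe sets (11 perfect-match 25-mers plus a target
sequence) with Agilent/Ceres 60-mer probes through shared transcripts:

* a probe set matches a transcript when at least 9 of its 11 PM probes
  occur as exact sense-strand substrings of the transcript;
* a 60-mer matches when its best ungapped placement (either strand) has
  identity Q = matches/60 >= 5/6, and per transcript only the best
  sense-strand 60-mer is retained;
* a probe set and a 60-mer correspond if they match the same transcript,
  or if the 60-mer matches the probe set's target sequence directly.

The internal matcher is exact-k-mer seeding plus ungapped full scan on
candidate transcripts; it stands in for gapped genome-scale alignment
(BLAT) and inherits an honest sensitivity limit: seeded mode can miss a
passing alignment whose mismatches break every exact seed.  Pass
``exhaustive=True`` to scan every transcript at every offset.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

PM_PROBE_LENGTH = 25
LONG_PROBE_LENGTH = 60
#: Minimum PM probes that must match a transcript exactly (9 of 11).
MIN_PM_MATCHES = 9
#: Minimum ungapped identity for a 60-mer match (>= 50 of 60 positions).
MIN_Q = 5.0 / 6.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeSetRecord:
    """An Affymetrix-style probe set: PM probes plus its target sequence."""

    probe_set_id: str
    pm_probes: list[str]
    target_sequence: str

    def __post_init__(self) -> None:
        self.pm_probes = [p.upper() for p in self.pm_probes]
        self.target_sequence = self.target_sequence.upper()
        for p in self.pm_probes:
            if len(p) != PM_PROBE_LENGTH:
                raise ValueError(
                    f"{self.probe_set_id}: PM probe length {len(p)} != {PM_PROBE_LENGTH}"
                )


@dataclass
class LongProbeRecord:
    """A 60-mer oligonucleotide probe."""

    probe_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != LONG_PROBE_LENGTH:
            raise ValueError(
                f"{self.probe_id}: probe length {len(self.sequence)} != {LONG_PROBE_LENGTH}"
            )


@dataclass(frozen=True)
class AlignmentResult:
    probe_id: str
    transcript_id: str
    matches: int
    strand: str  # "sense" | "antisense"

    @property
    def q(self) -> float:
        """Ungapped identity, matches/60."""
        return self.matches / LONG_PROBE_LENGTH


@dataclass(frozen=True)
class CorrespondencePair:
    """A (probe set, 60-mer) pair keyed to a gene identifier."""

    probe_set_id: str
    probe_id: str
    at_id: str
    q: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)


def match_probe_set_to_transcript(
    ps: ProbeSetRecord, transcript: str, min_matches: int = MIN_PM_MATCHES
) -> bool:
    """True when >= ``min_matches`` PM probes are exact sense substrings.

    PM probes are designed sense to the transcript, so reverse-complement
    occurrences do not count.
    """
    if not ps.pm_probes:
        raise ValueError(f"{ps.probe_set_id}: probe set has no PM probes")
    if not transcript:
        raise ValueError("empty transcript")
    transcript = transcript.upper()
    hits = sum(1 for p in ps.pm_probes if p in transcript)
    return hits >= min_matches


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_ungapped(probe: str, transcript: str) -> tuple[int, str] | None:
    """Best full-length ungapped placement of ``probe`` on either strand.

    Returns (matches, strand); sense wins ties. None if the transcript is
    shorter than the probe.
    """
    n = len(probe)
    t = _seq_to_array(transcript)
    if t.size < n:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(t, n)
    best = None
    for strand, p in (("sense", probe), ("antisense", reverse_complement(probe))):
        scores = (windows == _seq_to_array(p)).sum(axis=1)
        m = int(scores.max())
        if best is None or m > best[0]:
            best = (m, strand)
    return best


def align_long_probe(
    probe: LongProbeRecord,
    transcript: str,
    transcript_id: str = "",
    min_q: float = MIN_Q,
) -> AlignmentResult | None:
    """Align a 60-mer to one transcript; ``None`` below the Q threshold.

    The Q >= 5/6 rule is read inclusively: exactly 50 matching positions
    (Q = 0.8333...) is accepted.
    """
    if not transcript:
        raise ValueError("empty transcript")
    best = _best_ungapped(probe.sequence, transcript.upper())
    if best is None:
        return None
    matches, strand = best
    # guard against float round-off at exact equality
    if matches + 1e-9 < min_q * LONG_PROBE_LENGTH:
        return None
    return AlignmentResult(probe.probe_id, transcript_id, matches, strand)


def _kmer_index(seqs: Mapping[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for sid, seq in seqs.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(sid)
    return index


def _candidate_ids(probe_seq: str, index: dict[str, set[str]], k: int) -> set[str]:
    cands: set[str] = set()
    for s in (probe_seq, reverse_complement(probe_seq)):
        for i in range(len(s) - k + 1):
            hit = index.get(s[i : i + k])
            if hit:
                cands |= hit
    return cands


def build_correspondence(
    probe_sets: Sequence[ProbeSetRecord],
    long_probes: Sequence[LongProbeRecord],
    transcripts: Mapping[str, str],
    *,
    seed_k: int = 12,
    exhaustive: bool = False,
) -> list[CorrespondencePair]:
    """Pair probe sets with 60-mers via shared transcripts or directly.

    Per transcript only the best sense-strand 60-mer match is retained
    before pairing; direct probe-to-target matches are added unfiltered.
    The output is deduplicated on (probe_set_id, probe_id) and sorted, so
    it is independent of input ordering.
    """
    ps_ids = [ps.probe_set_id for ps in probe_sets]
    if len(set(ps_ids)) != len(ps_ids):
        raise ValueError("duplicate probe_set_id in input")
    lp_ids = [lp.probe_id for lp in long_probes]
    if len(set(lp_ids)) != len(lp_ids):
        raise ValueError("duplicate probe_id in input")

    transcripts = {tid: seq.upper() for tid, seq in transcripts.items()}

    # -- probe set -> transcript matches via an exact 25-mer lookup
    pm_index = _kmer_index(transcripts, PM_PROBE_LENGTH)
    ps_matches: dict[str, set[str]] = {}  # probe_set_id -> transcript ids
    for ps in probe_sets:
        if not ps.pm_probes:
            raise ValueError(f"{ps.probe_set_id}: probe set has no PM probes")
        counts: dict[str, int] = defaultdict(int)
        for p in ps.pm_probes:
            for tid in pm_index.get(p, ()):
                counts[tid] += 1
        ps_matches[ps.probe_set_id] = {t for t, c in counts.items() if c >= MIN_PM_MATCHES}

    # -- 60-mer -> transcript alignments, best sense match kept per transcript
    t_index = None if exhaustive else _kmer_index(transcripts, seed_k)
    best_sense: dict[str, AlignmentResult] = {}  # transcript -> retained probe
    for lp in long_probes:
        if exhaustive:
            cand = set(transcripts)
        else:
            cand = _candidate_ids(lp.sequence, t_index, seed_k)
        for tid in cand:
            aln = align_long_probe(lp, transcripts[tid], tid)
            if aln is None or aln.strand != "sense":
                continue
            cur = best_sense.get(tid)
            if (
                cur is None
                or aln.matches > cur.matches
                or (aln.matches == cur.matches and aln.probe_id < cur.probe_id)
            ):
                best_sense[tid] = aln

    pairs: dict[tuple[str, str], CorrespondencePair] = {}

    # transcript-mediated pairs
    for ps in probe_sets:
        for tid in sorted(ps_matches[ps.probe_set_id]):
            aln = best_sense.get(tid)
            if aln is None:
                continue
            key = (ps.probe_set_id, aln.probe_id)
            if key not in pairs:
                pairs[key] = CorrespondencePair(
                    ps.probe_set_id, aln.probe_id, tid, aln.q, aln.strand
                )

    # direct probe-to-target pairs ("... or each other")
    targets = {ps.probe_set_id: ps.target_sequence for ps in probe_sets}
    tgt_index = None if exhaustive else _kmer_index(targets, seed_k)
    for lp in long_probes:
        if exhaustive:
            cand = set(targets)
        else:
            cand = _candidate_ids(lp.sequence, tgt_index, seed_k)
        for psid in cand:
            aln = align_long_probe(lp, targets[psid], psid)
            if aln is None:
                continue
            key = (psid, lp.probe_id)
            if key in pairs:
                continue
            # gene key: the transcript this probe set matched, else the
            # probe set id itself (no transcript evidence exists)
            matched = ps_matches[psid]
            at_id = min(matched) if matched else psid
            pairs[key] = CorrespondencePair(psid, lp.probe_id, at_id, aln.q, aln.strand)

    return sorted(pairs.values(), key=lambda p: (p.probe_set_id, p.probe_id))


def collapse_to_genes(
    pairs: Iterable[CorrespondencePair],
    mean_signal: Mapping[str, float] | None = None,
) -> dict[str, tuple[str, str]]:
    """One (probe set, probe) pair per gene.

    Several pairs can share an at_id (e.g. probe sets with overlapping
    targets); a deterministic tie rule picks one: highest alignment Q,
    then largest mean two-dye signal of the 60-mer when supplied, then
    lexicographically smallest probe_set_id, then probe_id.
    """
    best: dict[str, tuple] = {}
    for p in pairs:
        q = p.q if p.q is not None else float("-inf")
        sig = mean_signal.get(p.probe_id, float("-inf")) if mean_signal else float("-inf")
        key = (-q, -sig, p.probe_set_id, p.probe_id)
        if p.at_id not in best or key < best[p.at_id][0]:
            best[p.at_id] = (key, (p.probe_set_id, p.probe_id))
    return {at_id: pair for at_id, (_, pair) in sorted(best.items())}
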