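"""Probe-correspondence rule layer vs a brute-force substring oracle."""

import random

import pytest

import seedarray as sa
from seedarray.correspondence import MIN_PM_MATCHES, reverse_complement


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(seq: str, positions, rng: random.Random) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


# ---------------------------------------------------------------- PM rule

@pytest.fixture(scope="module")
def transcript():
    return _random_seq(random.Random(1), 300)


def _probe_set_from(transcript, n_bad, rng):
    offsets = rng.sample(range(len(transcript) - 25 + 1), 11)
    pms = [transcript[o : o + 25] for o in offsets]
    for i in range(n_bad):
        pms[i] = _random_seq(rng, 25)  # vanishing chance of an exact hit
    return sa.ProbeSetRecord(f"ps_bad{n_bad}", pms, transcript)


@pytest.mark.parametrize("n_bad,expected", [(0, True), (2, True), (3, False)])
def test_pm_match_threshold_9_of_11(transcript, n_bad, expected):
    ps = _probe_set_from(transcript, n_bad, random.Random(42))
    assert sa.match_probe_set_to_transcript(ps, transcript) is expected


def test_pm_probes_are_sense_only(transcript):
    ps = _probe_set_from(transcript, 0, random.Random(7))
    assert not sa.match_probe_set_to_transcript(ps, reverse_complement(transcript))


def test_empty_probe_set_is_an_error(transcript):
    ps = sa.ProbeSetRecord("empty", [], transcript)
    with pytest.raises(ValueError):
        sa.match_probe_set_to_transcript(ps, transcript)


# ---------------------------------------------------------- 60-mer alignment

@pytest.mark.parametrize("n_mismatch,accepted", [(0, True), (10, True), (11, False)])
def test_q_threshold_inclusive_at_5_6(transcript, n_mismatch, accepted):
    rng = random.Random(n_mismatch)
    probe_seq = _mutate(
        transcript[40:100], rng.sample(range(60), n_mismatch), rng
    )
    aln = sa.align_long_probe(sa.LongProbeRecord("p1", probe_seq), transcript, "t")
    if accepted:
        assert aln is not None and aln.matches == 60 - n_mismatch
        assert aln.q >= 5 / 6 - 1e-12
    else:
        assert aln is None


def test_perfect_matches_record_strand(transcript):
    sense = sa.align_long_probe(
        sa.LongProbeRecord("p", transcript[10:70]), transcript, "t"
    )
    anti = sa.align_long_probe(
        sa.LongProbeRecord("p", reverse_complement(transcript[10:70])), transcript, "t"
    )
    assert sense.q == 1.0 and sense.strand == "sense"
    assert anti.q == 1.0 and anti.strand == "antisense"


def test_acceptance_upward_closed_in_matches(transcript):
    rng = random.Random(99)
    accepted = []
    for n_mm in range(0, 14):
        probe_seq = _mutate(transcript[100:160], list(range(n_mm)), rng)
        aln = sa.align_long_probe(sa.LongProbeRecord("p", probe_seq), transcript, "t")
        accepted.append(aln is not None)
    # once rejected, higher mismatch counts never flip back to accepted
    assert accepted == sorted(accepted, reverse=True)


# ------------------------------------------------------- brute-force oracle

def _oracle_best(probe_seq: str, seq: str):
    best = None
    for strand, p in (("sense", probe_seq), ("antisense", reverse_complement(probe_seq))):
        for off in range(len(seq) - 60 + 1):
            m = sum(a == b for a, b in zip(p, seq[off : off + 60]))
            if best is None or m > best[0]:
                best = (m, strand)
    return best


def _oracle_pairs(probe_sets, long_probes, transcripts):
    ps_match = {
        ps.probe_set_id: {
            t
            for t, seq in transcripts.items()
            if sum(pm in seq for pm in ps.pm_probes) >= MIN_PM_MATCHES
        }
        for ps in probe_sets
    }
    best_sense = {}
    for t, seq in transcripts.items():
        hits = []
        for lp in long_probes:
            res = _oracle_best(lp.sequence, seq)
            if res and res[0] >= 50 and res[1] == "sense":
                hits.append((-res[0], lp.probe_id))
        if hits:
            best_sense[t] = min(hits)[1]
    pairs = set()
    for ps in probe_sets:
        for t in ps_match[ps.probe_set_id]:
            if t in best_sense:
                pairs.add((ps.probe_set_id, best_sense[t], t))
    for lp in long_probes:
        for ps in probe_sets:
            res = _oracle_best(lp.sequence, ps.target_sequence)
            if res and res[0] >= 50:
                if any(pr[0] == ps.probe_set_id and pr[1] == lp.probe_id for pr in pairs):
                    continue
                matched = ps_match[ps.probe_set_id]
                at_id = min(matched) if matched else ps.probe_set_id
                pairs.add((ps.probe_set_id, lp.probe_id, at_id))
    return pairs


@pytest.fixture(scope="module")
def small_world():
    """~25 transcripts with exact, degraded, orphan and target-only probes."""
    rng = random.Random(12345)
    transcripts, probe_sets, long_probes = {}, [], []
    for i in range(25):
        t = f"At1g{i:05d}"
        seq = _random_seq(rng, rng.randint(150, 250))
        transcripts[t] = seq
        offs = rng.sample(range(len(seq) - 25 + 1), 11)
        probe_sets.append(sa.ProbeSetRecord(f"ps{i:03d}_at", [seq[o : o + 25] for o in offs], seq))
        o = rng.randint(0, len(seq) - 60)
        long_probes.append(sa.LongProbeRecord(f"crs{i:03d}", seq[o : o + 60]))
        if i % 5 == 0:  # competing degraded probe on the same transcript
            long_probes.append(
                sa.LongProbeRecord(f"crs{i:03d}x", _mutate(seq[o : o + 60], range(5), rng))
            )
    # a probe matching nothing at all
    long_probes.append(sa.LongProbeRecord("orphan", _random_seq(rng, 60)))
    # a probe set whose target is not any transcript, plus its direct probe
    novel = _random_seq(rng, 200)
    probe_sets.append(
        sa.ProbeSetRecord(
            "ps_direct_at",
            [novel[o : o + 25] for o in rng.sample(range(176), 11)],
            novel,
        )
    )
    long_probes.append(sa.LongProbeRecord("crs_direct", novel[50:110]))
    return transcripts, probe_sets, long_probes


def test_build_correspondence_matches_brute_force(small_world):
    transcripts, probe_sets, long_probes = small_world
    got = sa.build_correspondence(probe_sets, long_probes, transcripts, exhaustive=True)
    assert {(p.probe_set_id, p.probe_id, p.at_id) for p in got} == _oracle_pairs(
        probe_sets, long_probes, transcripts
    )


def test_seeded_matcher_agrees_with_exhaustive(small_world):
    transcripts, probe_sets, long_probes = small_world
    fast = sa.build_correspondence(probe_sets, long_probes, transcripts)
    slow = sa.build_correspondence(probe_sets, long_probes, transcripts, exhaustive=True)
    assert fast == slow


def test_output_independent_of_input_order(small_world):
    transcripts, probe_sets, long_probes = small_world
    base = sa.build_correspondence(probe_sets, long_probes, transcripts)
    rng = random.Random(0)
    ps2, lp2 = probe_sets[:], long_probes[:]
    rng.shuffle(ps2)
    rng.shuffle(lp2)
    items = list(transcripts.items())
    rng.shuffle(items)
    assert sa.build_correspondence(ps2, lp2, dict(items)) == base


def test_best_sense_match_retained():
    """Of two probes hitting one transcript (Q=1.0 vs Q=55/60) only the
    best sense match is paired through it."""
    rng = random.Random(8)
    seq = _random_seq(rng, 240)
    transcripts = {"G": seq}
    # target deliberately unrelated so no direct probe-to-target route exists
    ps = sa.ProbeSetRecord(
        "psG_at", [seq[o : o + 25] for o in rng.sample(range(216), 11)], _random_seq(rng, 200)
    )
    exact = sa.LongProbeRecord("crsA", seq[30:90])
    degraded = sa.LongProbeRecord("crsB", _mutate(seq[30:90], range(5), rng))
    pairs = sa.build_correspondence([ps], [exact, degraded], transcripts)
    assert [(p.probe_id, p.at_id) for p in pairs] == [("crsA", "G")]


def test_target_only_probe_still_paired(small_world):
    transcripts, probe_sets, long_probes = small_world
    pairs = sa.build_correspondence(probe_sets, long_probes, transcripts)
    direct = [p for p in pairs if p.probe_set_id == "ps_direct_at"]
    assert [(p.probe_id, p.at_id) for p in direct] == [("crs_direct", "ps_direct_at")]


def test_duplicate_ids_rejected(small_world):
    transcripts, probe_sets, long_probes = small_world
    with pytest.raises(ValueError):
        sa.build_correspondence(probe_sets + [probe_sets[0]], long_probes, transcripts)
    with pytest.raises(ValueError):
        sa.build_correspondence(probe_sets, long_probes + [long_probes[0]], transcripts)


# ------------------------------------------------------------ gene collapse

def test_collapse_identity_and_empty():
    pair = sa.CorrespondencePair("psA", "crsA", "At1g00010", 1.0, "sense")
    assert sa.collapse_to_genes([pair]) == {"At1g00010": ("psA", "crsA")}
    assert sa.collapse_to_genes([]) == {}


def test_collapse_tie_rules():
    g = "At1g00010"
    hi_q = sa.CorrespondencePair("psB", "crsB", g, 1.0, "sense")
    lo_q = sa.CorrespondencePair("psA", "crsA", g, 0.9, "sense")
    assert sa.collapse_to_genes([lo_q, hi_q])[g] == ("psB", "crsB")

    tie_a = sa.CorrespondencePair("psB", "crsB", g, 1.0, "sense")
    tie_b = sa.CorrespondencePair("psA", "crsA", g, 1.0, "sense")
    # equal Q: larger mean signal wins
    assert sa.collapse_to_genes([tie_a, tie_b], mean_signal={"crsB": 900, "crsA": 100})[
        g
    ] == ("psB", "crsB")
    # equal Q, no signal: lexicographically smallest probe_set_id
    assert sa.collapse_to_genes([tie_a, tie_b])[g] == ("psA", "crsA")
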