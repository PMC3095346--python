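"""Seeded two-platform silique transcriptome simulator with planted truth.

Emulates the study design end to end: per-comparison Affymetrix
(SLR, change P) statistics against both balanced-control replicates,
Agilent dye-swap two-dye signals, per-array detection P-values, and the
probe/transcript sequences needed by the correspondence stage.

Planted gene classes mirror the phenotype-associated contrast structure:

* ``large_seed`` genes are associated with endosperm overproliferation —
  up in the paternalized crosses (2xX4x, 2xX6x, fis1X2x) or down in the
  maternalized crosses (4xX2x, 6xX2x, msi1), near zero elsewhere;
* ``small_seed`` genes are the mirror image;
* ``fis_up`` genes are up in both FIS-class mutants (fis1X2x and msi1);
* ``background`` genes sit near zero everywhere.

Every draw flows from ``SimulationConfig.seed``; identical configs give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .correspondence import LongProbeRecord, ProbeSetRecord
from .designs import (
    AFFY_CROSSES,
    AGILENT_CROSSES,
    CONTROL_CROSS,
    DEFAULT_DESIGNS,
    MATERNALIZED,
    PATERNALIZED,
    CrossDesign,
    expected_comparisons,
)

GENE_CLASSES = ("large_seed", "small_seed", "fis_up", "background")

#: dye orientation labels: which channel carries the experimental sample
EXP_CY5 = "exp_cy5"
EXP_CY3 = "exp_cy3"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions emulated.

    Noise SDs are in log2 units (0.15 is a typical replicate SD for
    processed array log-ratios); two-dye baselines are log-normal around a
    median of 500 fluorescence units, and 'low expression' genes receive
    per-channel signals <= 25 so the Cy3+Cy5 > 50 presence rule excludes
    them on every array.
    """

    n_genes: int = 2000
    frac_large_seed: float = 0.05
    frac_small_seed: float = 0.05
    frac_fis_up: float = 0.02
    low_expression_fraction: float = 0.05
    noise_sd_affy: float = 0.15
    noise_sd_agilent: float = 0.15
    dye_bias_sd: float = 0.10
    baseline_median: float = 500.0
    baseline_log_sd: float = 0.5
    effect_low: float = 0.8
    effect_high: float = 2.0
    null_fc_limit: float = 0.15
    multi_probe_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_large_seed,
            self.frac_small_seed,
            self.frac_fis_up,
            self.low_expression_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        class_sum = self.frac_large_seed + self.frac_small_seed + self.frac_fis_up
        if class_sum > 1.0:
            raise ValueError("class fractions sum to more than 1")
        if self.low_expression_fraction > 1.0 - class_sum:
            raise ValueError("low-expression genes must come from the background")
        for name in ("noise_sd_affy", "noise_sd_agilent", "dye_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.6 < self.effect_low <= self.effect_high:
            raise ValueError("planted effects must exceed the 0.6 call threshold")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted per-gene truth: log2 fold changes vs the balanced control.

    ``fc`` is genes x experimental crosses; ``direction`` records whether a
    class gene is the up-in-associated-crosses or down-in-opposite-crosses
    variant of its class.  ``probes`` maps each gene to its synthetic
    Affymetrix probe set and Agilent 60-mer identifiers.
    """

    fc: pd.DataFrame
    classes: pd.Series
    direction: pd.Series
    low_expression: pd.Series
    probes: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.fc.index

    def gene_map(self) -> pd.DataFrame:
        """(at_id, probe_set_id, probe_id) mapping, as the correspondence
        stage would recover it for the default one-probe-per-gene design."""
        return self.probes.reset_index().rename(columns={"gene_id": "at_id"})

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "gene_id": self.fc.index,
                "class": self.classes.values,
                "direction": self.direction.values,
                "low_expression": self.low_expression.values,
                "probe_set_id": self.probes["probe_set_id"].values,
                "probe_id": self.probes["probe_id"].values,
            }
        )
        for cross in self.fc.columns:
            out[f"fc_{cross}"] = self.fc[cross].values
        return out


def _gene_ids(n: int) -> list[str]:
    return [f"At{i % 5 + 1}g{(i // 5 + 1) * 10:05d}" for i in range(n)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_truth(
    config: SimulationConfig,
    designs: dict[str, CrossDesign] | None = None,
) -> TruthTable:
    """Plant per-gene true fold changes for every experimental cross.

    Class gene counts are exact — ``round(fraction * n_genes)`` genes are
    assigned to each class along a seeded shuffle — so tests on counts are
    deterministic rather than binomial.
    """
    designs = designs if designs is not None else DEFAULT_DESIGNS
    missing = set(DEFAULT_DESIGNS) - set(designs)
    if missing:
        raise ValueError(f"designs must cover all crosses; missing {sorted(missing)}")

    rng = _rng(config, 0)
    n = config.n_genes
    genes = _gene_ids(n)
    order = rng.permutation(n)

    n_large = round(config.frac_large_seed * n)
    n_small = round(config.frac_small_seed * n)
    n_fis = round(config.frac_fis_up * n)
    n_low = round(config.low_expression_fraction * n)

    classes = np.full(n, "background", dtype=object)
    direction = np.full(n, "none", dtype=object)
    classes[order[:n_large]] = "large_seed"
    classes[order[n_large : n_large + n_small]] = "small_seed"
    classes[order[n_large + n_small : n_large + n_small + n_fis]] = "fis_up"
    for cls, start, count in (
        ("large_seed", 0, n_large),
        ("small_seed", n_large, n_small),
    ):
        idx = order[start : start + count]
        direction[idx[0::2]] = "up"
        direction[idx[1::2]] = "down"
    direction[order[n_large + n_small : n_large + n_small + n_fis]] = "up"

    low = np.zeros(n, dtype=bool)
    low[order[n_large + n_small + n_fis : n_large + n_small + n_fis + n_low]] = True

    fc = pd.DataFrame(
        rng.uniform(-config.null_fc_limit, config.null_fc_limit, (n, len(AFFY_CROSSES))),
        index=pd.Index(genes, name="gene_id"),
        columns=list(AFFY_CROSSES),
    )
    effects = rng.uniform(config.effect_low, config.effect_high, n)
    jitter = pd.DataFrame(
        rng.uniform(0.95, 1.05, (n, len(AFFY_CROSSES))),
        index=fc.index,
        columns=fc.columns,
    )

    target_crosses = {
        ("large_seed", "up"): (PATERNALIZED, +1),
        ("large_seed", "down"): (MATERNALIZED, -1),
        ("small_seed", "up"): (MATERNALIZED, +1),
        ("small_seed", "down"): (PATERNALIZED, -1),
        ("fis_up", "up"): (("fis1X2x", "msi1"), +1),
    }
    for (cls, direc), (crosses, sign) in target_crosses.items():
        mask = (classes == cls) & (direction == direc)
        for cross in crosses:
            fc.loc[mask, cross] = sign * effects[mask] * jitter.loc[mask, cross]

    probes = pd.DataFrame(
        {
            "probe_set_id": [f"ps{i:05d}_at" for i in range(n)],
            "probe_id": [f"crs{i:05d}" for i in range(n)],
        },
        index=fc.index,
    )
    return TruthTable(
        fc=fc,
        classes=pd.Series(classes, index=fc.index, name="class"),
        direction=pd.Series(direction, index=fc.index, name="direction"),
        low_expression=pd.Series(low, index=fc.index, name="low_expression"),
        probes=probes,
    )


def _change_p(rng: np.random.Generator, fc: np.ndarray) -> np.ndarray:
    """MAS5-style change P-values: near 0 = confident increase, near 1 =
    confident decrease, 0.5 = no evidence."""
    p = np.full(fc.shape, 0.5)
    up = fc >= 0.6
    down = fc <= -0.6
    p[up] = rng.uniform(0.0, 0.001, up.sum())
    p[down] = rng.uniform(0.999, 1.0, down.sum())
    return p


def generate_affymetrix(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-comparison (SLR, change P) statistics plus detection P-values.

    Each experimental replicate is compared to both control replicates:
    four comparisons per probe set for two-replicate crosses, two for
    msi1.  Returns ``(comparisons, detection)`` tidy frames.
    """
    missing = [c for c in AFFY_CROSSES if c not in truth.fc.columns]
    if missing:
        raise ValueError(f"truth table lacks crosses: {missing}")
    rng = _rng(config, 1)
    n = len(truth.gene_ids)
    ps_ids = truth.probes["probe_set_id"].values

    frames = []
    for cross in AFFY_CROSSES:
        k = expected_comparisons(cross)
        fc = np.repeat(truth.fc[cross].values, k)
        slr = fc + rng.normal(0.0, config.noise_sd_affy, n * k)
        frames.append(
            pd.DataFrame(
                {
                    "probe_set_id": np.repeat(ps_ids, k),
                    "cross": cross,
                    "comparison_index": np.tile(np.arange(1, k + 1), n),
                    "slr": slr,
                    "p": _change_p(rng, fc),
                }
            )
        )
    comparisons = pd.concat(frames, ignore_index=True)

    arrays = [f"{CONTROL_CROSS}_rep{r}" for r in (1, 2)] + [
        f"{cross}_rep{r}"
        for cross in AFFY_CROSSES
        for r in range(1, DEFAULT_DESIGNS[cross].n_replicates + 1)
    ]
    low = truth.low_expression.values
    det_frames = []
    for array in arrays:
        p = np.empty(n)
        p[~low] = rng.uniform(0.0, 0.05, (~low).sum())
        p[low] = rng.uniform(0.061, 1.0, low.sum())
        det_frames.append(
            pd.DataFrame({"probe_set_id": ps_ids, "array": array, "detection_p": p})
        )
    detection = pd.concat(det_frames, ignore_index=True)
    return comparisons, detection


def generate_agilent(
    truth: TruthTable,
    config: SimulationConfig,
    crosses: tuple[str, ...] = AGILENT_CROSSES,
) -> pd.DataFrame:
    """Dye-swap two-dye signals for the five sexual crosses.

    Per cross and probe: two arrays with swapped Cy3/Cy5 assignment, a
    shared per-gene dye bias that flips sign with orientation (so it
    cancels on averaging), and log-normal baselines.  No Agilent data
    exists for msi1; requesting it is an error.
    """
    if "msi1" in crosses:
        raise ValueError("no Agilent arrays exist for msi1 in this design")
    missing = [c for c in crosses if c not in truth.fc.columns]
    if missing:
        raise ValueError(f"truth table lacks crosses: {missing}")
    rng = _rng(config, 2)
    n = len(truth.gene_ids)
    probe_ids = truth.probes["probe_id"].values
    low = truth.low_expression.values

    baseline = np.exp(
        rng.normal(math.log(config.baseline_median), config.baseline_log_sd, n)
    )
    baseline = np.clip(baseline, 30.0, None)  # keeps normal genes above the sum>50 rule

    frames = []
    for cross in crosses:
        fc = truth.fc[cross].values
        bias = rng.normal(0.0, config.dye_bias_sd, n)
        for array_index, orientation, bias_sign in ((1, EXP_CY5, +1), (2, EXP_CY3, -1)):
            lr = fc + bias_sign * bias + rng.normal(0.0, config.noise_sd_agilent, n)
            s_ctrl = baseline
            s_exp = baseline * np.power(2.0, lr)
            if orientation == EXP_CY5:
                cy5, cy3 = s_exp.copy(), s_ctrl.copy()
            else:
                cy3, cy5 = s_exp.copy(), s_ctrl.copy()
            # planted low-expression genes: dim in both channels everywhere
            cy3[low] = rng.uniform(5.0, 25.0, low.sum())
            cy5[low] = rng.uniform(5.0, 25.0, low.sum())
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "cross": cross,
                        "array_index": array_index,
                        "dye_orientation": orientation,
                        "cy3": cy3,
                        "cy5": cy5,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_sequences(
    truth: TruthTable, config: SimulationConfig
) -> tuple[dict[str, str], list[ProbeSetRecord], list[LongProbeRecord]]:
    """Transcripts plus probe sequences consistent with the truth table.

    One transcript per gene; 11 PM 25-mers and one sense 60-mer sampled as
    exact substrings, with the full transcript as the probe set's target
    sequence.  When ``multi_probe_fraction`` > 0, affected genes receive a
    second, degraded 60-mer (five mismatches, Q = 55/60) to exercise the
    best-sense-match retention rule.
    """
    rng = _rng(config, 3)
    transcripts: dict[str, str] = {}
    probe_sets: list[ProbeSetRecord] = []
    long_probes: list[LongProbeRecord] = []
    n = len(truth.gene_ids)
    n_multi = round(config.multi_probe_fraction * n)

    for i, gene in enumerate(truth.gene_ids):
        length = int(rng.integers(200, 401))
        seq = _random_seq(rng, length)
        transcripts[gene] = seq

        pm_offsets = np.sort(rng.choice(length - 25 + 1, size=11, replace=False))
        pm = [seq[o : o + 25] for o in pm_offsets]
        probe_sets.append(
            ProbeSetRecord(truth.probes["probe_set_id"].iloc[i], pm, seq)
        )

        offset = int(rng.integers(0, length - 60 + 1))
        probe_id = truth.probes["probe_id"].iloc[i]
        long_probes.append(LongProbeRecord(probe_id, seq[offset : offset + 60]))

        if i < n_multi:
            # second probe with 5 mismatches confined to the first 10
            # positions, so a long exact stretch survives for seeding
            alt = bytearray(seq[offset : offset + 60], "ascii")
            for pos in rng.choice(10, size=5, replace=False):
                cur = alt[pos]
                choices = [b for b in b"ACGT" if b != cur]
                alt[pos] = choices[int(rng.integers(0, 3))]
            long_probes.append(LongProbeRecord(f"{probe_id}x", alt.decode("ascii")))

    return transcripts, probe_sets, long_probes
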