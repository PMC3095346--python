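"""qRT-PCR relative expression (Pfaffl) and microarray concordance.

The Pfaffl ratio corrects relative quantification for amplification
efficiency: Ratio = E_target^dCT_target / E_ref^dCT_ref, with dCT the
control-minus-experimental threshold-cycle difference and E in [1, 2]
(2 = perfect doubling per cycle).  Replicate reactions are averaged on
the ratio scale; the averaged ratio is called up/down/unchanged with
the same +/-0.6 log2 cutoff used for the arrays, and calls are scored
against the microarray call per platform and cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contrasts import round_half_up

QPCR_LOG2_THRESHOLD = 0.6

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass(frozen=True)
class QpcrReaction:
    gene_id: str
    cross_label: str
    efficiency_target: float
    efficiency_ref: float
    dct_target: float
    dct_ref: float

    def __post_init__(self) -> None:
        for e in (self.efficiency_target, self.efficiency_ref):
            if not 1.0 <= e <= 2.2:
                raise ValueError(f"amplification efficiency {e} outside [1, 2.2]")


def pfaffl_ratio(
    efficiency_target: float,
    dct_target: float,
    efficiency_ref: float,
    dct_ref: float,
) -> float:
    """Efficiency-corrected expression ratio E_t^dCT_t / E_r^dCT_r."""
    if efficiency_target <= 0 or efficiency_ref <= 0:
        raise ValueError("amplification efficiencies must be positive")
    return efficiency_target**dct_target / efficiency_ref**dct_ref


def reaction_ratio(r: QpcrReaction) -> float:
    return pfaffl_ratio(r.efficiency_target, r.dct_target, r.efficiency_ref, r.dct_ref)


def mean_ratio(ratios: Iterable[float]) -> float:
    """Replicate reactions averaged on the ratio scale."""
    vals = list(ratios)
    if not vals:
        raise ValueError("no reactions to average")
    return sum(vals) / len(vals)


def qpcr_call(ratio: float, log2_threshold: float = QPCR_LOG2_THRESHOLD) -> str:
    """up / down / unchanged from a mean expression ratio.

    Mirrors the microarray rule: |log2(ratio)| >= 0.6 calls a change.
    """
    if ratio <= 0:
        raise ValueError("expression ratio must be positive")
    lr = math.log2(ratio)
    if lr >= log2_threshold:
        return UP
    if lr <= -log2_threshold:
        return DOWN
    return UNCHANGED


def concordance(
    microarray_calls: Mapping[tuple[str, str, str], str],
    qpcr_calls: Mapping[tuple[str, str], str],
    genes: Sequence[str],
    cells: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, dict]:
    """Microarray-vs-qPCR call agreement per (platform, cross) cell.

    ``microarray_calls`` maps (platform, cross, gene) -> call and
    ``qpcr_calls`` maps (cross, gene) -> call, each in
    {up, down, unchanged}.  ``cells`` lists the (platform, cross) cells
    to score — 11 in the study design (6 Affymetrix + 5 Agilent crosses).
    A gene missing either call in a cell is counted as not tested.
    Returns the per-cell table and an overall summary where
    percent = 100 * total agreements / total tested, half-up to integer.
    """
    rows = []
    total_agree = total_tested = 0
    for platform, cross in cells:
        n_agree = n_tested = 0
        for gene in genes:
            ma = microarray_calls.get((platform, cross, gene))
            qp = qpcr_calls.get((cross, gene))
            if ma is None or qp is None:
                continue
            n_tested += 1
            n_agree += ma == qp
        percent = round_half_up(100.0 * n_agree / n_tested, 0) if n_tested else None
        rows.append(
            {
                "platform": platform,
                "cross": cross,
                "n_agree": n_agree,
                "n_tested": n_tested,
                "percent": percent,
            }
        )
        total_agree += n_agree
        total_tested += n_tested
    overall = {
        "n_agree": total_agree,
        "n_tested": total_tested,
        "percent": round_half_up(100.0 * total_agree / total_tested, 0)
        if total_tested
        else None,
    }
    return pd.DataFrame(rows), overall
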