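"""Per-gene, per-cross expression summaries for both platforms.

Affymetrix comparisons arrive as (SLR, change P) pairs from pairwise
MAS5/GCOS analysis; the change P is two-tailed in convention — values
near 0 mean confident increase, near 1 confident decrease, and 0.5 no
evidence.  The pSLR shrinks each SLR by a sigmoid weight of the folded
P-value so that statistically unsupported log-ratios approach zero:

    pSLR = SLR * w(p*),  p* = 2 * min(P, 1 - P),
    w(p*) = 1 / (1 + exp((2 * p* - 1) / 0.01))

For P near 0 or 1, w -> 1 and pSLR is essentially the SLR; at P = 0.5,
w < 1e-40 and the pSLR vanishes.  Agilent two-dye log-ratios are
oriented experimental-over-control on each array and averaged over the
dye swap, cancelling dye bias.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import AGILENT_CROSSES, expected_comparisons
from .simulate import EXP_CY5

#: sigmoid sharpness of the pSLR weight (log2-ratio P-value scale)
PSLR_SCALE = 0.01
DETECTION_ALPHA = 0.06
SIGNAL_FLOOR = 50.0


def pslr(slr, p):
    """P-value weighted signal log-ratio; accepts scalars or arrays.

    Raises if any P-value falls outside [0, 1].
    """
    slr_arr = np.asarray(slr, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if not np.all((p_arr >= 0.0) & (p_arr <= 1.0)):
        raise ValueError("change P-values must lie in [0, 1]")
    p_star = 2.0 * np.minimum(p_arr, 1.0 - p_arr)
    w = 1.0 / (1.0 + np.exp((2.0 * p_star - 1.0) / PSLR_SCALE))
    out = slr_arr * w
    if np.isscalar(slr) and np.isscalar(p):
        return float(out)
    return out


def average_pslr(slrs: Sequence[float], ps: Sequence[float], cross_label: str) -> float:
    """Mean pSLR over the array comparisons of one probe set and cross.

    The comparison count is fixed by the design: four for two-replicate
    crosses (2 experimental x 2 control replicates), two for msi1.
    """
    if len(slrs) != len(ps):
        raise ValueError("slrs and ps differ in length")
    k = expected_comparisons(cross_label)
    if len(slrs) != k:
        raise ValueError(
            f"{cross_label} requires {k} comparisons, got {len(slrs)}"
        )
    return float(np.mean(pslr(np.asarray(slrs), np.asarray(ps))))


def _row_logratio(df: pd.DataFrame) -> pd.Series:
    """Experimental-over-control log2 ratio per dye-swap row."""
    if (df[["cy3", "cy5"]] <= 0).any().any():
        raise ValueError("non-positive two-dye signal")
    exp_cy5 = df["dye_orientation"] == EXP_CY5
    ratio = np.where(exp_cy5, df["cy5"] / df["cy3"], df["cy3"] / df["cy5"])
    return pd.Series(np.log2(ratio), index=df.index)


def agilent_logratio(pair: pd.DataFrame) -> float:
    """Dye-swap averaged log-ratio for one probe in one cross.

    ``pair`` holds the two arrays of the swap (columns ``array_index``,
    ``dye_orientation``, ``cy3``, ``cy5``).  The ratio is oriented
    experimental/control on each array regardless of dye, so a pure dye
    bias of +b/-b around the true fold change cancels exactly.
    """
    if len(pair) != 2 or set(pair["array_index"]) != {1, 2}:
        raise ValueError("a dye-swap pair requires exactly arrays 1 and 2")
    if len(set(pair["dye_orientation"])) != 2:
        raise ValueError("dye-swap partner arrays must have opposite orientation")
    return float(_row_logratio(pair).mean())


def presence_filter(
    agilent_sums: Mapping[str, tuple[float, float]],
    detection_ps: Iterable[float],
    signal_floor: float = SIGNAL_FLOOR,
    detection_alpha: float = DETECTION_ALPHA,
) -> bool:
    """Presence rule for one gene's probe pair across all crosses.

    Present iff (a) some cross has Cy3+Cy5 strictly above ``signal_floor``
    on *both* dye-swap arrays, and (b) some Affymetrix array has detection
    P <= ``detection_alpha`` (the complement of 'absent on every array').
    """
    agilent_ok = any(
        s1 > signal_floor and s2 > signal_floor for s1, s2 in agilent_sums.values()
    )
    affy_ok = any(p <= detection_alpha for p in detection_ps)
    return agilent_ok and affy_ok


def affy_summaries(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Averaged pSLR per (probe_set_id, cross); validates comparison counts."""
    df = comparisons.copy()
    df["pslr"] = pslr(df["slr"].to_numpy(), df["p"].to_numpy())
    grouped = df.groupby(["probe_set_id", "cross"], sort=True)["pslr"].agg(["mean", "size"])
    for (ps, cross), size in grouped["size"].items():
        if size != expected_comparisons(cross):
            raise ValueError(
                f"{ps}/{cross}: expected {expected_comparisons(cross)} "
                f"comparisons, got {size}"
            )
    out = grouped["mean"].rename("avg_pslr").reset_index()
    return out


def agilent_summaries(dyeswap: pd.DataFrame) -> pd.DataFrame:
    """Dye-swap averaged log-ratio per (probe_id, cross)."""
    df = dyeswap.copy()
    counts = df.groupby(["probe_id", "cross"]).size()
    if (counts != 2).any():
        bad = counts[counts != 2].index[0]
        raise ValueError(f"probe/cross {bad} lacks a dye-swap partner array")
    df["logratio"] = _row_logratio(df)
    out = (
        df.groupby(["probe_id", "cross"], sort=True)["logratio"]
        .mean()
        .rename("avg_slr_agilent")
        .reset_index()
    )
    return out


def presence_flags(
    dyeswap: pd.DataFrame,
    detection: pd.DataFrame,
    signal_floor: float = SIGNAL_FLOOR,
    detection_alpha: float = DETECTION_ALPHA,
) -> tuple[pd.Series, pd.Series]:
    """Vectorized presence components: per probe_id and per probe_set_id."""
    sums = dyeswap.assign(total=dyeswap["cy3"] + dyeswap["cy5"])
    both_over = (
        sums.groupby(["probe_id", "cross"])["total"].min().gt(signal_floor)
    )
    agilent_ok = both_over.groupby("probe_id").any()
    affy_ok = (
        detection.groupby("probe_set_id")["detection_p"].min().le(detection_alpha)
    )
    return agilent_ok, affy_ok


def summarize_genes(
    comparisons: pd.DataFrame,
    detection: pd.DataFrame,
    dyeswap: pd.DataFrame,
    gene_map: pd.DataFrame,
    signal_floor: float = SIGNAL_FLOOR,
    detection_alpha: float = DETECTION_ALPHA,
) -> pd.DataFrame:
    """Tidy per-gene, per-cross summary joining both platforms.

    ``gene_map`` has columns (at_id, probe_set_id, probe_id) — the output
    of the correspondence collapse.  Returns columns (at_id, cross,
    avg_pslr, avg_slr_agilent, present); Agilent values are NaN for msi1,
    which has no two-dye arrays.
    """
    required = {"at_id", "probe_set_id", "probe_id"}
    if not required.issubset(gene_map.columns):
        raise ValueError(f"gene_map needs columns {sorted(required)}")

    affy = affy_summaries(comparisons).merge(
        gene_map[["at_id", "probe_set_id"]], on="probe_set_id", how="inner"
    )
    agil = agilent_summaries(dyeswap).merge(
        gene_map[["at_id", "probe_id"]], on="probe_id", how="inner"
    )
    merged = affy.merge(
        agil[["at_id", "cross", "avg_slr_agilent"]], on=["at_id", "cross"], how="left"
    )

    agilent_ok, affy_ok = presence_flags(dyeswap, detection, signal_floor, detection_alpha)
    gm = gene_map.set_index("at_id")
    present = (
        gm["probe_id"].map(agilent_ok).fillna(False)
        & gm["probe_set_id"].map(affy_ok).fillna(False)
    )
    merged["present"] = merged["at_id"].map(present).astype(bool)
    cols = ["at_id", "cross", "avg_pslr", "avg_slr_agilent", "present"]
    return merged[cols].sort_values(["at_id", "cross"], ignore_index=True)
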