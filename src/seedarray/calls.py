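"""Categorical differential-expression calls and cross-platform consensus.

A gene is called up when its averaged SLR (Agilent) or pSLR (Affymetrix)
is >= 0.6 (about a 50% expression change) and down when <= -0.6.  The
broader 'not up' (<= 0.3, about a 20% change) and 'not down' (>= -0.3)
flags feed the contrast-set algebra.  The consensus call requires both
platforms to agree: up on both, or both values at or below 0.3 for 'not
up'.  msi1, which has Affymetrix data only, is called on its single
platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UP_THRESHOLD = 0.6
NEUTRAL_THRESHOLD = 0.3

UP, DOWN, NEITHER, NONE = "up", "down", "neither", "none"


@dataclass(frozen=True)
class PlatformCall:
    call: str  # up | down | neither
    not_up: bool
    not_down: bool


def platform_call(
    value: float,
    up_threshold: float = UP_THRESHOLD,
    neutral_threshold: float = NEUTRAL_THRESHOLD,
) -> PlatformCall:
    """Single-platform call with its (not_up, not_down) flags.

    All thresholds are inclusive: 0.6 is up, 0.3 is not_up, -0.3 is
    not_down.  A value in [-0.3, 0.3] is simultaneously not_up and
    not_down.
    """
    if not np.isfinite(value):
        raise ValueError("call value must be finite")
    if value >= up_threshold:
        call = UP
    elif value <= -up_threshold:
        call = DOWN
    else:
        call = NEITHER
    return PlatformCall(call, value <= neutral_threshold, value >= -neutral_threshold)


def consensus_call(affy: PlatformCall, agilent: PlatformCall) -> str:
    """Two-platform consensus: up/down only when both platforms agree."""
    if affy.call == agilent.call and affy.call in (UP, DOWN):
        return affy.call
    return NONE


def _vector_calls(values: np.ndarray, up: float) -> np.ndarray:
    out = np.full(values.shape, NEITHER, dtype=object)
    with np.errstate(invalid="ignore"):
        out[values >= up] = UP
        out[values <= -up] = DOWN
    out[~np.isfinite(values)] = NONE
    return out


def build_call_table(
    summary: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD,
    neutral_threshold: float = NEUTRAL_THRESHOLD,
    present_only: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-cross call table from the two-platform summary.

    Input is the tidy frame from :func:`seedarray.platform_stats.summarize_genes`.
    Consensus columns use both platforms where both exist; crosses with a
    single platform (msi1) fall back to that platform's call and flags.
    Returns columns (at_id, cross, avg_pslr, avg_slr_agilent, affy_call,
    agilent_call, consensus, not_up, not_down).
    """
    df = summary.copy()
    if present_only:
        df = df[df["present"].astype(bool)].copy()
    affy = df["avg_pslr"].to_numpy(dtype=float)
    agil = df["avg_slr_agilent"].to_numpy(dtype=float)
    if not np.all(np.isfinite(affy)):
        raise ValueError("non-finite Affymetrix summary value")

    df["affy_call"] = _vector_calls(affy, up_threshold)
    df["agilent_call"] = _vector_calls(agil, up_threshold)

    has_agilent = np.isfinite(agil)
    consensus = np.full(len(df), NONE, dtype=object)
    both_up = has_agilent & (df["affy_call"] == UP) & (df["agilent_call"] == UP)
    both_down = has_agilent & (df["affy_call"] == DOWN) & (df["agilent_call"] == DOWN)
    consensus[both_up] = UP
    consensus[both_down] = DOWN
    # single-platform crosses: the Affymetrix call stands alone
    solo = ~has_agilent
    solo_calls = df.loc[solo, "affy_call"].replace(NEITHER, NONE).to_numpy()
    consensus[solo] = solo_calls

    with np.errstate(invalid="ignore"):
        not_up = (affy <= neutral_threshold) & (
            ~has_agilent | (agil <= neutral_threshold)
        )
        not_down = (affy >= -neutral_threshold) & (
            ~has_agilent | (agil >= -neutral_threshold)
        )
    df["consensus"] = consensus
    df["not_up"] = not_up
    df["not_down"] = not_down
    cols = [
        "at_id",
        "cross",
        "avg_pslr",
        "avg_slr_agilent",
        "affy_call",
        "agilent_call",
        "consensus",
        "not_up",
        "not_down",
    ]
    return df[cols].reset_index(drop=True)


def count_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-cross counts of up/down calls and the cross-platform overlap.

    Overlap counts genes called in the same direction on both platforms;
    Agilent and overlap cells are left missing for single-platform
    crosses, matching the study's summary-table layout.
    """
    rows = []
    for cross, grp in calls.groupby("cross", sort=True):
        has_agilent = grp["agilent_call"].isin([UP, DOWN, NEITHER]).any()
        row = {
            "cross": cross,
            "affy_up": int((grp["affy_call"] == UP).sum()),
            "affy_down": int((grp["affy_call"] == DOWN).sum()),
        }
        if has_agilent:
            row["agilent_up"] = int((grp["agilent_call"] == UP).sum())
            row["agilent_down"] = int((grp["agilent_call"] == DOWN).sum())
            row["overlap_up"] = int(
                ((grp["affy_call"] == UP) & (grp["agilent_call"] == UP)).sum()
            )
            row["overlap_down"] = int(
                ((grp["affy_call"] == DOWN) & (grp["agilent_call"] == DOWN)).sum()
            )
        else:
            row.update(
                agilent_up=pd.NA, agilent_down=pd.NA, overlap_up=pd.NA, overlap_down=pd.NA
            )
        rows.append(row)
    cols = [
        "cross",
        "affy_up",
        "agilent_up",
        "overlap_up",
        "affy_down",
        "agilent_down",
        "overlap_down",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
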