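"""Phenotype-associated contrast sets and agreement statistics.

A contrast definition is a conjunctive recipe over the call table: a
gene belongs to the set when it is consensus-up in every
``required_up`` cross, flagged not_up in every ``required_not_up``
cross, and likewise for the down side.  The built-in recipes reproduce
the study's seed-class gene lists, e.g. genes strongly associated with
endosperm overproliferation are up in 2xX4x and 2xX6x and not up in
4xX2x and 6xX2x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .calls import DOWN, UP


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding as used for printed percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContrastDefinition:
    name: str
    required_up: frozenset[str] = field(default_factory=frozenset)
    required_not_up: frozenset[str] = field(default_factory=frozenset)
    required_down: frozenset[str] = field(default_factory=frozenset)
    required_not_down: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_up", frozenset(self.required_up))
        object.__setattr__(self, "required_not_up", frozenset(self.required_not_up))
        object.__setattr__(self, "required_down", frozenset(self.required_down))
        object.__setattr__(self, "required_not_down", frozenset(self.required_not_down))
        if self.required_up & self.required_not_up:
            raise ValueError(f"{self.name}: up and not_up sets overlap")
        if self.required_down & self.required_not_down:
            raise ValueError(f"{self.name}: down and not_down sets overlap")

    @property
    def crosses(self) -> frozenset[str]:
        return (
            self.required_up
            | self.required_not_up
            | self.required_down
            | self.required_not_down
        )


#: The seven seed-class recipes of the study's supplementary gene lists,
#: plus the two headline tables (up in both paternal-excess crosses and
#: its maternal-excess mirror).  msi1 conditions are evaluated on its
#: single platform.
BUILTIN_CONTRASTS: dict[str, ContrastDefinition] = {
    d.name: d
    for d in (
        ContrastDefinition(
            "s5_1",
            required_up=frozenset({"2xX4x"}),
            required_not_up=frozenset({"4xX2x", "6xX2x"}),
        ),
        ContrastDefinition(
            "s5_2",
            required_up=frozenset({"2xX6x", "fis1X2x"}),
            required_not_up=frozenset({"4xX2x", "6xX2x"}),
        ),
        ContrastDefinition(
            "s5_3",
            required_down=frozenset({"4xX2x"}),
            required_not_down=frozenset({"2xX4x", "2xX6x"}),
        ),
        ContrastDefinition(
            "s5_4",
            required_up=frozenset({"4xX2x"}),
            required_not_up=frozenset({"2xX4x", "2xX6x"}),
        ),
        ContrastDefinition(
            "s5_5",
            required_down=frozenset({"2xX4x"}),
            required_not_down=frozenset({"4xX2x", "6xX2x"}),
        ),
        ContrastDefinition(
            "s5_6",
            required_down=frozenset({"2xX6x", "fis1X2x"}),
            required_not_down=frozenset({"4xX2x", "6xX2x"}),
        ),
        ContrastDefinition(
            "s5_7",
            required_up=frozenset({"fis1X2x", "msi1"}),
        ),
        ContrastDefinition(
            "large_seed_core",
            required_up=frozenset({"2xX4x", "2xX6x"}),
            required_not_up=frozenset({"4xX2x", "6xX2x"}),
        ),
        ContrastDefinition(
            "small_seed_core",
            required_up=frozenset({"4xX2x", "6xX2x"}),
            required_not_up=frozenset({"2xX4x", "2xX6x"}),
        ),
    )
}


def build_contrast_set(defn: ContrastDefinition, calls: pd.DataFrame) -> list[str]:
    """Genes satisfying every condition of a contrast definition.

    Uses consensus calls and two-platform flags (single-platform for
    crosses without Agilent data, as the call table already encodes).
    """
    known = set(calls["cross"].unique())
    unknown = defn.crosses - known
    if unknown:
        raise KeyError(f"{defn.name}: unknown cross labels {sorted(unknown)}")

    wide_consensus = calls.pivot(index="at_id", columns="cross", values="consensus")
    wide_not_up = calls.pivot(index="at_id", columns="cross", values="not_up")
    wide_not_down = calls.pivot(index="at_id", columns="cross", values="not_down")

    mask = pd.Series(True, index=wide_consensus.index)
    for cross in defn.required_up:
        mask &= wide_consensus[cross].eq(UP)
    for cross in defn.required_down:
        mask &= wide_consensus[cross].eq(DOWN)
    for cross in defn.required_not_up:
        mask &= wide_not_up[cross].fillna(False).astype(bool)
    for cross in defn.required_not_down:
        mask &= wide_not_down[cross].fillna(False).astype(bool)
    return sorted(mask.index[mask])


def build_all_contrasts(
    calls: pd.DataFrame,
    definitions: Mapping[str, ContrastDefinition] | None = None,
) -> dict[str, list[str]]:
    definitions = definitions if definitions is not None else BUILTIN_CONTRASTS
    return {name: build_contrast_set(d, calls) for name, d in definitions.items()}


def agreement_percentage(n_a: int, n_b: int, n_overlap: int, decimals: int = 1):
    """Overlap as a percentage of the maximum possible agreement.

    The maximum possible agreement between two gene sets is the size of
    the smaller set, so the statistic is 100 * overlap / min(n_a, n_b),
    half-up rounded.  Undefined (``None``) when either set is empty.
    """
    if n_overlap < 0 or n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    smaller = min(n_a, n_b)
    if n_overlap > smaller:
        raise ValueError("overlap exceeds the smaller set")
    if smaller == 0:
        return None
    return round_half_up(100.0 * n_overlap / smaller, decimals)


def annotation_fraction(
    gene_list: Sequence[str],
    flags: Mapping[str, bool],
    decimals: int = 1,
) -> float:
    """Percentage of a gene list carrying an annotation flag.

    Genes missing from ``flags`` default to False (unannotated).
    """
    if len(gene_list) == 0:
        raise ValueError("annotation fraction is undefined for an empty list")
    hits = sum(1 for g in gene_list if flags.get(g, False))
    return round_half_up(100.0 * hits / len(gene_list), decimals)
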