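"""Experimental design of the silique profiling study.

Seven 'crosses' are profiled against the balanced diploid control
(2xX2x): four interploidy crosses, a fertilized *fis1* mutant, and
unfertilized (autonomous) *msi1* seeds.  Interploidy crosses shift the
maternal:paternal genome ratio in the endosperm — paternal excess
(2xX4x, 2xX6x) drives endosperm overproliferation, maternal excess
(4xX2x, 6xX2x) inhibits it — while the FIS-class mutants phenocopy
paternal excess through loss of PRC2 function.

The Affymetrix experiment covers all seven crosses (one biological
replicate for msi1, two for the rest); the Agilent two-dye experiment
covers the five sexual crosses only.
"""

from __future__ import annotations

from dataclasses import dataclass

CONTROL_CROSS = "2xX2x"

#: Crosses whose transcriptomes group with paternal excess.
PATERNALIZED = ("2xX4x", "2xX6x", "fis1X2x")
#: Crosses whose transcriptomes group with maternal excess.
MATERNALIZED = ("4xX2x", "6xX2x", "msi1")

#: Experimental crosses hybridized on each platform.
AFFY_CROSSES = ("2xX4x", "2xX6x", "4xX2x", "6xX2x", "fis1X2x", "msi1")
AGILENT_CROSSES = ("2xX4x", "2xX6x", "4xX2x", "6xX2x", "fis1X2x")

ALL_CROSSES = (CONTROL_CROSS,) + AFFY_CROSSES

PHENOTYPE_CLASSES = (
    "balanced",
    "paternal_excess",
    "maternal_excess",
    "fis_mutant_fertilized",
    "fis_mutant_autonomous",
)


@dataclass(frozen=True)
class CrossDesign:
    """One 'cross' in the study design.

    ``maternal_genomes_endosperm``/``paternal_genomes_endosperm`` give the
    absolute genome counts in the endosperm (2:1 in a balanced cross, since
    the diploid central cell fuses with one haploid sperm).
    """

    cross_label: str
    n_replicates: int
    maternal_genomes_endosperm: int
    paternal_genomes_endosperm: int
    phenotype_class: str

    def __post_init__(self) -> None:
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class: {self.phenotype_class!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: The study design: genome ratios follow the maternal:paternal spectrum
#: (2:1 balanced, 2:2 and 2:3 paternal excess, 4:1 and 6:1 maternal excess;
#: autonomous msi1 endosperm carries no paternal genomes).
DEFAULT_DESIGNS: dict[str, CrossDesign] = {
    d.cross_label: d
    for d in (
        CrossDesign("2xX2x", 2, 2, 1, "balanced"),
        CrossDesign("2xX4x", 2, 2, 2, "paternal_excess"),
        CrossDesign("2xX6x", 2, 2, 3, "paternal_excess"),
        CrossDesign("4xX2x", 2, 4, 1, "maternal_excess"),
        CrossDesign("6xX2x", 2, 6, 1, "maternal_excess"),
        CrossDesign("fis1X2x", 2, 2, 1, "fis_mutant_fertilized"),
        CrossDesign("msi1", 1, 2, 0, "fis_mutant_autonomous"),
    )
}


def expected_comparisons(cross_label: str) -> int:
    """Number of array-vs-control comparisons per probe set on Affymetrix.

    Each experimental replicate is compared against both replicates of the
    balanced control, giving four comparisons for two-replicate crosses and
    two for single-replicate msi1.
    """
    if cross_label not in AFFY_CROSSES:
        raise KeyError(f"not an experimental cross: {cross_label!r}")
    return DEFAULT_DESIGNS[cross_label].n_replicates * DEFAULT_DESIGNS[CONTROL_CROSS].n_replicates
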