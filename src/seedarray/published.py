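"""Published summary counts from the silique profiling study (GEO GSE20007).

These are the printed count columns of the study's summary tables —
inputs for desk-scale recomputation of the derived statistics (agreement
percentages, concordance rates, annotation fractions).  The underlying
genome-scale gene lists require the original array data and are not
bundled; synthetic data from :mod:`seedarray.simulate` exercises the
full pipeline instead.
"""

from __future__ import annotations

import pandas as pd

#: Genes called up/down per cross and platform, with the cross-platform
#: overlap.  msi1 was hybridized on Affymetrix only.
CROSS_PLATFORM_CALL_COUNTS = pd.DataFrame(
    [
        ("2xX4x", "up", 597, 755, 157),
        ("2xX4x", "down", 818, 378, 93),
        ("2xX6x", "up", 821, 814, 288),
        ("2xX6x", "down", 877, 1072, 392),
        ("4xX2x", "up", 1164, 870, 300),
        ("4xX2x", "down", 1854, 801, 326),
        ("6xX2x", "up", 1388, 2109, 776),
        ("6xX2x", "down", 1859, 2333, 921),
        ("fis1X2x", "up", 1068, 2582, 401),
        ("fis1X2x", "down", 1904, 3039, 710),
    ],
    columns=["cross", "direction", "affymetrix", "agilent", "overlap"],
)

#: qRT-PCR validation: agreements out of 20 genes per platform and cross
#: (11 cells; msi1 has no Agilent arrays).
QPCR_AGREEMENT_COUNTS = pd.DataFrame(
    [
        ("affymetrix", "msi1", 13),
        ("affymetrix", "6xX2x", 15),
        ("affymetrix", "4xX2x", 18),
        ("affymetrix", "2xX4x", 14),
        ("affymetrix", "2xX6x", 17),
        ("affymetrix", "fis1X2x", 18),
        ("agilent", "6xX2x", 15),
        ("agilent", "4xX2x", 8),
        ("agilent", "2xX4x", 17),
        ("agilent", "2xX6x", 19),
        ("agilent", "fis1X2x", 16),
    ],
    columns=["platform", "cross", "n_agree"],
)
QPCR_GENES_PER_CELL = 20

#: Transcription-factor annotation counts: genome-wide and among the
#: genes called present in the experiment.
TF_ANNOTATED_GENOME = 1922
PROTEIN_CODING_GENES = 27379
TF_ANNOTATED_PRESENT = 1192
GENES_CALLED_PRESENT = 14944
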