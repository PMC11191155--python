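"""Published PDAC metastasis case-study reference data (metadata only).

The 15-gene composite biomarker candidate reported for the PDAC metastasis
case study, together with its per-selector fold counts (out of 10) and the
cohort composition used there.  These are shipped as reference fixtures for
validation and documentation; nothing here is recomputed by the package.

Class-labelling convention (AJCC staging): stage IA-IIA with no regional
lymph-node invasion (N0) -> class 1 "non-metastasis"; stage IIB-IV (N>=1 or
M1) -> class 0 "metastasis".  Note class 0 is the majority class.
"""

from __future__ import annotations

PDAC_SIGNATURE_15: tuple[str, ...] = (
    "ABCC9", "AP1M2", "CAPN5", "ITK", "MPDZ", "RCSD1", "TMPRSS4",
    "ABCA8", "ELMO3", "C1R", "CELF2", "IL7R", "TTYH2", "CD37", "ZFP82",
)

# gene -> (lasso, boruta, varselrf) fold counts out of 10
PDAC_SIGNATURE_FOLD_COUNTS: dict[str, tuple[int, int, int]] = {
    "ABCC9": (10, 10, 10),
    "AP1M2": (10, 10, 10),
    "CAPN5": (10, 10, 10),
    "ITK": (10, 10, 10),
    "MPDZ": (10, 10, 10),
    "RCSD1": (10, 10, 6),
    "TMPRSS4": (10, 10, 10),
    "ABCA8": (9, 10, 9),
    "ELMO3": (9, 10, 5),
    "C1R": (8, 10, 10),
    "CELF2": (8, 10, 10),
    "IL7R": (8, 10, 10),
    "TTYH2": (8, 10, 9),
    "CD37": (7, 10, 9),
    "ZFP82": (7, 10, 8),
}

# cohort composition: class counts per role (class 0 = metastasis)
REFERENCE_COHORTS: dict[str, dict[int, int]] = {
    "train": {0: 201, 1: 107},
    "validation": {0: 138, 1: 43},
}

# percentages as printed in the study's stratification table
REFERENCE_COHORT_PERCENTS: dict[str, dict[int, float]] = {
    "train": {0: 65.26, 1: 34.74},
    "validation": {0: 76.25, 1: 23.75},
}


def load_signature() -> list[str]:
    """The 15-gene reference signature as a validated gene set."""
    genes = list(PDAC_SIGNATURE_15)
    if len(set(genes)) != len(genes):
        raise ValueError("signature fixture contains duplicates")
    if set(genes) != set(PDAC_SIGNATURE_FOLD_COUNTS):
        raise ValueError("signature fixture and fold-count table disagree")
    return genes
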