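"""Reference cohort tables: 15 presurgical TNBC patients, matched plasma
and urine liquid biopsies.

These small printed tables are the study conditions the package's synthetic
generator emulates and the inputs to the reference-cohort statistics:
per-patient cfDNA concentrations (ng/mL; zero means below the fluorometric
detection limit), the per-fluid five-class impact counts of the filtered
somatic variants, the per-fluid tier counts, the pooled VAF-bin counts, and
the cohort Venn components (fluid-exclusive and shared variant counts).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cfdna_concentrations",
    "class_count_table",
    "tier_count_table",
    "vaf_bin_counts",
    "venn_components",
]

_CONCENTRATIONS = [
    # patient_id, plasma ng/mL, urine ng/mL
    ("1", 37, 206),
    ("2", 218, 160),
    ("3", 80, 180),
    ("4", 356, 412),
    ("5", 252, 0),
    ("6", 172, 1820),
    ("7", 244, 196),
    ("8", 420, 0),
    ("9", 69, 650),
    ("10", 212, 192),
    ("11", 118, 1730),
    ("12", 442, 1410),
    ("13", 112, 180),
    ("14", 158, 110),
    ("15", 80, 254),
]


def cfdna_concentrations() -> pd.DataFrame:
    """Matched plasma/urine cfDNA concentrations (ng/mL) for 15 patients."""
    return pd.DataFrame(_CONCENTRATIONS, columns=["patient_id", "plasma_ng_ml", "urine_ng_ml"])


def class_count_table() -> pd.DataFrame:
    """Five-class impact counts of filtered variants per fluid (rows: fluid)."""
    return pd.DataFrame(
        {
            "pathogenic": [77, 71],
            "likely_pathogenic": [98, 204],
            "VUS": [1022, 1819],
            "likely_benign": [20, 17],
            "benign": [5, 6],
        },
        index=pd.Index(["plasma", "urine"], name="fluid"),
    )


def tier_count_table() -> pd.DataFrame:
    """Clinical-significance tier counts per fluid (rows: fluid)."""
    return pd.DataFrame(
        {"I": [6, 11], "II": [130, 158], "III": [1059, 1924], "IV": [27, 24]},
        index=pd.Index(["plasma", "urine"], name="fluid"),
    )


def vaf_bin_counts() -> pd.Series:
    """Pooled (both fluids) variant counts per VAF abundance bin."""
    return pd.Series(
        [1226, 1061, 633, 346, 73],
        index=pd.Index(["3-5", "5-10", "10-20", "20-50", "50-100"], name="vaf_bin"),
        name="count",
    )


def venn_components() -> dict[str, int]:
    """Cohort Venn components: fluid-exclusive and shared variant counts."""
    return {"plasma_exclusive": 791, "urine_exclusive": 1686, "shared": 431}
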