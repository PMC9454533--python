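"""ACMG/AMP five-class impact, AMP/ASCO/CAP tiering and VAF abundance bins.

The five-class impact call combines standardized evidence codes
(PVS/PS/PM/PP on the pathogenic side, BA/BS/BP on the benign side) with the
2015 ACMG/AMP combining rules.  Conflicting evidence — a pathogenic-side
rule and a benign-side rule both firing — resolves to VUS, as does the
absence of any firing rule.  Clinical-significance tiers follow the 2017
AMP/ASCO/CAP scheme: tier I for evidence levels A/B, tier II for C/D,
tier III for variants of unknown clinical significance, tier IV for
(likely) benign variants.
"""

from __future__ import annotations

from .variants import AnnotatedVariant, EVIDENCE_CODES

__all__ = [
    "ACMG_CLASSES",
    "TIERS",
    "VAF_BINS",
    "acmg_classify",
    "assign_tier",
    "vaf_bin",
    "classify_variant",
]

ACMG_CLASSES = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")
TIERS = ("I", "II", "III", "IV")

#: Abundance bins over the post-filter VAF domain [3, 100] percent:
#: left-closed, right-open, except the last bin which is closed at 100.
VAF_BINS = ("3-5", "5-10", "10-20", "20-50", "50-100")
_BIN_EDGES = (3.0, 5.0, 10.0, 20.0, 50.0, 100.0)


def acmg_classify(evidence_codes) -> str:
    """Combine ACMG/AMP evidence codes into one of the five impact classes.

    Pathogenic requires one of:
      PVS1 with (>=1 PS, or >=2 PM, or 1 PM + 1 PP, or >=2 PP);
      >=2 PS;
      1 PS with (>=3 PM, or 2 PM + >=2 PP, or 1 PM + >=4 PP).
    Likely pathogenic requires one of:
      PVS1 + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM;
      2 PM + >=2 PP; 1 PM + >=4 PP.
    Benign: BA1, or >=2 BS.  Likely benign: 1 BS + 1 BP, or >=2 BP.
    Both sides firing, or neither, yields VUS.
    """
    codes = frozenset(evidence_codes)
    unknown = codes - EVIDENCE_CODES
    if unknown:
        raise ValueError(f"unknown evidence codes: {sorted(unknown)}")

    pvs = "PVS1" in codes
    n_ps = sum(1 for c in codes if c.startswith("PS"))
    n_pm = sum(1 for c in codes if c.startswith("PM"))
    n_pp = sum(1 for c in codes if c.startswith("PP"))
    ba1 = "BA1" in codes
    n_bs = sum(1 for c in codes if c.startswith("BS"))
    n_bp = sum(1 for c in codes if c.startswith("BP"))

    pathogenic = (
        (pvs and (n_ps >= 1 or n_pm >= 2 or (n_pm >= 1 and n_pp >= 1) or n_pp >= 2))
        or n_ps >= 2
        or (
            n_ps == 1
            and (n_pm >= 3 or (n_pm == 2 and n_pp >= 2) or (n_pm == 1 and n_pp >= 4))
        )
    )
    likely_pathogenic = (
        (pvs and n_pm == 1)
        or (n_ps == 1 and 1 <= n_pm <= 2)
        or (n_ps == 1 and n_pp >= 2)
        or n_pm >= 3
        or (n_pm == 2 and n_pp >= 2)
        or (n_pm == 1 and n_pp >= 4)
    )
    benign = ba1 or n_bs >= 2
    likely_benign = (n_bs == 1 and n_bp >= 1) or n_bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "VUS"


def assign_tier(acmg_class: str, clinical_evidence_level: str) -> str:
    """Map impact class and clinical evidence level to an AMP/ASCO/CAP tier."""
    if acmg_class not in ACMG_CLASSES:
        raise ValueError(f"unknown ACMG class {acmg_class!r}")
    if acmg_class in ("benign", "likely_benign"):
        return "IV"
    if clinical_evidence_level in ("A", "B"):
        return "I"
    if clinical_evidence_level in ("C", "D"):
        return "II"
    return "III"


def vaf_bin(vaf_pct: float) -> str:
    """Assign a post-filter VAF (percent) to its abundance bin.

    Bins are [3,5), [5,10), [10,20), [20,50), [50,100]; values outside
    [3, 100] are out of the post-cascade domain and raise ValueError.
    """
    if not (_BIN_EDGES[0] <= vaf_pct <= _BIN_EDGES[-1]):
        raise ValueError(f"VAF {vaf_pct} outside the post-filter domain [3, 100]")
    for label, lo, hi in zip(VAF_BINS, _BIN_EDGES, _BIN_EDGES[1:]):
        if lo <= vaf_pct < hi:
            return label
    return VAF_BINS[-1]  # vaf_pct == 100


def classify_variant(variant: AnnotatedVariant) -> tuple[str, str, str]:
    """Return ``(acmg_class, tier, vaf_bin)`` for one variant."""
    cls = acmg_classify(variant.evidence_codes)
    return cls, assign_tier(cls, variant.clinical_evidence_level), vaf_bin(variant.vaf)
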