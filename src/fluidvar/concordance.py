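"""Matched-fluid set analysis and cohort aggregation.

Two calls made in different body fluids are "the same variant" iff their
normalized ``(chrom, pos, ref, alt)`` keys are equal — annotations, VAF and
quality play no part in identity.  Per patient this yields a Venn structure
(plasma-exclusive / shared / urine-exclusive) and two directional recovery
rates; cohort aggregation adds per-fluid totals, medians, VAF-bin / class /
tier distribution tables, per-gene counts and the pathogenic presence
matrix.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ACMG_CLASSES, TIERS, VAF_BINS, classify_variant
from .variants import AnnotatedVariant

__all__ = [
    "ConcordancePair",
    "CohortSummary",
    "match_pair",
    "recovery_rate",
    "cohort_summarize",
    "pathogenic_matrix",
]

Key = tuple[str, int, str, str]


def recovery_rate(source_set: Iterable[Key], target_set: Iterable[Key]) -> float | None:
    """Percent of source keys present in the target; None for an empty source.

    Undefined (empty-source) recoveries are excluded from cohort medians
    rather than being zero-filled.
    """
    source = set(source_set)
    if not source:
        return None
    return 100.0 * len(source & set(target_set)) / len(source)


@dataclass
class ConcordancePair:
    """One patient's plasma/urine variant-set comparison."""

    patient_id: str
    plasma: dict[Key, AnnotatedVariant]
    urine: dict[Key, AnnotatedVariant]
    plasma_conc: float = 0.0
    urine_conc: float = 0.0
    shared: set[Key] = field(default_factory=set)
    plasma_exclusive: set[Key] = field(default_factory=set)
    urine_exclusive: set[Key] = field(default_factory=set)
    recovery_pu: float | None = None  # plasma variants recovered in urine
    recovery_up: float | None = None  # urine variants recovered in plasma
    pathogenic_recovery_pu: float | None = None
    pathogenic_recovery_up: float | None = None

    def pathogenic_keys(self, fluid: str) -> set[Key]:
        """Keys classified pathogenic in the given source fluid."""
        variants = self.plasma if fluid == "plasma" else self.urine
        return {k for k, v in variants.items() if classify_variant(v)[0] == "pathogenic"}

    def validate(self) -> None:
        p, u = set(self.plasma), set(self.urine)
        assert self.shared == p & u
        assert len(p) == len(self.plasma_exclusive) + len(self.shared)
        assert len(u) == len(self.urine_exclusive) + len(self.shared)
        for r in (self.recovery_pu, self.recovery_up):
            assert r is None or 0.0 <= r <= 100.0


def _index_by_key(variants: Sequence[AnnotatedVariant], label: str) -> dict[Key, AnnotatedVariant]:
    index: dict[Key, AnnotatedVariant] = {}
    for v in variants:
        if v.key in index:
            raise ValueError(f"duplicate normalized key {v.key} in {label} sample")
        index[v.key] = v
    return index


def match_pair(
    plasma_variants: Sequence[AnnotatedVariant],
    urine_variants: Sequence[AnnotatedVariant],
    patient_id: str = "",
    plasma_conc: float = 0.0,
    urine_conc: float = 0.0,
) -> ConcordancePair:
    """Compare a patient's post-cascade plasma and urine variant sets.

    Inputs must be normalized; a duplicate key within one sample is a
    post-normalization collision and raises ValueError.  Pathogenic-only
    recovery uses the pathogenic class in the *source* fluid: a variant
    pathogenic in plasma counts as recovered if its key is present in urine
    regardless of the class assigned to the urine call.
    """
    plasma = _index_by_key(plasma_variants, "plasma")
    urine = _index_by_key(urine_variants, "urine")
    p_keys, u_keys = set(plasma), set(urine)
    pair = ConcordancePair(
        patient_id=patient_id,
        plasma=plasma,
        urine=urine,
        plasma_conc=plasma_conc,
        urine_conc=urine_conc,
        shared=p_keys & u_keys,
        plasma_exclusive=p_keys - u_keys,
        urine_exclusive=u_keys - p_keys,
        recovery_pu=recovery_rate(p_keys, u_keys),
        recovery_up=recovery_rate(u_keys, p_keys),
    )
    pair.pathogenic_recovery_pu = recovery_rate(pair.pathogenic_keys("plasma"), u_keys)
    pair.pathogenic_recovery_up = recovery_rate(pair.pathogenic_keys("urine"), p_keys)
    pair.validate()
    return pair


def _median(values: Sequence[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(statistics.median(vals)) if vals else None


@dataclass
class CohortSummary:
    """Cohort-level aggregation of matched-pair results."""

    per_sample_counts: pd.DataFrame  # patient_id, plasma, urine, shared
    venn: dict[str, int]  # plasma_exclusive, urine_exclusive, shared, totals
    medians: dict[str, float | None]
    recovery: pd.DataFrame  # per patient, both directions, overall + pathogenic
    vaf_bin_table: pd.DataFrame  # bins x fluids
    class_table: pd.DataFrame  # ACMG classes x fluids
    tier_table: pd.DataFrame  # tiers x fluids
    gene_table: pd.DataFrame  # gene, fluid counts, samples altered
    pathogenic_presence: pd.DataFrame

    def validate(self) -> None:
        totals = {
            "plasma": int(self.per_sample_counts["plasma"].sum()),
            "urine": int(self.per_sample_counts["urine"].sum()),
        }
        assert self.venn["plasma_total"] == self.venn["plasma_exclusive"] + self.venn["shared"]
        assert self.venn["urine_total"] == self.venn["urine_exclusive"] + self.venn["shared"]
        assert self.venn["plasma_total"] == totals["plasma"]
        assert self.venn["urine_total"] == totals["urine"]
        assert self.venn["grand_total"] == totals["plasma"] + totals["urine"]
        for table in (self.vaf_bin_table, self.class_table, self.tier_table):
            for fluid, total in totals.items():
                assert int(table[fluid].sum()) == total, f"{fluid} table does not sum"


def _distribution_tables(
    pairs: Sequence[ConcordancePair],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    counts = {
        "vaf": {f: {b: 0 for b in VAF_BINS} for f in ("plasma", "urine")},
        "class": {f: {c: 0 for c in ACMG_CLASSES} for f in ("plasma", "urine")},
        "tier": {f: {t: 0 for t in TIERS} for f in ("plasma", "urine")},
    }
    for pair in pairs:
        for fluid, variants in (("plasma", pair.plasma), ("urine", pair.urine)):
            for v in variants.values():
                cls, tier, vbin = classify_variant(v)
                counts["vaf"][fluid][vbin] += 1
                counts["class"][fluid][cls] += 1
                counts["tier"][fluid][tier] += 1
    vaf = pd.DataFrame(counts["vaf"]).reindex(list(VAF_BINS))
    cls = pd.DataFrame(counts["class"]).reindex(list(ACMG_CLASSES))
    tier = pd.DataFrame(counts["tier"]).reindex(list(TIERS))
    for df in (vaf, cls, tier):
        df.index.name = "category"
    return vaf, cls, tier


def _gene_table(pairs: Sequence[ConcordancePair]) -> pd.DataFrame:
    rows: dict[str, dict[str, object]] = {}
    for pair in pairs:
        for fluid, variants in (("plasma", pair.plasma), ("urine", pair.urine)):
            seen_genes = set()
            for v in variants.values():
                gene = v.gene or "(unannotated)"
                row = rows.setdefault(
                    gene,
                    {
                        "gene": gene,
                        "plasma": 0,
                        "urine": 0,
                        "samples_altered_plasma": 0,
                        "samples_altered_urine": 0,
                    },
                )
                row[fluid] += 1
                if gene not in seen_genes:
                    row[f"samples_altered_{fluid}"] += 1
                    seen_genes.add(gene)
    df = pd.DataFrame(rows.values()) if rows else pd.DataFrame(
        columns=["gene", "plasma", "urine", "samples_altered_plasma", "samples_altered_urine"]
    )
    if len(df):
        df["total"] = df["plasma"] + df["urine"]
        df = df.sort_values(["total", "gene"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def pathogenic_matrix(pairs: Sequence[ConcordancePair]) -> pd.DataFrame:
    """Presence matrix of pathogenic variants across sample x fluid columns.

    Rows are distinct pathogenic variant keys (labelled by gene and
    coordinates); columns ``<patient>_P`` / ``<patient>_U``; cells 0/1.
    Rows are ordered by the number of positive samples, descending, ties by
    label.  A variant enters the matrix if it is classified pathogenic in
    at least one sample; presence in a column means the key was detected in
    that sample regardless of the class assigned there.
    """
    labels: dict[Key, str] = {}
    for pair in pairs:
        for variants in (pair.plasma, pair.urine):
            for key, v in variants.items():
                if key not in labels and classify_variant(v)[0] == "pathogenic":
                    labels[key] = v.label
    columns = [f"{p.patient_id}_{suffix}" for p in pairs for suffix in ("P", "U")]
    data = {}
    for key, label in labels.items():
        row = []
        for pair in pairs:
            row.append(1 if key in pair.plasma else 0)
            row.append(1 if key in pair.urine else 0)
        data[label] = row
    df = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    df.index.name = "variant"
    if len(df):
        order = df.sum(axis=1).sort_values(ascending=False, kind="mergesort")
        df = df.loc[sorted(df.index, key=lambda l: (-order[l], l))]
    return df


def cohort_summarize(pairs: Sequence[ConcordancePair]) -> CohortSummary:
    """Aggregate matched-pair results into the cohort summary.

    Medians use the even-count-average convention; undefined recoveries are
    dropped before taking medians; the gene table is sorted by total count
    descending with ties broken by symbol.
    """
    if not pairs:
        raise ValueError("cohort_summarize requires at least one pair")
    per_sample = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "plasma": [len(p.plasma) for p in pairs],
            "urine": [len(p.urine) for p in pairs],
            "shared": [len(p.shared) for p in pairs],
        }
    )
    venn = {
        "plasma_exclusive": sum(len(p.plasma_exclusive) for p in pairs),
        "urine_exclusive": sum(len(p.urine_exclusive) for p in pairs),
        "shared": sum(len(p.shared) for p in pairs),
    }
    venn["plasma_total"] = venn["plasma_exclusive"] + venn["shared"]
    venn["urine_total"] = venn["urine_exclusive"] + venn["shared"]
    venn["grand_total"] = venn["plasma_total"] + venn["urine_total"]
    recovery = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "recovery_pu": [p.recovery_pu for p in pairs],
            "recovery_up": [p.recovery_up for p in pairs],
            "pathogenic_recovery_pu": [p.pathogenic_recovery_pu for p in pairs],
            "pathogenic_recovery_up": [p.pathogenic_recovery_up for p in pairs],
        }
    )
    medians = {
        "plasma_per_sample": _median(per_sample["plasma"].tolist()),
        "urine_per_sample": _median(per_sample["urine"].tolist()),
        "shared_per_sample": _median(per_sample["shared"].tolist()),
        "recovery_pu": _median([p.recovery_pu for p in pairs]),
        "recovery_up": _median([p.recovery_up for p in pairs]),
        "pathogenic_recovery_pu": _median([p.pathogenic_recovery_pu for p in pairs]),
        "pathogenic_recovery_up": _median([p.pathogenic_recovery_up for p in pairs]),
    }
    vaf, cls, tier = _distribution_tables(pairs)
    summary = CohortSummary(
        per_sample_counts=per_sample,
        venn=venn,
        medians=medians,
        recovery=recovery,
        vaf_bin_table=vaf,
        class_table=cls,
        tier_table=tier,
        gene_table=_gene_table(pairs),
        pathogenic_presence=pathogenic_matrix(pairs),
    )
    summary.validate()
    return summary
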