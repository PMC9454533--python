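"""Synthetic matched plasma/urine cohort generator with planted ground truth.

Emulates the statistical structure of a 15-patient TNBC liquid-biopsy
cohort at the level of *annotated post-calling VCFs*: per-sample
post-filter variant counts with medians near 66 (plasma) and 110 (urine), a
VAF mixture concentrated below 20%, five-class impact proportions dominated
by VUS, a controllable shared-variant fraction between the two fluids,
log-normal cfDNA concentrations with a controllable (weakly negative by
default) rank correlation, and per-filter planted removals whose fates are
recorded as ground truth so cascade recall/precision is testable exactly.

It does not simulate reads, UMIs or sequencing error; annotations
(effects, population frequencies, evidence codes) are drawn directly from
class-conditional recipes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import WindowSet, write_sample_vcf
from .variants import AnnotatedVariant

__all__ = [
    "GENE_PANEL",
    "DEFAULT_GENE_WEIGHTS",
    "SyntheticConfig",
    "SyntheticTruth",
    "CohortPaths",
    "sample_vaf",
    "plant_removals",
    "generate_cohort",
]

_CONTIGS = [str(c) for c in range(1, 23)] + ["X"]

#: 93 breast-cancer-associated gene symbols (panel scale of the study's
#: targeted assay) with synthetic loci: each gene owns a 50 kb slot on its
#: chromosome; variants fall in the first 30 kb, the excluded 100-base
#: window sits at slot offset 40 000.
_GENE_SYMBOLS = [
    "AKT1", "AKT2", "AKT3", "APC", "ARID1A", "ARID1B", "ATM", "ATR", "AURKA",
    "BAP1", "BARD1", "BRCA1", "BRCA2", "BRIP1", "CASP8", "CCND1", "CDH1",
    "CDK4", "CDK6", "CDKN1B", "CDKN2A", "CHEK1", "CHEK2", "CREBBP", "CTCF",
    "EGFR", "EP300", "ERBB2", "ERBB3", "ERBB4", "ESR1", "EZH2", "FANCA",
    "FANCC", "FANCD2", "FGFR1", "FGFR2", "FGFR3", "FGFR4", "FOXA1", "GATA3",
    "HRAS", "IGF1R", "JAK2", "KDM6A", "KIT", "KMT2C", "KMT2D", "KRAS",
    "MAP2K4", "MAP3K1", "MDM2", "MDM4", "MET", "MLH1", "MSH2", "MSH6",
    "MTOR", "MUC16", "MYC", "NBN", "NCOR1", "NF1", "NOTCH1", "NOTCH2",
    "PALB2", "PBRM1", "PDGFRA", "PIK3CA", "PIK3R1", "PMS2", "PTEN", "RAD50",
    "RAD51", "RAD51C", "RAD51D", "RB1", "RET", "RUNX1", "SETD2", "SF3B1",
    "SMAD4", "SMARCA4", "STK11", "SYNE1", "TBX3", "TP53", "TSC1", "TSC2",
    "VHL", "XRCC2", "ZNF217", "CDKN2B",
]
assert len(_GENE_SYMBOLS) == 93

_SLOT = 50_000
_VARIANT_SPAN = 30_000
_WINDOW_OFFSET = 40_000
_WINDOW_LEN = 100

#: gene -> (chrom, slot start); deterministic layout.
GENE_PANEL: dict[str, tuple[str, int]] = {
    gene: (_CONTIGS[i % len(_CONTIGS)], 1_000_000 + (i // len(_CONTIGS)) * _SLOT)
    for i, gene in enumerate(_GENE_SYMBOLS)
}

#: Giant genes carry more variants simply because they offer more residues;
#: a MUC16-like size bias is modelled as elevated sampling weights.
DEFAULT_GENE_WEIGHTS: dict[str, float] = {"MUC16": 12.0, "SYNE1": 6.0, "KMT2C": 5.0, "NF1": 4.0}

_VAF_EDGES = (3.0, 5.0, 10.0, 20.0, 50.0, 100.0)

#: Evidence-code recipes that deterministically yield each impact class
#: under the 2015 combining rules.
_EVIDENCE_RECIPES: dict[str, list[frozenset[str]]] = {
    "pathogenic": [
        frozenset({"PVS1", "PS1"}),
        frozenset({"PS1", "PS2"}),
        frozenset({"PVS1", "PM1", "PM2"}),
    ],
    "likely_pathogenic": [
        frozenset({"PVS1", "PM1"}),
        frozenset({"PS1", "PM1"}),
        frozenset({"PM1", "PM2", "PM3"}),
        frozenset({"PS1", "PP1", "PP2"}),
    ],
    "VUS": [frozenset(), frozenset({"PP1"}), frozenset({"PM1"}), frozenset({"PS1"})],
    "likely_benign": [frozenset({"BS1", "BP1"}), frozenset({"BP1", "BP2"})],
    "benign": [frozenset({"BA1"}), frozenset({"BS1", "BS2"})],
}

#: P(clinical evidence level | impact class); tier I must stay rare.
_LEVEL_PROBS: dict[str, tuple[tuple[str, float], ...]] = {
    "pathogenic": (("A", 0.02), ("B", 0.02), ("C", 0.40), ("D", 0.25), ("none", 0.31)),
    "likely_pathogenic": (("A", 0.02), ("B", 0.02), ("C", 0.40), ("D", 0.25), ("none", 0.31)),
    "VUS": (("C", 0.004), ("D", 0.004), ("none", 0.992)),
    "likely_benign": (("none", 1.0),),
    "benign": (("none", 1.0),),
}

_EFFECT_PROBS: tuple[tuple[str, float], ...] = (
    ("missense", 0.62),
    ("frameshift", 0.08),
    ("synonymous", 0.08),
    ("splice_region", 0.07),
    ("stop_change", 0.05),
    ("intronic", 0.05),
    ("inframe_indel", 0.04),
    ("start_loss", 0.01),
)

REMOVAL_REASONS = (
    "low_quality",
    "low_vaf",
    "excluded_window",
    "common_population",
    "deep_intronic",
    "not_deleterious",
)


class SyntheticConfig(BaseModel):
    """Study conditions of the emulated cohort.

    Defaults reproduce the reference cohort's structure: per-sample
    post-filter count medians 66/110, shared fraction 431/1222 ~ 0.35, VAF
    bin masses from the printed pooled bin counts, class proportions from
    the printed pooled class counts, concentration medians 172/196 ng/mL
    with a weak negative rank correlation and a 2/15 urine non-detect rate.
    """

    n_patients: int = Field(default=15, ge=0)
    seed: int  # mandatory; every stream derives from it
    plasma_median_count: float = Field(default=66.0, gt=0)
    urine_median_count: float = Field(default=110.0, gt=0)
    plasma_count_sigma: float = Field(default=0.45, ge=0)
    urine_count_sigma: float = Field(default=0.50, ge=0)
    shared_fraction: float = Field(default=431.0 / 1222.0, ge=0, le=1)
    vaf_bin_masses: tuple[float, float, float, float, float] = (
        1226 / 3339,
        1061 / 3339,
        633 / 3339,
        346 / 3339,
        73 / 3339,
    )
    class_proportions: dict[str, float] = {
        "pathogenic": 148 / 3339,
        "likely_pathogenic": 302 / 3339,
        "VUS": 2841 / 3339,
        "likely_benign": 37 / 3339,
        "benign": 11 / 3339,
    }
    #: expected planted removals per surviving variant, by reason
    removal_rates: dict[str, float] = {
        "low_quality": 0.20,
        "low_vaf": 0.40,
        "excluded_window": 0.05,
        "common_population": 0.25,
        "deep_intronic": 0.05,
        "not_deleterious": 0.05,
    }
    #: recurrent pathogenic hotspot variants (per-patient presence
    #: probability in both fluids); model for "found in all 30 samples"
    hotspot_presence: tuple[float, ...] = (1.0, 0.8)
    plasma_conc_median: float = Field(default=172.0, gt=0)
    urine_conc_median: float = Field(default=196.0, gt=0)
    plasma_conc_sigma: float = Field(default=0.8, ge=0)
    urine_conc_sigma: float = Field(default=1.3, ge=0)
    #: Gaussian-copula correlation between the fluids' concentrations
    conc_correlation: float = Field(default=-0.2, ge=-1, le=1)
    urine_nondetect_prob: float = Field(default=2.0 / 15.0, ge=0, le=1)
    gene_weights: dict[str, float] | None = None

    @field_validator("vaf_bin_masses")
    @classmethod
    def _masses_normalized(cls, v):
        if any(m < 0 for m in v) or not math.isclose(sum(v), 1.0, abs_tol=1e-6):
            raise ValueError("vaf_bin_masses must be non-negative and sum to 1")
        return v

    @field_validator("class_proportions")
    @classmethod
    def _props_normalized(cls, v):
        if any(p < 0 for p in v.values()) or not math.isclose(sum(v.values()), 1.0, abs_tol=1e-6):
            raise ValueError("class_proportions must be non-negative and sum to 1")
        if set(v) != set(_EVIDENCE_RECIPES):
            raise ValueError(f"class_proportions keys must be {sorted(_EVIDENCE_RECIPES)}")
        return v

    @field_validator("removal_rates")
    @classmethod
    def _rates_valid(cls, v):
        unknown = set(v) - set(REMOVAL_REASONS)
        if unknown:
            raise ValueError(f"unknown removal reasons: {sorted(unknown)}")
        if any(r < 0 for r in v.values()):
            raise ValueError("removal rates must be >= 0")
        return v

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        import json

        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class SyntheticTruth:
    """Ground truth for every emitted record plus true concentrations."""

    records: pd.DataFrame  # patient_id, fluid, key fields, fate, reason, ...
    concentrations: dict[str, tuple[float, float]]
    config: SyntheticConfig

    def planted_fate(self, patient_id: str, fluid: str, key) -> tuple[str, str]:
        df = self.records
        chrom, pos, ref, alt = key
        hit = df[
            (df.patient_id == patient_id)
            & (df.fluid == fluid)
            & (df.chrom == chrom)
            & (df.pos == pos)
            & (df.ref == ref)
            & (df.alt == alt)
        ]
        if len(hit) != 1:
            raise KeyError(f"truth has {len(hit)} rows for {patient_id}/{fluid}/{key}")
        row = hit.iloc[0]
        return row.fate, row.reason

    def save(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CohortPaths:
    outdir: Path
    manifest: Path
    concentrations: Path
    windows_bed: Path
    truth: Path
    sample_vcfs: dict[tuple[str, str], Path]  # (patient_id, fluid) -> path


def _weighted_choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    p = np.asarray(probs, dtype=float)
    return items[int(rng.choice(len(items), p=p / p.sum()))]


def sample_vaf(config: SyntheticConfig, rng: np.random.Generator) -> float:
    """Draw a VAF percent from the configured bin mixture.

    The bin is drawn by its configured mass, then the value uniformly
    within the bin; results lie in [3, 100].
    """
    i = int(rng.choice(5, p=np.asarray(config.vaf_bin_masses)))
    lo, hi = _VAF_EDGES[i], _VAF_EDGES[i + 1]
    return float(rng.uniform(lo, hi))


def _panel_windows() -> WindowSet:
    return WindowSet.from_intervals(
        (chrom, start + _WINDOW_OFFSET, start + _WINDOW_OFFSET + _WINDOW_LEN)
        for chrom, start in GENE_PANEL.values()
    )


_BASES = "ACGT"


def _draw_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    if not indel:
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(3))]
        if alt == ref:
            alt = _BASES[3]
        return ref, alt
    anchor = _BASES[int(rng.integers(4))]
    tail = "".join(_BASES[int(rng.integers(4))] for _ in range(int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return anchor, anchor + tail  # insertion
    return anchor + tail, anchor  # deletion


def _draw_key(
    rng: np.random.Generator,
    config: SyntheticConfig,
    used: set,
    gene: str | None = None,
    in_window: bool = False,
    indel: bool = False,
) -> tuple[str, int, str, str, str]:
    """Draw an unused (chrom, pos, ref, alt) key plus its gene symbol."""
    genes = list(GENE_PANEL)
    weights = dict.fromkeys(genes, 1.0)
    weights.update(DEFAULT_GENE_WEIGHTS if config.gene_weights is None else config.gene_weights)
    probs = [weights[g] for g in genes]
    for _ in range(200):
        g = gene or _weighted_choice(rng, genes, probs)
        chrom, slot = GENE_PANEL[g]
        if in_window:
            pos = int(rng.integers(slot + _WINDOW_OFFSET + 1, slot + _WINDOW_OFFSET + _WINDOW_LEN + 1))
        else:
            pos = int(rng.integers(slot + 1, slot + _VARIANT_SPAN))
        ref, alt = _draw_alleles(rng, indel)
        if (chrom, pos, ref, alt) not in used:
            used.add((chrom, pos, ref, alt))
            return chrom, pos, ref, alt, g
    raise RuntimeError("could not draw a fresh variant key (panel exhausted?)")


def _survivor_annotations(rng: np.random.Generator, config: SyntheticConfig) -> dict:
    """Class, evidence, effect, offset and flags for a cascade survivor."""
    classes = list(config.class_proportions)
    cls = _weighted_choice(rng, classes, [config.class_proportions[c] for c in classes])
    recipes = _EVIDENCE_RECIPES[cls]
    evidence = recipes[int(rng.integers(len(recipes)))]
    levels, lv_probs = zip(*_LEVEL_PROBS[cls])
    level = _weighted_choice(rng, list(levels), list(lv_probs))
    if cls in ("benign", "likely_benign"):
        # must still pass the deleterious filter: retained consequence class
        effect, offset = "missense", 0
    else:
        effect = _weighted_choice(rng, [e for e, _ in _EFFECT_PROBS], [p for _, p in _EFFECT_PROBS])
        if effect == "splice_region":
            offset = int(rng.choice([-2, -1, 1, 2]))
        elif effect == "intronic":
            offset = int(rng.choice([-1, 1])) * int(rng.integers(3, 21))
        else:
            offset = 0
    if rng.random() < 0.01:
        pop_af, estpath = float(rng.uniform(0.011, 0.3)), True  # rescued common variant
    elif rng.random() < 0.3:
        pop_af, estpath = float(rng.uniform(0.0, 0.01)), False
    else:
        pop_af, estpath = None, False
    return {
        "class_label": cls,
        "evidence_codes": evidence,
        "clinical_evidence_level": level,
        "effect": effect,
        "intron_offset": offset,
        "pop_af": pop_af,
        "established_pathogenic": estpath,
        "splice_pred_flag": effect == "intronic" and bool(rng.random() < 0.5),
        "gof_flag": bool(rng.random() < 0.02),
        "lof_flag": bool(rng.random() < 0.05),
    }


def _make_variant(
    key: tuple[str, int, str, str],
    gene: str,
    ann: dict,
    rng: np.random.Generator,
    config: SyntheticConfig,
    sample_id: str,
    fluid: str,
    vaf: float | None = None,
    quality: float | None = None,
) -> AnnotatedVariant:
    chrom, pos, ref, alt = key
    depth_median = 200.0 if fluid == "plasma" else 70.0
    depth = max(10, int(round(float(rng.lognormal(math.log(depth_median), 0.5)))))
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        call_quality=quality if quality is not None else float(rng.uniform(50.0, 99.0)),
        vaf=vaf if vaf is not None else sample_vaf(config, rng),
        depth=depth,
        pop_af=ann["pop_af"],
        effect=ann["effect"],
        intron_offset=ann["intron_offset"],
        splice_pred_flag=ann["splice_pred_flag"],
        gof_flag=ann["gof_flag"],
        lof_flag=ann["lof_flag"],
        evidence_codes=ann["evidence_codes"],
        clinical_evidence_level=ann["clinical_evidence_level"],
        established_pathogenic=ann["established_pathogenic"],
        sample_id=sample_id,
        fluid=fluid,
    )


def plant_removals(
    n_survivors: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    used: set,
    sample_id: str,
    fluid: str,
    windows: WindowSet | None,
) -> list[tuple[AnnotatedVariant, str]]:
    """Generate planted-removal records for one sample.

    Each plant violates exactly its intended criterion and satisfies every
    other filter clause, so the cascade must remove it at exactly the
    intended stage for exactly the intended reason.  Counts per reason are
    Poisson with mean ``rate x n_survivors``.
    """
    out: list[tuple[AnnotatedVariant, str]] = []
    for reason in REMOVAL_REASONS:
        rate = config.removal_rates.get(reason, 0.0)
        n = int(rng.poisson(rate * n_survivors))
        if n > 0 and reason == "excluded_window" and (windows is None or len(windows) == 0):
            raise ValueError("cannot plant windowed removals with an empty WindowSet")
        for _ in range(n):
            chrom, pos, ref, alt, gene = _draw_key(
                rng, config, used, in_window=(reason == "excluded_window")
            )
            # clean baseline: VUS class, retained effect, rare, high quality
            ann = {
                "class_label": "VUS",
                "evidence_codes": frozenset(),
                "clinical_evidence_level": "none",
                "effect": "missense",
                "intron_offset": 0,
                "pop_af": None,
                "established_pathogenic": False,
                "splice_pred_flag": False,
                "gof_flag": False,
                "lof_flag": False,
            }
            vaf = None
            quality = None
            if reason == "low_quality":
                quality = float(rng.uniform(10.0, 49.5))
            elif reason == "low_vaf":
                vaf = float(rng.uniform(0.2, 2.9))
            elif reason == "common_population":
                ann["pop_af"] = float(rng.uniform(0.0101, 0.5))
            elif reason == "deep_intronic":
                ann["effect"] = "intronic"
                ann["intron_offset"] = int(rng.choice([-1, 1])) * int(rng.integers(21, 200))
            elif reason == "not_deleterious":
                ann["class_label"] = "benign"
                ann["evidence_codes"] = frozenset({"BA1"})
                ann["effect"] = "synonymous"
            v = _make_variant(
                (chrom, pos, ref, alt), gene, ann, rng, config, sample_id, fluid, vaf, quality
            )
            out.append((v, reason))
    return out


_REASON_STAGE = {
    "low_quality": "confidence",
    "low_vaf": "confidence",
    "excluded_window": "confidence",
    "common_population": "common",
    "deep_intronic": "deleterious",
    "not_deleterious": "deleterious",
}


def _truth_row(v: AnnotatedVariant, fate: str, reason: str, shared_status: str, hotspot: bool) -> dict:
    return {
        "patient_id": v.sample_id,
        "fluid": v.fluid,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "fate": fate,
        "stage": _REASON_STAGE.get(reason, ""),
        "reason": reason,
        "class_label": "",
        "shared_status": shared_status,
        "hotspot": hotspot,
    }


def _count_draw(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(float(rng.lognormal(math.log(median), sigma)))))


def generate_cohort(config: SyntheticConfig, outdir: str | Path) -> tuple[CohortPaths, SyntheticTruth]:
    """Write a full synthetic cohort to ``outdir`` and return its truth.

    Emits, per patient, one plasma and one urine VCF with the pipeline's
    custom tag set, plus a shared exclusion-window BED, a concentrations
    CSV, a manifest TSV and a truth TSV.  Output is byte-identical for
    identical ``config`` (the seed lives in the config); per-patient
    substreams derive from ``(seed, patient index)`` so a patient's data is
    stable under changes of the cohort size.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = _panel_windows()

    # cohort-level stream: hotspot identities
    rng_cohort = np.random.default_rng([config.seed, 1_048_576])
    hotspots = []
    used_global: set = set()
    for j, presence in enumerate(config.hotspot_presence):
        chrom, pos, ref, alt, gene = _draw_key(rng_cohort, config, used_global)
        ann = {
            "class_label": "pathogenic",
            "evidence_codes": frozenset({"PVS1", "PS1"}),
            "clinical_evidence_level": "C",
            "effect": "missense",
            "intron_offset": 0,
            "pop_af": None,
            "established_pathogenic": True,
            "splice_pred_flag": False,
            "gof_flag": False,
            "lof_flag": True,
        }
        hotspots.append(((chrom, pos, ref, alt), gene, ann, presence))

    truth_rows: list[dict] = []
    concentrations: dict[str, tuple[float, float]] = {}
    sample_vcfs: dict[tuple[str, str], Path] = {}
    manifest_lines = ["patient_id\tplasma_vcf\turine_vcf"]

    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng([config.seed, i])

        # concentrations: log-normal margins tied by a Gaussian copula
        z1 = float(rng.standard_normal())
        e = float(rng.standard_normal())
        rho = config.conc_correlation
        z2 = rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * e
        plasma_conc = float(np.exp(math.log(config.plasma_conc_median) + config.plasma_conc_sigma * z1))
        urine_conc = float(np.exp(math.log(config.urine_conc_median) + config.urine_conc_sigma * z2))
        if rng.random() < config.urine_nondetect_prob:
            urine_conc = 0.0
        concentrations[pid] = (round(plasma_conc, 2), round(urine_conc, 2))

        n_plasma = _count_draw(rng, config.plasma_median_count, config.plasma_count_sigma)
        n_urine = _count_draw(rng, config.urine_median_count, config.urine_count_sigma)
        n_shared = min(int(rng.binomial(n_plasma, config.shared_fraction)), n_urine)

        used: set = set(k for k, *_ in hotspots)
        plasma_vars: list[AnnotatedVariant] = []
        urine_vars: list[AnnotatedVariant] = []

        def add_survivor(key, gene, ann, shared_status, hotspot=False):
            for fluid, bucket in (("plasma", plasma_vars), ("urine", urine_vars)):
                if shared_status == "plasma_only" and fluid == "urine":
                    continue
                if shared_status == "urine_only" and fluid == "plasma":
                    continue
                v = _make_variant(key, gene, ann, rng, config, pid, fluid)
                bucket.append(v)
                row = _truth_row(v, "survive", "", shared_status, hotspot)
                row["class_label"] = ann["class_label"]
                truth_rows.append(row)

        for key, gene, ann, presence in hotspots:
            if rng.random() < presence:
                add_survivor(key, gene, ann, "shared", hotspot=True)

        for _ in range(n_shared):
            chrom, pos, ref, alt, gene = _draw_key(rng, config, used)
            add_survivor((chrom, pos, ref, alt), gene, _survivor_annotations(rng, config), "shared")
        for _ in range(n_plasma - n_shared):
            chrom, pos, ref, alt, gene = _draw_key(rng, config, used)
            add_survivor((chrom, pos, ref, alt), gene, _survivor_annotations(rng, config), "plasma_only")
        for _ in range(n_urine - n_shared):
            chrom, pos, ref, alt, gene = _draw_key(rng, config, used)
            add_survivor((chrom, pos, ref, alt), gene, _survivor_annotations(rng, config), "urine_only")

        for fluid, bucket, n_surv in (
            ("plasma", plasma_vars, n_plasma),
            ("urine", urine_vars, n_urine),
        ):
            for v, reason in plant_removals(n_surv, config, rng, used, pid, fluid, windows):
                bucket.append(v)
                truth_rows.append(_truth_row(v, "removed", reason, "", False))

        for fluid, bucket in (("plasma", plasma_vars), ("urine", urine_vars)):
            path = outdir / f"{pid}_{fluid}.vcf"
            write_sample_vcf(path, bucket, f"{pid}_{fluid}")
            sample_vcfs[(pid, fluid)] = path
        manifest_lines.append(f"{pid}\t{pid}_plasma.vcf\t{pid}_urine.vcf")

    # shared files
    bed_path = outdir / "excluded_windows.bed"
    bed_lines = [
        f"{chrom}\t{start + _WINDOW_OFFSET}\t{start + _WINDOW_OFFSET + _WINDOW_LEN}"
        for gene, (chrom, start) in sorted(GENE_PANEL.items())
    ]
    bed_path.write_text("\n".join(bed_lines) + "\n")

    conc_path = outdir / "concentrations.csv"
    conc_lines = ["patient_id,plasma_ng_ml,urine_ng_ml"]
    conc_lines += [f"{pid},{p:.2f},{u:.2f}" for pid, (p, u) in concentrations.items()]
    conc_path.write_text("\n".join(conc_lines) + "\n")

    manifest_path = outdir / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")

    truth_cols = [
        "patient_id", "fluid", "chrom", "pos", "ref", "alt", "gene",
        "fate", "stage", "reason", "class_label", "shared_status", "hotspot",
    ]
    truth_df = pd.DataFrame(truth_rows, columns=truth_cols)
    truth = SyntheticTruth(records=truth_df, concentrations=concentrations, config=config)
    truth_path = outdir / "truth.tsv"
    truth.save(truth_path)

    paths = CohortPaths(
        outdir=outdir,
        manifest=manifest_path,
        concentrations=conc_path,
        windows_bed=bed_path,
        truth=truth_path,
        sample_vcfs=sample_vcfs,
    )
    return paths, truth
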