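"""The sequential three-stage somatic-variant filter cascade.

Stage 1 (confidence) removes low-quality calls (site quality below 50),
low-support calls (VAF below 3%) and calls inside the excluded
"exonically variable" windows.  Stage 2 (common variants) removes variants
seen at more than 1% in the normal population unless they are established
pathogenic variants.  Stage 3 (predicted deleterious) keeps variants no
deeper than 20 bases into an intron that are plausibly function-altering:
classified pathogenic / likely pathogenic / VUS, gain- or
loss-of-function-associated, of a damaging consequence class, near-exonic
splice-site loss (within 2 intronic bases), or flagged by an external
splice predictor.

All thresholds are inclusive on the keep side (quality >= 50 kept,
VAF >= 3% kept, pop_af <= 1% kept, |offset| <= 20 kept).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .classify import acmg_classify
from .io import WindowSet, window_contains
from .variants import AnnotatedVariant

__all__ = [
    "FilterConfig",
    "StageReport",
    "CascadeReport",
    "confidence_filter",
    "common_filter",
    "deleterious_filter",
    "run_cascade",
    "REMOVAL_REASONS",
]

STAGES = ("confidence", "common", "deleterious")

#: Removal reasons, in attribution order within each stage.
REMOVAL_REASONS = {
    "confidence": ("low_quality", "low_vaf", "excluded_window"),
    "common": ("common_population",),
    "deleterious": ("deep_intronic", "not_deleterious"),
}

#: Consequence classes that satisfy the loss-of-function retention clause.
LOF_EFFECTS = frozenset(
    {"frameshift", "inframe_indel", "start_loss", "stop_change", "missense", "copy_number_loss"}
)


class FilterConfig(BaseModel):
    """Thresholds of the three-stage cascade (keep-side inclusive)."""

    min_call_quality: float = Field(default=50.0, ge=0)
    min_vaf_pct: float = Field(default=3.0, ge=0, le=100)
    max_pop_af: float = Field(default=0.01, ge=0)
    max_intron_offset: int = Field(default=20, ge=0)
    splice_loss_offset: int = Field(default=2, ge=0)

    @classmethod
    def from_json(cls, path) -> "FilterConfig":
        import json
        from pathlib import Path

        return cls.model_validate(json.loads(Path(path).read_text()))

    @model_validator(mode="after")
    def _check(self) -> "FilterConfig":
        return self


@dataclass
class StageReport:
    stage: str
    n_in: int = 0
    n_removed: int = 0
    n_out: int = 0
    reasons: Counter = field(default_factory=Counter)


@dataclass
class CascadeReport:
    """Per-stage attrition counts for one sample."""

    sample_id: str = ""
    fluid: str = ""
    stages: list[StageReport] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_surviving(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def validate(self) -> None:
        for a, b in zip(self.stages, self.stages[1:]):
            if a.n_out != b.n_in:
                raise AssertionError(f"stage chaining broken: {a.stage} -> {b.stage}")
        for s in self.stages:
            if s.n_in != s.n_removed + s.n_out or min(s.n_in, s.n_removed, s.n_out) < 0:
                raise AssertionError(f"inconsistent counts in stage {s.stage}")
            if sum(s.reasons.values()) != s.n_removed:
                raise AssertionError(f"reason counts do not sum in stage {s.stage}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            row = {
                "sample_id": self.sample_id,
                "fluid": self.fluid,
                "stage": s.stage,
                "n_in": s.n_in,
                "n_removed": s.n_removed,
                "n_out": s.n_out,
            }
            for reason in REMOVAL_REASONS[s.stage]:
                row[reason] = s.reasons.get(reason, 0)
            rows.append(row)
        return pd.DataFrame(rows)


Removal = tuple[AnnotatedVariant, str]


def confidence_filter(
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig,
    windows: WindowSet | None = None,
) -> tuple[list[AnnotatedVariant], list[Removal]]:
    """Keep calls with quality >= threshold, VAF >= threshold, outside windows.

    Each removal is attributed to its first failing criterion in the order
    quality, VAF, window.
    """
    windows = windows or WindowSet()
    kept: list[AnnotatedVariant] = []
    removed: list[Removal] = []
    for v in variants:
        if v.call_quality < config.min_call_quality:
            removed.append((v, "low_quality"))
        elif v.vaf < config.min_vaf_pct:
            removed.append((v, "low_vaf"))
        elif window_contains(windows, v.chrom, v.pos):
            removed.append((v, "excluded_window"))
        else:
            kept.append(v)
    return kept, removed


def common_filter(
    variants: Iterable[AnnotatedVariant], config: FilterConfig
) -> tuple[list[AnnotatedVariant], list[Removal]]:
    """Remove population-common variants unless established pathogenic.

    A missing population allele frequency is treated as 0: absence from
    the population databases is itself evidence of rarity.
    """
    kept: list[AnnotatedVariant] = []
    removed: list[Removal] = []
    for v in variants:
        pop_af = v.pop_af if v.pop_af is not None else 0.0
        if pop_af <= config.max_pop_af or v.established_pathogenic:
            kept.append(v)
        else:
            removed.append((v, "common_population"))
    return kept, removed


def deleterious_filter(
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig,
    classifier: Callable[[AnnotatedVariant], str] | None = None,
) -> tuple[list[AnnotatedVariant], list[Removal]]:
    """Keep near-exonic variants that are plausibly function-altering.

    ``classifier`` maps a variant to its ACMG class; by default the
    package's own evidence-code combiner is used (the same engine that
    produces the reported class distributions).
    """
    classify = classifier or (lambda v: acmg_classify(v.evidence_codes))
    kept: list[AnnotatedVariant] = []
    removed: list[Removal] = []
    for v in variants:
        if abs(v.intron_offset) > config.max_intron_offset:
            removed.append((v, "deep_intronic"))
            continue
        deleterious = (
            classify(v) in ("pathogenic", "likely_pathogenic", "VUS")
            or v.gof_flag
            or v.lof_flag
            or v.effect in LOF_EFFECTS
            or (v.effect == "splice_region" and abs(v.intron_offset) <= config.splice_loss_offset)
            or v.splice_pred_flag
        )
        if deleterious:
            kept.append(v)
        else:
            removed.append((v, "not_deleterious"))
    return kept, removed


def run_cascade(
    sample_variants: Sequence[AnnotatedVariant],
    config: FilterConfig | None = None,
    windows: WindowSet | None = None,
    classifier: Callable[[AnnotatedVariant], str] | None = None,
    sample_id: str = "",
    fluid: str = "",
) -> tuple[list[AnnotatedVariant], CascadeReport]:
    """Apply confidence -> common -> predicted-deleterious in sequence."""
    config = config or FilterConfig()
    report = CascadeReport(sample_id=sample_id, fluid=fluid)
    current = list(sample_variants)
    for stage, fn in (
        ("confidence", lambda vs: confidence_filter(vs, config, windows)),
        ("common", lambda vs: common_filter(vs, config)),
        ("deleterious", lambda vs: deleterious_filter(vs, config, classifier)),
    ):
        kept, removed = fn(current)
        report.stages.append(
            StageReport(
                stage=stage,
                n_in=len(current),
                n_removed=len(removed),
                n_out=len(kept),
                reasons=Counter(reason for _, reason in removed),
            )
        )
        current = kept
    report.validate()
    return current, report
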