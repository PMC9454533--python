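"""End-to-end cohort analysis as a model/results pair.

:class:`MatchedFluidCohort` is built from a cohort of matched plasma/urine
samples (manifest + concentrations + exclusion windows + thresholds); its
:meth:`~MatchedFluidCohort.fit` runs ingest -> filter cascade ->
classification -> matched-pair concordance -> cohort statistics and returns
a :class:`CohortResults` carrying per-sample cascade reports, per-patient
concordance pairs, the cohort summary tables and the statistical tests,
with ``summary()`` and ``save()`` for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel

from . import io as fio
from .classify import classify_variant
from .concordance import CohortSummary, ConcordancePair, cohort_summarize, match_pair
from .filters import CascadeReport, FilterConfig, run_cascade
from .io import TagConfig, WindowSet
from .stats import TestResult, chi_square_independence, median_range, spearman_rho, wilcoxon_signed_rank
from .variants import PatientPair

__all__ = ["MatchedFluidCohort", "CohortResults", "RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Paths and options of one end-to-end run."""

    manifest: str
    concentrations: str | None = None
    windows_bed: str | None = None
    filter_config: FilterConfig = FilterConfig()
    tag_config: TagConfig = TagConfig()
    outdir: str = "fluidvar_out"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


class MatchedFluidCohort:
    """A matched plasma/urine ctDNA cohort ready to be analysed."""

    def __init__(
        self,
        pairs: Sequence[PatientPair],
        windows: WindowSet | None = None,
        filter_config: FilterConfig | None = None,
        tag_config: TagConfig | None = None,
    ) -> None:
        if not pairs:
            raise ValueError("cohort must contain at least one patient pair")
        self.pairs = list(pairs)
        self.windows = windows or WindowSet()
        self.filter_config = filter_config or FilterConfig()
        self.tag_config = tag_config or TagConfig()

    @classmethod
    def from_paths(
        cls,
        manifest: str | Path,
        concentrations: str | Path | None = None,
        windows_bed: str | Path | None = None,
        filter_config: FilterConfig | None = None,
        tag_config: TagConfig | None = None,
    ) -> "MatchedFluidCohort":
        conc = fio.read_concentrations(concentrations) if concentrations else {}
        pairs = fio.read_manifest(manifest, conc)
        windows = fio.read_window_bed(windows_bed) if windows_bed else None
        return cls(pairs, windows, filter_config, tag_config)

    def fit(self) -> "CohortResults":
        """Run the full analysis and return the results object."""
        reports: list[CascadeReport] = []
        conc_pairs: list[ConcordancePair] = []
        survivors: dict[tuple[str, str], list] = {}
        for pair in self.pairs:
            per_fluid = {}
            for fluid, path in (("plasma", pair.plasma_vcf), ("urine", pair.urine_vcf)):
                try:
                    variants = fio.read_sample_vcf(
                        path, self.tag_config, sample_id=pair.patient_id, fluid=fluid
                    )
                except OSError as exc:
                    raise RuntimeError(
                        f"ingest stage failed for patient {pair.patient_id} ({fluid}): {exc}"
                    ) from exc
                kept, report = run_cascade(
                    variants,
                    self.filter_config,
                    self.windows,
                    sample_id=pair.patient_id,
                    fluid=fluid,
                )
                per_fluid[fluid] = kept
                reports.append(report)
                survivors[(pair.patient_id, fluid)] = kept
            conc_pairs.append(
                match_pair(
                    per_fluid["plasma"],
                    per_fluid["urine"],
                    patient_id=pair.patient_id,
                    plasma_conc=pair.plasma_conc,
                    urine_conc=pair.urine_conc,
                )
            )
        summary = cohort_summarize(conc_pairs)

        plasma_conc = [p.plasma_conc for p in self.pairs]
        urine_conc = [p.urine_conc for p in self.pairs]
        have_conc = any(plasma_conc) or any(urine_conc)
        conc_spearman = conc_wilcoxon = None
        if have_conc and len(self.pairs) >= 3:
            try:
                conc_spearman = spearman_rho(plasma_conc, urine_conc)
            except ValueError:
                conc_spearman = None
            try:
                conc_wilcoxon = wilcoxon_signed_rank(plasma_conc, urine_conc)
            except ValueError:
                conc_wilcoxon = None

        # class distribution plasma vs urine; all-zero classes carry no
        # information about the association and are dropped from the table
        cls_table = summary.class_table.T  # fluids x classes
        nonzero = cls_table.loc[:, cls_table.sum(axis=0) > 0]
        class_chi2 = None
        if nonzero.shape[1] >= 2 and (nonzero.sum(axis=1) > 0).all():
            class_chi2 = chi_square_independence(nonzero.to_numpy())

        return CohortResults(
            model=self,
            cascade_reports=reports,
            pairs=conc_pairs,
            summary_tables=summary,
            conc_spearman=conc_spearman,
            conc_wilcoxon=conc_wilcoxon,
            class_chi2=class_chi2,
            survivors=survivors,
        )


@dataclass
class CohortResults:
    """Results of a fitted matched-fluid cohort analysis."""

    model: MatchedFluidCohort
    cascade_reports: list[CascadeReport]
    pairs: list[ConcordancePair]
    summary_tables: CohortSummary
    conc_spearman: TestResult | None
    conc_wilcoxon: TestResult | None
    class_chi2: TestResult | None
    survivors: dict

    # -- headline numbers ------------------------------------------------
    def summary_dict(self) -> dict:
        """Headline numbers (unrounded) as a JSON-serializable dict."""
        s = self.summary_tables
        plasma_conc = [p.plasma_conc for p in self.model.pairs]
        urine_conc = [p.urine_conc for p in self.model.pairs]
        out = {
            "n_patients": len(self.pairs),
            "venn": dict(s.venn),
            "medians": {k: v for k, v in s.medians.items()},
            "per_fluid_totals": {
                "plasma": s.venn["plasma_total"],
                "urine": s.venn["urine_total"],
            },
            "concentrations": {
                "plasma_median_min_max": median_range(plasma_conc) if plasma_conc else None,
                "urine_median_min_max": median_range(urine_conc) if urine_conc else None,
            },
            "tests": {
                "conc_spearman": _test_dict(self.conc_spearman),
                "conc_wilcoxon": _test_dict(self.conc_wilcoxon),
                "class_chi2": _test_dict(self.class_chi2),
            },
            "vaf_bins": {
                f: {k: int(n) for k, n in s.vaf_bin_table[f].items()} for f in ("plasma", "urine")
            },
            "classes": {
                f: {k: int(n) for k, n in s.class_table[f].items()} for f in ("plasma", "urine")
            },
            "tiers": {
                f: {k: int(n) for k, n in s.tier_table[f].items()} for f in ("plasma", "urine")
            },
        }
        return out

    def summary(self) -> str:
        """Human-readable report (percent values to one decimal)."""
        s = self.summary_tables
        lines = ["Matched-fluid ctDNA cohort analysis", "=" * 36]
        lines.append(f"patients: {len(self.pairs)}")
        v = s.venn
        lines.append(
            f"variants: plasma {v['plasma_total']} = {v['plasma_exclusive']} exclusive + "
            f"{v['shared']} shared; urine {v['urine_total']} = {v['urine_exclusive']} "
            f"exclusive + {v['shared']} shared; grand total {v['grand_total']}"
        )
        med = s.medians
        lines.append(
            f"per-sample medians: plasma {med['plasma_per_sample']:.1f}, "
            f"urine {med['urine_per_sample']:.1f}, shared {med['shared_per_sample']:.1f}"
        )

        def fmt(x):
            return "n/a" if x is None else f"{x:.1f}%"

        lines.append(
            "recovery medians: plasma->urine "
            f"{fmt(med['recovery_pu'])}, urine->plasma {fmt(med['recovery_up'])}; "
            f"pathogenic-only {fmt(med['pathogenic_recovery_pu'])} / {fmt(med['pathogenic_recovery_up'])}"
        )
        for name, res in (
            ("Spearman (conc)", self.conc_spearman),
            ("Wilcoxon (conc)", self.conc_wilcoxon),
            ("Chi-square (classes)", self.class_chi2),
        ):
            if res is not None:
                lines.append(f"{name}: statistic={res.statistic:.4g}, p={res.p_value:.4g} [{res.method}]")
        for title, table in (
            ("VAF bins", s.vaf_bin_table),
            ("ACMG classes", s.class_table),
            ("Tiers", s.tier_table),
        ):
            lines.append("")
            lines.append(title)
            lines.append(table.to_string())
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, outdir: str | Path) -> Path:
        """Write every report artifact (TSVs, summary.json, annotated VCFs)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        s = self.summary_tables
        pd.DataFrame([s.venn]).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        s.per_sample_counts.to_csv(outdir / "per_sample_counts.tsv", sep="\t", index=False)
        s.recovery.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
        s.vaf_bin_table.to_csv(outdir / "vaf_bins.tsv", sep="\t")
        s.class_table.to_csv(outdir / "class_dist.tsv", sep="\t")
        s.tier_table.to_csv(outdir / "tier_dist.tsv", sep="\t")
        s.gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
        s.pathogenic_presence.to_csv(outdir / "pathogenic_matrix.tsv", sep="\t")
        pd.concat([r.to_frame() for r in self.cascade_reports], ignore_index=True).to_csv(
            outdir / "cascade_report.tsv", sep="\t", index=False
        )
        (outdir / "summary.json").write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n")
        for (pid, fluid), variants in self.survivors.items():
            extra = {}
            for v in variants:
                cls, tier, vbin = classify_variant(v)
                extra[v.key] = {"ACMG_CLASS": cls, "TIER": tier, "VAFBIN": vbin}
            fio.write_sample_vcf(
                outdir / f"{pid}_{fluid}.filtered.vcf", variants, f"{pid}_{fluid}", extra
            )
        return outdir

    # -- plotting ---------------------------------------------------------
    def plot_vaf_bins(self, ax=None):
        """Stacked-bar VAF-bin distribution per fluid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.summary_tables.vaf_bin_table.T.plot(kind="bar", stacked=True, ax=ax)
        ax.set_ylabel("variants")
        ax.set_xlabel("fluid")
        return ax

    def plot_venn(self, ax=None):
        """Bar rendering of the Venn components (exclusive/shared counts)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.summary_tables.venn
        keys = ["plasma_exclusive", "shared", "urine_exclusive"]
        ax.bar(keys, [v[k] for k in keys])
        ax.set_ylabel("variants")
        return ax


def _test_dict(res: TestResult | None) -> dict | None:
    if res is None:
        return None
    return {"statistic": res.statistic, "p_value": res.p_value, "method": res.method}


def run_pipeline(run_config: RunConfig) -> CohortResults:
    """Orchestrate one end-to-end run from a :class:`RunConfig`; writes all
    report artifacts into ``run_config.outdir`` and returns the results."""
    model = MatchedFluidCohort.from_paths(
        run_config.manifest,
        run_config.concentrations,
        run_config.windows_bed,
        run_config.filter_config,
        run_config.tag_config,
    )
    results = model.fit()
    results.save(run_config.outdir)
    return results
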