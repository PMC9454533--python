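import hashlib
from pathlib import Path

import numpy as np
import pytest

from fluidvar import SyntheticConfig, generate_cohort, plant_removals, sample_vaf
from fluidvar.io import WindowSet
from fluidvar.synthetic import GENE_PANEL, _panel_windows


def _tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def test_panel_has_93_genes_with_disjoint_loci():
    assert len(GENE_PANEL) == 93
    seen = set()
    for gene, (chrom, start) in GENE_PANEL.items():
        assert (chrom, start) not in seen
        seen.add((chrom, start))


def test_same_seed_byte_identical(tmp_path):
    cfg = SyntheticConfig(seed=1, n_patients=4)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg, d1)
    generate_cohort(cfg, d2)
    assert _tree_digest(d1) == _tree_digest(d2)


def test_different_seed_differs(tmp_path):
    a, _ = generate_cohort(SyntheticConfig(seed=1, n_patients=2), tmp_path / "a")
    b, _ = generate_cohort(SyntheticConfig(seed=2, n_patients=2), tmp_path / "b")
    assert (
        (tmp_path / "a" / "P01_plasma.vcf").read_text()
        != (tmp_path / "b" / "P01_plasma.vcf").read_text()
    )


def test_empty_cohort(tmp_path):
    paths, truth = generate_cohort(SyntheticConfig(seed=3, n_patients=0), tmp_path)
    assert truth.records.empty
    assert paths.manifest.read_text().strip() == "patient_id\tplasma_vcf\turine_vcf"
    assert not paths.sample_vcfs


def test_truth_covers_every_emitted_record(small_cohort):
    _, paths, truth, _ = small_cohort
    from fluidvar import read_sample_vcf

    df = truth.records
    assert set(df.fate.unique()) <= {"survive", "removed"}
    for (pid, fluid), path in paths.sample_vcfs.items():
        variants = read_sample_vcf(path, sample_id=pid, fluid=fluid)
        truth_keys = {
            (r.chrom, int(r.pos), r.ref, r.alt)
            for _, r in df[(df.patient_id == pid) & (df.fluid == fluid)].iterrows()
        }
        assert {v.key for v in variants} == truth_keys


class TestSampleVaf:
    def test_degenerate_mass_on_last_bin(self):
        cfg = SyntheticConfig(seed=1, vaf_bin_masses=(0, 0, 0, 0, 1.0))
        rng = np.random.default_rng(0)
        draws = [sample_vaf(cfg, rng) for _ in range(200)]
        assert all(50.0 <= v <= 100.0 for v in draws)

    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(seed=1)
        a = [sample_vaf(cfg, np.random.default_rng(42)) for _ in range(10)]
        b = [sample_vaf(cfg, np.random.default_rng(42)) for _ in range(10)]
        assert a == b

    def test_bin_masses_recovered_at_1e4_draws(self):
        cfg = SyntheticConfig(seed=1)
        rng = np.random.default_rng(12345)
        edges = (3.0, 5.0, 10.0, 20.0, 50.0, 100.0)
        n = 10_000
        draws = np.array([sample_vaf(cfg, rng) for _ in range(n)])
        counts = np.histogram(draws, bins=edges)[0]
        for observed, mass in zip(counts, cfg.vaf_bin_masses):
            se = np.sqrt(mass * (1 - mass) / n)
            assert abs(observed / n - mass) <= 3 * se + 1e-9


class TestPlantRemovals:
    def test_each_plant_violates_exactly_its_criterion(self):
        cfg = SyntheticConfig(seed=5)
        rng = np.random.default_rng(5)
        windows = _panel_windows()
        plants = plant_removals(300, cfg, rng, set(), "p1", "plasma", windows)
        assert plants, "expected some plants at these rates"
        from fluidvar import FilterConfig, run_cascade

        seen_reasons = set()
        for v, reason in plants:
            survivors, report = run_cascade([v], FilterConfig(), windows)
            assert not survivors, (v, reason)
            removed_reason = [r for s in report.stages for r in s.reasons][0]
            assert removed_reason == reason
            seen_reasons.add(reason)
        assert seen_reasons == {
            "low_quality",
            "low_vaf",
            "excluded_window",
            "common_population",
            "deep_intronic",
            "not_deleterious",
        }

    def test_windowed_plant_requires_windows(self):
        cfg = SyntheticConfig(seed=5)
        with pytest.raises(ValueError):
            plant_removals(500, cfg, np.random.default_rng(1), set(), "p1", "plasma", WindowSet())


def test_shared_fraction_recovered_small(small_cohort):
    """Pipeline-measured plasma->urine recovery estimates the configured
    shared fraction within 3 binomial standard errors."""
    config, _, _, results = small_cohort
    n_plasma = sum(len(p.plasma) for p in results.pairs)
    n_shared = sum(len(p.shared) for p in results.pairs)
    p_hat = n_shared / n_plasma
    se = np.sqrt(config.shared_fraction * (1 - config.shared_fraction) / n_plasma)
    assert abs(p_hat - config.shared_fraction) <= 3 * se + 0.01  # hotspots add a small shift


def test_concentration_correlation_recovered_at_n100(tmp_path):
    from fluidvar import read_concentrations, spearman_rho

    cfg = SyntheticConfig(seed=9, n_patients=100, hotspot_presence=(),
                          plasma_median_count=5, urine_median_count=5,
                          removal_rates={})
    paths, _ = generate_cohort(cfg, tmp_path)
    conc = read_concentrations(paths.concentrations)
    plasma = [p for p, _ in conc.values()]
    urine = [u for _, u in conc.values()]
    rho = spearman_rho(plasma, urine).statistic
    assert abs(rho - cfg.conc_correlation) <= 0.15
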