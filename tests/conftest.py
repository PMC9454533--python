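import pytest

from fluidvar import MatchedFluidCohort, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 15-patient synthetic cohort (seed 7) with its truth and a fitted run."""
    outdir = tmp_path_factory.mktemp("cohort7")
    config = SyntheticConfig(seed=7, n_patients=15)
    paths, truth = generate_cohort(config, outdir)
    model = MatchedFluidCohort.from_paths(paths.manifest, paths.concentrations, paths.windows_bed)
    results = model.fit()
    return config, paths, truth, results


def make_variant(**kwargs):
    """AnnotatedVariant factory with sane post-filter defaults."""
    from fluidvar import AnnotatedVariant

    defaults = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        gene="TP53",
        call_quality=80.0,
        vaf=12.0,
        depth=100,
        pop_af=None,
        effect="missense",
        intron_offset=0,
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)
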