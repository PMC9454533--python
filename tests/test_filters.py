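import pytest

from fluidvar import FilterConfig, WindowSet, common_filter, confidence_filter, deleterious_filter, run_cascade

from conftest import make_variant

CFG = FilterConfig()
WINDOWS = WindowSet.from_intervals([("1", 5000, 5100)])


def keys(variants):
    return {v.key for v in variants}


class TestConfidenceFilter:
    def test_quality_threshold_inclusive(self):
        low = make_variant(pos=1, call_quality=49.0, vaf=10.0)
        edge = make_variant(pos=2, call_quality=50.0, vaf=3.0)
        kept, removed = confidence_filter([low, edge], CFG, WINDOWS)
        assert keys(kept) == {edge.key}
        assert removed == [(low, "low_quality")]

    def test_vaf_threshold_inclusive(self):
        below = make_variant(pos=1, vaf=2.999)
        at = make_variant(pos=2, vaf=3.0)
        kept, removed = confidence_filter([below, at], CFG, WINDOWS)
        assert keys(kept) == {at.key}
        assert removed[0][1] == "low_vaf"

    def test_window_exclusion(self):
        inside = make_variant(pos=5050, call_quality=90.0, vaf=40.0)
        outside = make_variant(pos=5500)
        kept, removed = confidence_filter([inside, outside], CFG, WINDOWS)
        assert keys(kept) == {outside.key}
        assert removed[0][1] == "excluded_window"

    def test_first_failing_reason_attribution(self):
        v = make_variant(pos=5050, call_quality=10.0, vaf=1.0)  # fails all three
        _, removed = confidence_filter([v], CFG, WINDOWS)
        assert removed[0][1] == "low_quality"


class TestCommonFilter:
    def test_common_removed(self):
        v = make_variant(pop_af=0.02)
        kept, removed = common_filter([v], CFG)
        assert not kept and removed[0][1] == "common_population"

    def test_established_pathogenic_rescued(self):
        v = make_variant(pop_af=0.02, established_pathogenic=True)
        kept, removed = common_filter([v], CFG)
        assert kept and not removed

    def test_missing_pop_af_treated_as_rare(self):
        v = make_variant(pop_af=None)
        kept, _ = common_filter([v], CFG)
        assert kept

    def test_threshold_inclusive(self):
        v = make_variant(pop_af=0.01)
        kept, _ = common_filter([v], CFG)
        assert kept


class TestDeleteriousFilter:
    def test_deep_intronic_removed(self):
        v = make_variant(effect="missense", intron_offset=21)
        kept, removed = deleterious_filter([v], CFG)
        assert not kept and removed[0][1] == "deep_intronic"

    def test_offset_20_kept(self):
        v = make_variant(effect="intronic", intron_offset=-20, splice_pred_flag=True,
                         evidence_codes=frozenset({"BA1"}))
        kept, _ = deleterious_filter([v], CFG)
        assert kept  # retained by the splice predictor despite benign class

    def test_benign_synonymous_removed(self):
        v = make_variant(effect="synonymous", evidence_codes=frozenset({"BA1"}))
        kept, removed = deleterious_filter([v], CFG)
        assert not kept and removed[0][1] == "not_deleterious"

    def test_vus_missense_kept(self):
        v = make_variant(effect="missense", evidence_codes=frozenset())
        kept, _ = deleterious_filter([v], CFG)
        assert kept

    def test_splice_region_within_two_bases(self):
        near = make_variant(pos=1, effect="splice_region", intron_offset=2,
                            evidence_codes=frozenset({"BA1"}))
        far = make_variant(pos=2, effect="splice_region", intron_offset=3,
                           evidence_codes=frozenset({"BA1"}))
        kept, removed = deleterious_filter([near, far], CFG)
        assert keys(kept) == {near.key}
        assert removed[0][1] == "not_deleterious"

    def test_gof_flag_retains_benign(self):
        v = make_variant(effect="synonymous", gof_flag=True, evidence_codes=frozenset({"BA1"}))
        kept, _ = deleterious_filter([v], CFG)
        assert kept


def _planted_ten():
    """Ten variants with hand-evaluated fates: 3 low-quality, 2 common,
    1 deep-intronic benign, 4 clean survivors."""
    removed_quality = [make_variant(pos=p, call_quality=q) for p, q in ((1, 10.0), (2, 49.9), (3, 0.0))]
    removed_common = [
        make_variant(pos=4, pop_af=0.011),
        make_variant(pos=5, pop_af=0.5),
    ]
    removed_intronic = [
        make_variant(pos=6, effect="intronic", intron_offset=150, evidence_codes=frozenset({"BA1"}))
    ]
    clean = [make_variant(pos=p) for p in (7, 8, 9, 10)]
    return removed_quality, removed_common, removed_intronic, clean


def test_cascade_on_planted_fixture():
    rq, rc, ri, clean = _planted_ten()
    survivors, report = run_cascade(rq + rc + ri + clean, CFG, WINDOWS)
    assert keys(survivors) == keys(clean)
    by_stage = {s.stage: s for s in report.stages}
    assert by_stage["confidence"].reasons == {"low_quality": 3}
    assert by_stage["common"].reasons == {"common_population": 2}
    assert by_stage["deleterious"].reasons == {"deep_intronic": 1}
    assert report.n_in == 10 and report.n_surviving == 4


def test_cascade_empty_input():
    survivors, report = run_cascade([], CFG, WINDOWS)
    assert survivors == []
    assert report.n_in == 0 and report.n_surviving == 0
    assert all(s.n_removed == 0 for s in report.stages)


def test_monotone_attrition_and_stage_chaining(small_cohort):
    _, _, _, results = small_cohort
    for report in results.cascade_reports:
        outs = [s.n_out for s in report.stages]
        assert outs == sorted(outs, reverse=True)
        report.validate()


def test_staged_equals_fused_composition():
    rq, rc, ri, clean = _planted_ten()
    variants = rq + rc + ri + clean
    survivors, _ = run_cascade(variants, CFG, WINDOWS)
    c1, _ = confidence_filter(variants, CFG, WINDOWS)
    c2, _ = common_filter(c1, CFG)
    c3, _ = deleterious_filter(c2, CFG)
    assert keys(survivors) == keys(c3)


def test_each_filter_idempotent_on_own_output():
    rq, rc, ri, clean = _planted_ten()
    variants = rq + rc + ri + clean
    for fn in (
        lambda vs: confidence_filter(vs, CFG, WINDOWS),
        lambda vs: common_filter(vs, CFG),
        lambda vs: deleterious_filter(vs, CFG),
    ):
        once, _ = fn(variants)
        twice, removed_again = fn(once)
        assert keys(twice) == keys(once) and not removed_again
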