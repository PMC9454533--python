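import numpy as np
import pytest

from fluidvar import cohort_summarize, match_pair, pathogenic_matrix, recovery_rate

from conftest import make_variant


def _vars(positions, fluid, **kwargs):
    return [make_variant(pos=p, fluid=fluid, **kwargs) for p in positions]


class TestMatchPair:
    def test_identical_sets(self):
        plasma = _vars(range(1, 6), "plasma")
        urine = _vars(range(1, 6), "urine")
        pair = match_pair(plasma, urine, "p1")
        assert len(pair.shared) == 5
        assert not pair.plasma_exclusive and not pair.urine_exclusive
        assert pair.recovery_pu == pair.recovery_up == 100.0

    def test_disjoint_sets(self):
        pair = match_pair(_vars([1, 2, 3], "plasma"), _vars([4, 5, 6, 7], "urine"), "p1")
        assert not pair.shared
        assert pair.recovery_pu == 0.0 and pair.recovery_up == 0.0

    def test_partial_overlap_recovery_arithmetic(self):
        plasma = _vars(range(1, 11), "plasma")  # 10
        urine = _vars(range(7, 27), "urine")  # 20, overlap 7..10 = 4
        pair = match_pair(plasma, urine, "p1")
        assert len(pair.shared) == 4
        assert pair.recovery_pu == pytest.approx(40.0)
        assert pair.recovery_up == pytest.approx(20.0)

    def test_duplicate_key_within_sample_rejected(self):
        dup = _vars([1, 1], "plasma")
        with pytest.raises(ValueError):
            match_pair(dup, [], "p1")

    def test_pathogenic_recovery_uses_source_class(self):
        """A variant pathogenic in plasma counts as recovered when its key is
        present in urine, even if the urine call is classified differently."""
        path_codes = frozenset({"PVS1", "PS1"})
        plasma = [make_variant(pos=1, fluid="plasma", evidence_codes=path_codes),
                  make_variant(pos=2, fluid="plasma", evidence_codes=path_codes)]
        urine = [make_variant(pos=1, fluid="urine")]  # VUS in urine
        pair = match_pair(plasma, urine, "p1")
        assert pair.pathogenic_recovery_pu == pytest.approx(50.0)
        assert pair.pathogenic_recovery_up is None  # no pathogenic urine calls


class TestRecoveryRate:
    def test_basic(self):
        assert recovery_rate({"a", "b"}, {"b", "c"}) == pytest.approx(50.0)

    def test_empty_source_undefined(self):
        assert recovery_rate(set(), {"b"}) is None

    def test_symmetric_numerator(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = set(map(int, rng.integers(0, 30, rng.integers(1, 15))))
            b = set(map(int, rng.integers(0, 30, rng.integers(1, 15))))
            na = recovery_rate(a, b) * len(a) / 100.0
            nb = recovery_rate(b, a) * len(b) / 100.0
            assert round(na) == round(nb) == len(a & b)


class TestCohortSummary:
    def test_single_pair_totals_and_medians(self):
        pair = match_pair(_vars([1, 2, 3, 4], "plasma"),
                          _vars([3, 4, 5, 6, 7, 8], "urine"), "p1")
        s = cohort_summarize([pair])
        assert s.venn["plasma_total"] == 4 and s.venn["urine_total"] == 6
        assert s.medians["plasma_per_sample"] == 4 and s.medians["urine_per_sample"] == 6

    def test_even_count_median(self):
        pairs = [
            match_pair(_vars([1, 2], "plasma"), _vars([1], "urine"), "p1"),
            match_pair(_vars([1, 2, 3, 4], "plasma"), _vars([2], "urine"), "p2"),
        ]
        s = cohort_summarize(pairs)
        assert s.medians["plasma_per_sample"] == pytest.approx(3.0)

    def test_venn_conservation_and_table_sums(self, small_cohort):
        _, _, _, results = small_cohort
        s = results.summary_tables
        s.validate()  # asserts Venn conservation and distribution-table sums
        v = s.venn
        assert v["grand_total"] == (
            v["plasma_exclusive"] + v["urine_exclusive"] + 2 * v["shared"]
        )

    def test_cohort_duplication_leaves_medians_unchanged(self):
        pairs = [
            match_pair(_vars([1, 2, 3], "plasma"), _vars([2, 3, 4, 5], "urine"), "p1"),
            match_pair(_vars([1, 2, 3, 4, 5], "plasma"), _vars([5], "urine"), "p2"),
        ]
        doubled = pairs + [
            match_pair(_vars([1, 2, 3], "plasma"), _vars([2, 3, 4, 5], "urine"), "p3"),
            match_pair(_vars([1, 2, 3, 4, 5], "plasma"), _vars([5], "urine"), "p4"),
        ]
        m1 = cohort_summarize(pairs).medians
        m2 = cohort_summarize(doubled).medians
        for key in ("recovery_pu", "recovery_up", "plasma_per_sample", "urine_per_sample"):
            assert m1[key] == m2[key]

    def test_gene_table_matches_planted_counts(self, small_cohort):
        _, _, truth, results = small_cohort
        df = truth.records
        surv = df[df.fate == "survive"]
        planted = surv.groupby("gene").size().sort_values(ascending=False)
        table = results.summary_tables.gene_table.set_index("gene")
        for gene, count in planted.items():
            assert int(table.loc[gene, "total"]) == int(count)
        assert int(table["total"].sum()) == len(surv)


class TestPathogenicMatrix:
    def test_empty_when_no_pathogenic(self):
        pair = match_pair(_vars([1], "plasma"), _vars([2], "urine"), "p1")
        assert pathogenic_matrix([pair]).empty

    def test_planted_presence_pattern(self):
        path_codes = frozenset({"PVS1", "PS1"})
        hotspot = dict(chrom="17", pos=7000, ref="C", alt="T", gene="CHEK2",
                       evidence_codes=path_codes)
        pairs = []
        for pid in ("p1", "p2", "p3"):
            plasma = [make_variant(fluid="plasma", **hotspot)]
            urine = [make_variant(fluid="urine", **hotspot)]
            if pid == "p2":  # one private pathogenic variant in p2's plasma
                plasma.append(make_variant(pos=123, fluid="plasma", gene="NF1",
                                           evidence_codes=path_codes))
            pairs.append(match_pair(plasma, urine, pid))
        m = pathogenic_matrix(pairs)
        assert list(m.columns) == ["p1_P", "p1_U", "p2_P", "p2_U", "p3_P", "p3_U"]
        assert m.shape == (2, 6)
        # the everywhere-present hotspot ranks first with an all-ones row
        assert m.index[0].startswith("CHEK2")
        assert m.iloc[0].tolist() == [1, 1, 1, 1, 1, 1]
        assert m.iloc[1].tolist() == [0, 0, 1, 0, 0, 0]

    def test_matrix_matches_generator_plant(self, small_cohort):
        _, _, truth, results = small_cohort
        df = truth.records
        hot = df[df.hotspot & (df.fate == "survive")]
        m = results.summary_tables.pathogenic_presence
        for (chrom, pos, ref, alt), grp in hot.groupby(["chrom", "pos", "ref", "alt"]):
            label = [ix for ix in m.index if ix.endswith(f"{chrom}:{pos}:{ref}>{alt}")]
            assert len(label) == 1
            row = m.loc[label[0]]
            expected_cols = {
                f"{r.patient_id}_{'P' if r.fluid == 'plasma' else 'U'}" for _, r in grp.iterrows()
            }
            assert {c for c in m.columns if row[c] == 1} == expected_cols
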