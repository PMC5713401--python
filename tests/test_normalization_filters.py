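import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcoexp import (
    CountMatrix,
    DEGRecord,
    ExpressionMatrix,
    PipelineConfig,
    bh_adjust,
    classify_deg,
    compute_fpkm,
    deg_count_matrix,
    filter_fold_range,
    filter_widely_expressed,
    log2_fold_change,
    presence_filter,
    zscore_profiles,
)
from conftest import random_matrix
from oracles import bh_oracle


class TestComputeFpkm:
    def _counts(self, counts, lengths, libsizes, stages=("a", "b", "c")):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        return CountMatrix(genes, stages, counts,
                           dict(zip(genes, lengths)),
                           dict(zip(stages, libsizes)))

    def test_zero_counts_give_zero_fpkm(self):
        cm = self._counts(np.zeros((2, 3), dtype=int), [1000, 2000],
                          [1e6, 2e6, 3e6])
        assert np.all(compute_fpkm(cm).values == 0.0)

    def test_hand_value(self):
        # 10 fragments, 2000 bp, 1e6 mapped: 10 * 1e9 / (2000 * 1e6) = 5.0
        cm = self._counts(np.full((1, 3), 10), [2000], [1e6, 1e6, 1e6])
        assert compute_fpkm(cm).values[0, 0] == 5.0

    def test_doubling_library_halves_column(self, rng):
        counts = rng.integers(0, 1000, size=(10, 3))
        cm1 = self._counts(counts, [500] * 10, [1e6, 1e6, 1e6])
        cm2 = self._counts(counts, [500] * 10, [2e6, 1e6, 1e6])
        f1, f2 = compute_fpkm(cm1), compute_fpkm(cm2)
        np.testing.assert_allclose(f2.values[:, 0], f1.values[:, 0] / 2)
        np.testing.assert_allclose(f2.values[:, 1:], f1.values[:, 1:])

    def test_linear_in_counts_inverse_in_length(self, rng):
        counts = rng.integers(1, 1000, size=(5, 3))
        lengths = rng.integers(300, 3000, size=5)
        libs = rng.integers(int(1e6), int(3e7), size=3)
        base = compute_fpkm(self._counts(counts, lengths, libs))
        doubled = compute_fpkm(self._counts(2 * counts, lengths, libs))
        np.testing.assert_allclose(doubled.values, 2 * base.values)
        halflen = compute_fpkm(self._counts(counts, 2 * lengths, libs))
        np.testing.assert_allclose(halflen.values, base.values / 2)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            self._counts(np.ones((1, 3), dtype=int), [0], [1e6, 1e6, 1e6])

    def test_bad_library_size_rejected(self):
        with pytest.raises(ValueError, match="library"):
            self._counts(np.ones((1, 3), dtype=int), [100], [1e6, -1, 1e6])


class TestFilterWidelyExpressed:
    def test_strict_boundary_excluded(self, stages7):
        values = np.full((1, 7), 5.0)
        values[0, 3] = 1.0
        m = ExpressionMatrix(["g1"], stages7, values)
        assert filter_widely_expressed(m, 1.0) == frozenset()

    def test_all_zero_excluded_all_ten_retained(self, stages7):
        m = ExpressionMatrix(["zero", "ten"], stages7,
                             np.vstack([np.zeros(7), np.full(7, 10.0)]))
        assert filter_widely_expressed(m, 1.0) == {"ten"}

    def test_matches_brute_force(self, rng):
        m = random_matrix(rng, 100, 7, scale=2.0)
        expected = {g for i, g in enumerate(m.gene_ids)
                    if min(m.values[i]) > 1.0}
        assert filter_widely_expressed(m, 1.0) == expected

    def test_idempotent(self, rng):
        m = random_matrix(rng, 50, 7, scale=2.0)
        kept = filter_widely_expressed(m, 1.0)
        again = filter_widely_expressed(m.subset(sorted(kept)), 1.0)
        assert again == kept


class TestFilterFoldRange:
    def test_flat_gene_excluded(self, stages7):
        m = ExpressionMatrix(["flat"], stages7, np.full((1, 7), 3.0))
        assert filter_fold_range(m, 1.0001) == frozenset()

    def test_hand_case_retained(self, stages7):
        values = np.linspace(2.0, 5.0, 7)[None, :]
        m = ExpressionMatrix(["g"], stages7, values)
        # 5/2 = 2.5 > 2
        assert filter_fold_range(m, 2.0) == {"g"}

    def test_monotone_in_fold_min(self, rng):
        m = random_matrix(rng, 80, 7)
        previous = None
        for fold_min in (1.5, 2.0, 3.0, 5.0):
            kept = filter_fold_range(m, fold_min)
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_matches_brute_force(self, rng):
        m = random_matrix(rng, 100, 7)
        expected = {g for i, g in enumerate(m.gene_ids)
                    if max(m.values[i]) / min(m.values[i]) > 2.0}
        assert filter_fold_range(m, 2.0) == expected

    def test_pseudocount_applied(self, stages7):
        values = np.array([[0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 3.0]])
        m = ExpressionMatrix(["g"], stages7, values)
        # (3 + 1) / (0 + 1) = 4 > 2 with pseudocount 1
        assert filter_fold_range(m, 2.0, pseudocount=1.0) == {"g"}
        # without pseudocount min = 0 -> infinite ratio -> retained
        assert filter_fold_range(m, 2.0) == {"g"}


class TestPresenceFilter:
    def test_excluded_at_five_of_seven(self, stages7):
        values = np.zeros((1, 7))
        values[0, :2] = 5.0  # zero in 5 of 7 stages: 0.714 >= 0.6
        m = ExpressionMatrix(["g"], stages7, values)
        assert presence_filter(m, 0.6) == frozenset()

    def test_retained_at_four_of_seven(self, stages7):
        values = np.zeros((1, 7))
        values[0, :3] = 5.0  # zero in 4 of 7 stages: 0.571 < 0.6
        m = ExpressionMatrix(["g"], stages7, values)
        assert presence_filter(m, 0.6) == {"g"}

    def test_all_positive_retained(self, rng):
        m = random_matrix(rng, 30, 7)
        assert presence_filter(m, 0.6) == set(m.gene_ids)

    def test_detection_floor(self, stages7):
        values = np.full((1, 7), 0.5)
        values[0, :2] = 5.0
        m = ExpressionMatrix(["g"], stages7, values)
        assert presence_filter(m, 0.6, detection_floor=1.0) == frozenset()
        assert presence_filter(m, 0.6, detection_floor=0.0) == {"g"}


class TestLog2FoldChange:
    def test_identity(self):
        assert log2_fold_change(5.0, 5.0) == 0.0

    def test_hand_value(self):
        # log2((3 + 1) / (1 + 1)) = 1
        assert log2_fold_change(1.0, 3.0, pseudocount=1.0) == 1.0

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(
            -log2_fold_change(b, a), abs=1e-12)

    def test_requires_positive_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(1.0, 2.0, pseudocount=0.0)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_known_example(self):
        # sorted: 0.01*4/1=0.04, 0.02*4/2=0.04, 0.03*4/3=0.04, 0.04*4/4=0.04
        assert bh_adjust([0.04, 0.01, 0.03, 0.02]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=300)
    def test_matches_brute_force_oracle(self, pvalues):
        np.testing.assert_allclose(bh_adjust(pvalues), bh_oracle(pvalues),
                                   atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_output_in_unit_interval_and_geq_input(self, pvalues):
        adjusted = bh_adjust(pvalues)
        for p, q in zip(pvalues, adjusted):
            assert 0 <= q <= 1
            assert q >= p - 1e-12


class TestClassifyDeg:
    def test_up_call(self):
        (rec,) = classify_deg([DEGRecord("g", "a", "b", 1.5, fdr=0.01)])
        assert rec.call == "up"

    def test_high_fdr_blocks_call(self):
        (rec,) = classify_deg([DEGRecord("g", "a", "b", 1.5, fdr=0.2)])
        assert rec.call == "ns"

    def test_boundary_log2fc_is_ns(self):
        # threshold is strict: log2FC must exceed 1
        (rec,) = classify_deg([DEGRecord("g", "a", "b", 1.0, fdr=0.001)])
        assert rec.call == "ns"

    def test_down_call(self):
        (rec,) = classify_deg([DEGRecord("g", "a", "b", -2.0, fdr=0.01)])
        assert rec.call == "down"

    def test_fdr_absent_uses_fold_change_only(self):
        (rec,) = classify_deg([DEGRecord("g", "a", "b", 3.0)])
        assert rec.call == "up"

    def test_pvalues_get_bh_adjusted(self):
        records = [DEGRecord(f"g{i}", "a", "b", 2.0, pvalue=p)
                   for i, p in enumerate([0.001, 0.02, 0.9])]
        out = classify_deg(records)
        expected_fdr = bh_oracle([0.001, 0.02, 0.9])
        assert [r.fdr for r in out] == pytest.approx(expected_fdr)
        assert [r.call for r in out] == ["up", "up", "ns"]

    def test_mapping_inputs_accepted(self):
        out = classify_deg([{"gene_id": "g", "stage_a": "a", "stage_b": "b",
                             "log2fc": 2.0}])
        assert out[0].call == "up"


class TestDegCountMatrix:
    def test_monotone_more_than_doubling_gene(self, stages7):
        values = 10.0 * 2.1 ** np.arange(7)
        m = ExpressionMatrix(["g"], stages7, values[None, :])
        config = PipelineConfig(pseudocount=1e-6)
        counts = deg_count_matrix(m, config)
        for i, a in enumerate(stages7):
            for j, b in enumerate(stages7):
                if i < j:
                    assert counts.up(a, b) == 1
                    assert counts.down(a, b) == 0

    def test_identical_columns_all_zero(self, stages7):
        m = ExpressionMatrix(["g1", "g2"], stages7, np.full((2, 7), 4.0))
        counts = deg_count_matrix(m)
        for a in stages7:
            for b in stages7:
                assert counts.up(a, b) == 0
                assert counts.down(a, b) == 0

    def test_reversal_antisymmetry_random(self, rng):
        m = random_matrix(rng, 40, 5)
        counts = deg_count_matrix(m)
        for a in m.stage_labels:
            for b in m.stage_labels:
                assert counts.up(a, b) == counts.down(b, a)

    def test_to_frame_shape(self, rng):
        m = random_matrix(rng, 10, 4)
        frame = deg_count_matrix(m).to_frame()
        assert frame.shape == (4, 4)
        assert all(frame.iloc[i, i] == "0" for i in range(4))

    def test_needs_two_stages(self, stages7):
        m = ExpressionMatrix(["g"], stages7, np.ones((1, 7)))
        deg_count_matrix(m)  # fine
        with pytest.raises(ValueError):
            ExpressionMatrix(["g"], ["a"], np.ones((1, 1)))


class TestZscoreProfiles:
    def test_basic_row(self, stages7):
        m = ExpressionMatrix(["g"], stages7[:3] + stages7[3:],
                             np.arange(1.0, 8.0)[None, :])
        profiles = zscore_profiles(m)
        row = profiles.z[0]
        assert row.mean() == pytest.approx(0.0, abs=1e-9)
        assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_definition_on_123(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"],
                             np.array([[1.0, 2.0, 3.0]]))
        row = zscore_profiles(m).z[0]
        np.testing.assert_allclose(row, [-1.0, 0.0, 1.0])

    def test_constant_row_flagged_and_zeroed(self, stages7):
        m = ExpressionMatrix(["flat", "var"], stages7,
                             np.vstack([np.full(7, 2.0),
                                        np.arange(7.0)]))
        profiles = zscore_profiles(m)
        assert profiles.constant_genes == {"flat"}
        assert np.all(profiles.z[0] == 0.0)

    def test_invariant_to_positive_affine_scaling(self, rng):
        values = rng.lognormal(0, 1, size=(20, 7))
        stages = [f"s{i}" for i in range(7)]
        genes = [f"g{i}" for i in range(20)]
        base = zscore_profiles(ExpressionMatrix(genes, stages, values))
        scaled = zscore_profiles(
            ExpressionMatrix(genes, stages, 7.3 * values + 2.0))
        np.testing.assert_allclose(scaled.z, base.z, atol=1e-9)


class TestFilterFunnel:
    def test_funnel_shape_and_ordering(self, rng):
        """widely-expressed then fold-range, as published; each step only
        removes genes."""
        m = random_matrix(rng, 200, 7, scale=3.0)
        wide = filter_widely_expressed(m, 1.0)
        variable = filter_fold_range(
            m.subset(sorted(wide)), 2.0)
        assert variable <= wide <= set(m.gene_ids)
        assert len(wide) < m.n_genes  # scale chosen so both steps bite
        assert len(variable) <= len(wide)

    def test_fpkm_chain_is_consistent(self):
        # a chain from counts: FPKM values then the funnel, fully determined
        genes = ["hi", "lo", "flat"]
        stages = ("a", "b", "c")
        counts = np.array([[100, 400, 1600], [1, 1, 1], [500, 500, 500]])
        cm = CountMatrix(genes, stages, counts,
                         {"hi": 1000, "lo": 1000, "flat": 1000},
                         {"a": 1e6, "b": 1e6, "c": 1e6})
        fpkm = compute_fpkm(cm)
        # hi: 100, 400, 1600; lo: 1 (not > 1); flat: 500
        wide = filter_widely_expressed(fpkm, 1.0)
        assert wide == {"hi", "flat"}
        variable = filter_fold_range(fpkm.subset(sorted(wide)), 2.0)
        assert variable == {"hi"}


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=20, deadline=None)
def test_fpkm_scale_invariance_property(seed):
    """FPKM is invariant to scaling counts, lengths and library sizes by
    the same factor structure: counts*k with libsize*k is a no-op."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 500, size=(5, 3))
    genes = [f"g{i}" for i in range(5)]
    stages = ["a", "b", "c"]
    lengths = dict(zip(genes, rng.integers(300, 3000, size=5).tolist()))
    libs = rng.integers(int(1e6), int(1e7), size=3)
    cm1 = CountMatrix(genes, stages, counts, lengths,
                      dict(zip(stages, libs.tolist())))
    cm2 = CountMatrix(genes, stages, counts * 3, lengths,
                      dict(zip(stages, (libs * 3).tolist())))
    np.testing.assert_allclose(compute_fpkm(cm2).values,
                               compute_fpkm(cm1).values, rtol=1e-12)


def test_log2fc_threshold_semantics_match_deg_matrix(rng):
    """deg_count_matrix agrees with direct classify_deg calls."""
    m = random_matrix(rng, 30, 4)
    config = PipelineConfig()
    counts = deg_count_matrix(m, config)
    a, b = m.stage_labels[0], m.stage_labels[2]
    ia, ib = 0, 2
    expected_up = sum(
        1 for i in range(m.n_genes)
        if math.log2((m.values[i, ib] + 1) / (m.values[i, ia] + 1)) > 1.0)
    assert counts.up(a, b) == expected_up
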