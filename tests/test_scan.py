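"""Multi-allelic weighted Fst, top-quantile selection, joining, gene overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from cnvpop.cnvr import merge_calls_to_cnvrs
from cnvpop.io import GeneModel
from cnvpop.scan import (AlleleFrequencies, ScanConfig, allele_frequencies,
                         annotate_genes, fst_scan, fst_segment, join_connected,
                         run_selection_scan, select_top_quantile)
from cnvpop.segmentation import CN_CLASSES, build_genotype_matrix, partition_all

from conftest import fst_reference, make_call, random_frequency_vector


def freqs(mapping, n):
    return AlleleFrequencies(mapping, n)


class TestAlleleFrequencies:
    def _matrix(self):
        calls = [
            make_call("S1", start=100, end=200, cn=1),
            make_call("S2", start=100, end=200, cn=1),
            make_call("S4", start=100, end=200, cn=3),
        ]
        segments = partition_all(merge_calls_to_cnvrs(calls))
        return build_genotype_matrix(["S1", "S2", "S3", "S4"], segments, calls)

    def test_all_diploid_group(self):
        calls = [make_call("S9", start=10, end=20, cn=1)]
        segments = partition_all(merge_calls_to_cnvrs(calls))
        matrix = build_genotype_matrix(["S1", "S2", "S3", "S4"], segments, [])
        af = allele_frequencies(matrix, "chr1:10-20", ["S1", "S2", "S3", "S4"])
        assert af.freqs == {"A2": 1.0} and af.n == 4

    def test_counting(self):
        af = allele_frequencies(self._matrix(), "chr1:100-200",
                                ["S1", "S2", "S3", "S4"])
        assert af.freqs == {"A1": 0.5, "A2": 0.25, "A3": 0.25}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(self._matrix(), "chr1:100-200", [])

    def test_frequencies_sum_to_one_on_random_matrices(self, rng):
        matrix = self._matrix()
        for _ in range(20):
            group = list(rng.choice(matrix.samples,
                                    size=rng.integers(1, 5), replace=False))
            af = allele_frequencies(matrix, "chr1:100-200", group)
            assert sum(af.freqs.values()) == pytest.approx(1.0)

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            AlleleFrequencies({"A1": 0.5, "A2": 0.4}, 10)
        with pytest.raises(ValueError, match="class"):
            AlleleFrequencies({"A9": 1.0}, 10)


class TestFstSegment:
    def test_identical_polymorphic_groups_have_zero_fst(self):
        x = freqs({"A1": 0.3, "A2": 0.7}, 10)
        y = freqs({"A1": 0.3, "A2": 0.7}, 10)
        res = fst_segment(x, y)
        assert res.defined and res.fst == pytest.approx(0.0, abs=1e-15)

    def test_fixed_difference_gives_fst_one(self):
        res = fst_segment(freqs({"A1": 1.0}, 10), freqs({"A3": 1.0}, 10))
        assert res.ht == pytest.approx(0.5)
        assert res.hs == pytest.approx(0.0)
        assert res.fst == pytest.approx(1.0)

    def test_hand_expanded_arithmetic_case(self):
        # x={A1:.5,A2:.5} n=10; y={A2:1} n=10
        # t = {A1:.25, A2:.75}; Ht = 1-(.0625+.5625)=.375; Hs=(.5*10+0*10)/20=.25
        res = fst_segment(freqs({"A1": 0.5, "A2": 0.5}, 10), freqs({"A2": 1.0}, 10))
        assert res.t == pytest.approx({"A1": 0.25, "A2": 0.75})
        assert res.ht == pytest.approx(0.375)
        assert res.hs == pytest.approx(0.25)
        assert res.fst == pytest.approx(1 / 3)

    def test_monomorphic_segment_is_flagged_undefined(self):
        res = fst_segment(freqs({"A2": 1.0}, 10), freqs({"A2": 1.0}, 5))
        assert not res.defined and math.isnan(res.fst)

    def test_symmetry(self, rng):
        for _ in range(50):
            xv = random_frequency_vector(rng)
            yv = random_frequency_vector(rng)
            nx, ny = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            x = freqs({c: f for c, f in zip(CN_CLASSES, xv) if f > 0}, nx)
            y = freqs({c: f for c, f in zip(CN_CLASSES, yv) if f > 0}, ny)
            a, b = fst_segment(x, y), fst_segment(y, x)
            assert a.defined == b.defined
            if a.defined:
                assert a.fst == pytest.approx(b.fst, abs=1e-14)

    def test_equal_group_sizes_reduce_t_to_plain_average(self, rng):
        for _ in range(20):
            xv = random_frequency_vector(rng)
            yv = random_frequency_vector(rng)
            x = freqs({c: f for c, f in zip(CN_CLASSES, xv) if f > 0}, 17)
            y = freqs({c: f for c, f in zip(CN_CLASSES, yv) if f > 0}, 17)
            res = fst_segment(x, y)
            for cls, t in res.t.items():
                assert t == (x.freqs.get(cls, 0.0) + y.freqs.get(cls, 0.0)) / 2

    def test_matches_independent_transcription(self, rng):
        for _ in range(200):
            xv = random_frequency_vector(rng)
            yv = random_frequency_vector(rng)
            nx, ny = int(rng.integers(1, 60)), int(rng.integers(1, 60))
            x = freqs({c: f for c, f in zip(CN_CLASSES, xv) if f > 0}, nx)
            y = freqs({c: f for c, f in zip(CN_CLASSES, yv) if f > 0}, ny)
            _, ht, hs, fst = fst_reference(xv, yv, nx, ny)
            res = fst_segment(x, y)
            assert res.ht == pytest.approx(ht, abs=1e-14)
            assert res.hs == pytest.approx(hs, abs=1e-14)
            if fst is None:
                assert not res.defined
            else:
                assert res.fst == pytest.approx(fst, abs=1e-13)


class TestFstScan:
    def _matrix_two_groups(self):
        calls = [
            make_call("X1", start=100, end=200, cn=1),
            make_call("X2", start=100, end=200, cn=1),
            make_call("Y1", start=500, end=600, cn=3),
            make_call("X1", start=900, end=950, cn=1),
            make_call("Y1", start=900, end=950, cn=1),
        ]
        segments = partition_all(merge_calls_to_cnvrs(calls))
        samples = ["X1", "X2", "Y1", "Y2"]
        return build_genotype_matrix(samples, segments, calls)

    def test_scan_returns_one_row_per_segment_in_genome_order(self):
        matrix = self._matrix_two_groups()
        table = fst_scan(matrix, ["X1", "X2"], ["Y1", "Y2"])
        assert len(table) == len(matrix.segments)
        assert list(table["start"]) == sorted(table["start"])

    def test_all_diploid_groups_are_undefined(self):
        calls = [make_call("Z9", start=10, end=20, cn=1)]
        segments = partition_all(merge_calls_to_cnvrs(calls))
        matrix = build_genotype_matrix(["X1", "X2", "Y1", "Y2"], segments, [])
        table = fst_scan(matrix, ["X1", "X2"], ["Y1", "Y2"])
        assert not table["defined"].any()

    def test_overlapping_groups_rejected(self):
        matrix = self._matrix_two_groups()
        with pytest.raises(ValueError, match="overlap"):
            fst_scan(matrix, ["X1", "X2"], ["X2", "Y1"])

    def test_vectorised_scan_matches_scalar_path(self, rng):
        matrix = self._matrix_two_groups()
        table = fst_scan(matrix, ["X1", "X2"], ["Y1", "Y2"])
        for row in table.itertuples(index=False):
            x = allele_frequencies(matrix, row.segment_id, ["X1", "X2"])
            y = allele_frequencies(matrix, row.segment_id, ["Y1", "Y2"])
            res = fst_segment(x, y)
            assert res.defined == row.defined
            assert res.ht == pytest.approx(row.ht, abs=1e-14)
            assert res.hs == pytest.approx(row.hs, abs=1e-14)
            if res.defined:
                assert res.fst == pytest.approx(row.fst, abs=1e-14)

    def test_planted_divergent_segment_ranks_first(self):
        calls = []
        # fixed loss in X at one locus, everything else shared noise
        for k in range(1, 6):
            calls.append(make_call(f"X{k}", start=1000, end=1100, cn=0))
        calls.append(make_call("X1", start=5000, end=5100, cn=1))
        calls.append(make_call("Y1", start=5000, end=5100, cn=1))
        segments = partition_all(merge_calls_to_cnvrs(calls))
        samples = [f"X{k}" for k in range(1, 6)] + [f"Y{k}" for k in range(1, 6)]
        matrix = build_genotype_matrix(samples, segments, calls)
        table = fst_scan(matrix, samples[:5], samples[5:])
        top = table.loc[table["fst"].idxmax()]
        assert top["segment_id"] == "chr1:1000-1100"


class TestSelectTopQuantile:
    def _table(self, fst_values):
        n = len(fst_values)
        return pd.DataFrame(
            {
                "segment_id": [f"chr1:{i * 10 + 1}-{i * 10 + 5}" for i in range(n)],
                "chrom": "chr1",
                "start": [i * 10 + 1 for i in range(n)],
                "end": [i * 10 + 5 for i in range(n)],
                "fst": fst_values,
                "defined": [not (isinstance(v, float) and math.isnan(v))
                            for v in fst_values],
            }
        )

    def test_thousand_distinct_values_select_five(self, rng):
        values = list(rng.permutation(np.linspace(0.0, 0.999, 1000)))
        threshold, selected = select_top_quantile(self._table(values))
        assert len(selected) == 5  # ceil(0.005 * 1000)
        assert threshold == pytest.approx(sorted(values)[-5])

    def test_ties_at_threshold_are_all_included(self):
        threshold, selected = select_top_quantile(self._table([0.4] * 10))
        assert threshold == pytest.approx(0.4)
        assert len(selected) == 10  # m=1 but all tie

    def test_threshold_equals_minimum_of_selected(self, rng):
        values = list(rng.random(400))
        threshold, selected = select_top_quantile(self._table(values))
        assert selected["fst"].min() == pytest.approx(threshold)

    def test_monomorphic_zero_policy_enlarges_denominator(self):
        # 200 distinct defined values + 800 monomorphic segments
        defined = list(np.linspace(0.01, 0.99, 200))
        values = defined + [math.nan] * 800
        exclude_thr, exclude_sel = select_top_quantile(self._table(values))
        assert len(exclude_sel) == 1  # ceil(0.005*200)=1
        assert exclude_thr == pytest.approx(max(defined))
        zero_thr, zero_sel = select_top_quantile(
            self._table(values), ScanConfig(monomorphic="zero")
        )
        assert len(zero_sel) == 5  # ceil(0.005*1000)=5 ranked rows
        assert zero_thr == pytest.approx(sorted(defined)[-5])

    def test_no_defined_fst_rejected(self):
        with pytest.raises(ValueError, match="defined"):
            select_top_quantile(self._table([math.nan, math.nan]))


class TestJoinConnected:
    def test_adjacent_intervals_join(self):
        assert join_connected([("chr1", 100, 200), ("chr1", 201, 300)]) == \
            [("chr1", 100, 300)]

    def test_intervals_with_gap_stay_separate(self):
        # the two PRODH windows are 135 kb apart and must not be joined
        ivs = [("chr17", 74154357, 74157145), ("chr17", 74292319, 74305201)]
        assert join_connected(ivs) == ivs

    def test_idempotent_and_order_invariant(self, rng):
        for _ in range(20):
            ivs = []
            for _ in range(int(rng.integers(1, 12))):
                start = int(rng.integers(1, 500))
                ivs.append((f"chr{int(rng.integers(1, 3))}", start,
                            start + int(rng.integers(0, 60))))
            joined = join_connected(ivs)
            assert join_connected(joined) == joined
            shuffled = [ivs[i] for i in rng.permutation(len(ivs))]
            assert join_connected(shuffled) == joined

    def test_different_chromosomes_never_join(self):
        assert len(join_connected([("chr1", 1, 100), ("chr2", 50, 80)])) == 2


class TestAnnotateGenes:
    # gene window fixture mirroring the five-gene cluster on chr29
    GENES = [
        GeneModel("chr29", 51180000, 51190000, "SIGIRR"),
        GeneModel("chr29", 51200000, 51230000, "PKP3"),
        GeneModel("chr29", 51250000, 51290000, "TOLLIP"),
        GeneModel("chr29", 51300000, 51310000, "IFITM1"),
        GeneModel("chr29", 51320000, 51330000, "IFITM3"),
        GeneModel("chr29", 60000000, 60010000, "ELSEWHERE"),
    ]

    def test_interval_collects_all_overlapped_genes_in_position_order(self):
        interval = ("chr29", 51174709, 51371767)
        result = annotate_genes([interval], self.GENES)
        assert result[interval] == ["SIGIRR", "PKP3", "TOLLIP", "IFITM1", "IFITM3"]

    def test_one_bp_overlap_attaches(self):
        gene = GeneModel("chr1", 50, 100, "EDGE")
        interval = ("chr1", 100, 200)
        assert annotate_genes([interval], [gene])[interval] == ["EDGE"]

    def test_gene_ending_just_before_interval_does_not_attach(self):
        gene = GeneModel("chr1", 50, 99, "EDGE")
        interval = ("chr1", 100, 200)
        assert annotate_genes([interval], [gene])[interval] == []

    def test_interval_without_genes_gets_empty_list(self):
        interval = ("chr3", 1, 10)
        assert annotate_genes([interval], self.GENES)[interval] == []


class TestRunSelectionScan:
    def test_joint_resegmentation_restricted_to_comparison_groups(self):
        calls = [
            make_call("X1", start=100, end=200, cn=1),
            make_call("Y1", start=150, end=300, cn=1),
            make_call("Z1", start=120, end=400, cn=3),  # outside both groups
        ]
        results = run_selection_scan(calls, ["X1", "X2"], ["Y1", "Y2"])
        # Z1's boundaries must not appear: segments cut only at 100/150/201/301
        assert results.matrix.segment_ids == \
            ["chr1:100-149", "chr1:150-200", "chr1:201-300"]

    def test_gene_annotation_attached_when_genes_supplied(self):
        calls = [make_call(f"X{k}", start=100, end=200, cn=0) for k in (1, 2)]
        genes = [GeneModel("chr1", 180, 260, "GENE1")]
        results = run_selection_scan(calls, ["X1", "X2"], ["Y1", "Y2"], genes=genes)
        assert results.genes is not None
        assert results.genes[results.joined[0]] == ["GENE1"]
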