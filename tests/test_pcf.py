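import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from katacall import (
    PcfParams,
    VariantTable,
    compute_imd,
    kata,
    pcf_objective,
    pcf_segment,
    read_foci_bed,
    write_foci_bed,
)
from katacall.pcf import KataegisFocus, PcfWarning


def exhaustive_best_objective(values, gamma, kmin):
    """Independent oracle: enumerate every valid contiguous segmentation."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    best = np.inf
    for nb in range(0, n):
        for bps in itertools.combinations(range(1, n), nb):
            bounds = [0, *bps, n]
            if any(b - a < kmin for a, b in zip(bounds, bounds[1:])):
                continue
            cost = gamma * nb
            for a, b in zip(bounds, bounds[1:]):
                seg = v[a:b]
                cost += float(np.sum((seg - seg.mean()) ** 2))
            best = min(best, cost)
    return best


def _table(positions, chrom="chr1"):
    return VariantTable.from_records(
        [(chrom, int(p), "C", "T") for p in positions], "t"
    )


class TestPcfSegment:
    def test_constant_input_is_one_segment(self):
        assert pcf_segment([2, 2, 2, 2], gamma=5.0) == [(0, 3, 2.0)]

    def test_step_split_when_penalty_is_cheap(self):
        segs = pcf_segment([0, 0, 0, 3, 3, 3], gamma=1.0, kmin=2)
        assert segs == [(0, 2, 0.0), (3, 5, 3.0)]
        assert pcf_objective([0, 0, 0, 3, 3, 3], segs, gamma=1.0) == pytest.approx(1.0)
        one_seg = [(0, 5, 1.5)]
        assert pcf_objective([0, 0, 0, 3, 3, 3], one_seg, gamma=1.0) == pytest.approx(13.5)

    def test_step_merges_when_penalty_dominates(self):
        assert pcf_segment([0, 0, 0, 3, 3, 3], gamma=100.0, kmin=2) == [(0, 5, 1.5)]

    def test_segment_means_are_arithmetic_means(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        for i, j, mean in pcf_segment(v, gamma=0.5):
            assert mean == pytest.approx(v[i : j + 1].mean())

    def test_segments_tile_the_index_range(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(8, 1, 20)])
        segs = pcf_segment(v, gamma=2.0, kmin=3)
        assert segs[0][0] == 0 and segs[-1][1] == len(v) - 1
        for (i1, j1, _), (i2, j2, _) in zip(segs, segs[1:]):
            assert i2 == j1 + 1
        assert all(j - i + 1 >= 3 for i, j, _ in segs)

    def test_objective_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            kmin = int(rng.integers(1, 4))
            gamma = float(rng.choice([0.5, 2.0, 10.0]))
            v = np.round(rng.normal(size=n) * rng.choice([1, 4]), 3)
            if n < kmin:
                continue
            segs = pcf_segment(v, gamma=gamma, kmin=kmin)
            dp = pcf_objective(v, segs, gamma)
            oracle = exhaustive_best_objective(v, gamma, kmin)
            assert dp == pytest.approx(oracle, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10**6))
    def test_gamma_monotonicity_never_adds_segments(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=25) * 3
        counts = [len(pcf_segment(v, gamma=g)) for g in (0.5, 1, 2, 5, 10, 50)]
        assert counts == sorted(counts, reverse=True)

    def test_short_series_returns_single_segment_with_note(self):
        with pytest.warns(PcfWarning):
            segs = pcf_segment([1.0], gamma=1.0, kmin=2)
        assert segs == [(0, 0, 1.0)]

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            pcf_segment([1.0, np.nan, 2.0], gamma=1.0)

    def test_tie_broken_toward_fewer_segments(self):
        # all-equal values: every segmentation has SSE 0; fewer wins
        assert len(pcf_segment([5.0] * 8, gamma=1.0, kmin=1)) == 1


class TestKata:
    def test_dense_run_called_as_single_focus(self):
        positions = [1000 + 100 * i for i in range(7)]
        result = kata(compute_imd(_table(positions)))
        assert len(result.foci) == 1
        focus = result.foci[0]
        assert focus.n_mut == 7
        assert focus.mean_imd == pytest.approx(100.0)
        assert (focus.start_pos, focus.end_pos) == (1000, 1600)
        assert focus.span_bp == 601

    def test_uniform_sparse_spacing_yields_no_foci(self):
        positions = [10_000 * (i + 1) for i in range(100)]
        result = kata(compute_imd(_table(positions)))
        assert result.foci == []
        assert len(result.segments) == 1  # constant log-IMD series

    def test_empty_imd_warns_and_returns_empty(self):
        import pandas as pd

        from katacall.imd import ImdTable

        empty = ImdTable(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "imd", "subst_class"]),
            sample_id="e",
        )
        with pytest.warns(PcfWarning):
            result = kata(empty)
        assert result.foci == [] and result.segments == []

    def test_segment_mutation_counts_tile_variants(self):
        rng = np.random.default_rng(8)
        # sparse background with an embedded dense cluster
        positions = sorted(
            set(rng.integers(1, 5_000_000, 60)) | {100_000 + 90 * i for i in range(12)}
        )
        imd = compute_imd(_table(positions))
        result = kata(imd)
        n_variants = len(imd)
        total = sum(s.n_mut for s in result.segments)
        assert total == n_variants + (len(result.segments) - 1)
        # consecutive segments share their boundary variant
        for a, b in zip(result.segments, result.segments[1:]):
            assert b.start_pos == a.end_pos

    def test_every_focus_satisfies_both_thresholds(self):
        rng = np.random.default_rng(9)
        positions = sorted(
            set(rng.integers(1, 2_000_000, 50)) | {500_000 + 70 * i for i in range(9)}
        )
        params = PcfParams()
        result = kata(compute_imd(_table(positions)), params)
        focus_keys = {(f.chrom, f.start_pos, f.end_pos) for f in result.foci}
        for s in result.segments:
            qualifies = s.n_mut >= params.min_mut and s.mean_imd <= params.max_mean_imd
            assert ((s.chrom, s.start_pos, s.end_pos) in focus_keys) == qualifies

    @given(
        st.integers(min_value=7, max_value=16),
        st.integers(min_value=20, max_value=150),
        st.integers(min_value=0, max_value=10**5),
    )
    def test_planted_cluster_in_sparse_background_is_always_called(
        self, n_focus, spacing, seed
    ):
        """A >=7-variant cluster at <=150-bp spacing inside a >=100x sparser
        background must always be called with the default parameters."""
        rng = np.random.default_rng(seed)
        bg = np.cumsum(rng.integers(20_000, 200_000, size=30)) + 1
        start = int(bg[10]) + 15_000
        cluster = [start + spacing * i for i in range(n_focus)]
        positions = sorted(set(bg.tolist()) | set(cluster))
        result = kata(compute_imd(_table(positions)))
        assert any(
            f.start_pos <= cluster[-1] and f.end_pos >= cluster[0] for f in result.foci
        )

    def test_params_must_be_positive(self):
        with pytest.raises(ValueError):
            PcfParams(gamma=0)
        with pytest.raises(ValueError):
            PcfParams(max_mean_imd=-1)


class TestFociBed:
    def test_bed_line_uses_zero_based_half_open_coordinates(self, tmp_path):
        focus = KataegisFocus(
            chrom="chr1", start_pos=1000, end_pos=1600, n_mut=7,
            mean_imd=100.0, mean_log10_imd=2.0, focus_id=1,
        )
        path = write_foci_bed([focus], tmp_path / "f.bed")
        assert path.read_text() == "chr1\t999\t1600\tfocus_1\t7\n"

    def test_empty_focus_list_gives_empty_file(self, tmp_path):
        path = write_foci_bed([], tmp_path / "e.bed")
        assert path.read_text() == ""

    def test_intervals_round_trip_through_bed(self, tmp_path):
        foci = [
            KataegisFocus("chr1", 1000, 1600, 7, 100.0, 2.0, focus_id=1),
            KataegisFocus("chr2", 5, 999, 12, 90.0, 1.9, focus_id=2),
        ]
        back = read_foci_bed(write_foci_bed(foci, tmp_path / "rt.bed"))
        assert [(f.chrom, f.start_pos, f.end_pos, f.n_mut) for f in back] == [
            (f.chrom, f.start_pos, f.end_pos, f.n_mut) for f in foci
        ]
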