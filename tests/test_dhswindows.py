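import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhsevo.dhswindows import (
    FilterConfig,
    TilingConfig,
    WindowSet,
    count_cuts,
    reciprocal_count_filter,
    sharp_peak_filter,
    tile_region,
    union_top_peaks,
    zero_count_filter,
)
from dhsevo.ioformats import CountMatrix, GenomicInterval, SampleMeta, ScoredPeakSet


def iv(s, e, chrom="chr1"):
    return GenomicInterval("hg", chrom, s, e)


def brute_force_tiling(L, window=300, overlap=100, edge=0.10):
    """Direct enumeration of the tiling rule, independent of tile_region."""
    if L <= window:
        mid = L // 2
        return [mid - window // 2]
    step = window - overlap
    n = (L - window) // step + 1
    span = window + (n - 1) * step
    leftover = L - span
    if leftover // 2 < edge * L:
        off0 = leftover // 2
        return [off0 + i * step for i in range(n)]
    s = (L - window) / n
    return [int(np.round(i * s)) for i in range(n + 1)]


class TestTileRegion:
    def test_exact_window_is_itself(self):
        out = tile_region(iv(1000, 1300))
        assert [(w.start, w.end) for w in out] == [(1000, 1300)]

    def test_l1000_four_centered_windows(self):
        out = tile_region(iv(0, 1000))
        assert [w.start for w in out] == [50, 250, 450, 650]
        assert all(len(w) == 300 for w in out)

    def test_l450_exact_cover_two_windows(self):
        out = tile_region(iv(0, 450))
        assert [w.start for w in out] == [0, 150]
        assert out[-1].end == 450

    def test_small_region_expanded_centered(self):
        out = tile_region(iv(1000, 1100))
        (w,) = out
        assert len(w) == 300 and w.start == 1050 - 150

    def test_expansion_clipped_at_chrom_start(self):
        (w,) = tile_region(iv(10, 110))
        assert w.start == 0 and w.end == 300

    def test_oracle_all_lengths(self):
        cfg = TilingConfig()
        for L in range(301, 2001):
            got = [w.start for w in tile_region(iv(0, L), cfg)]
            assert got == brute_force_tiling(L), f"L={L}"
            ws = tile_region(iv(0, L), cfg)
            assert all(len(w) == 300 for w in ws)
            # coverage >= (1 - 2*edge) * L and windows never overrun the region
            covered = min(L, ws[-1].end) - max(0, ws[0].start)
            assert covered >= (1 - 2 * cfg.edge_threshold) * L - 1
            assert ws[0].start >= 0 and ws[-1].end <= L


class TestTilingProperties:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(start=st.integers(0, 10**7), L=st.integers(301, 50_000))
    def test_windows_cover_and_stay_inside(self, start, L):
        cfg = TilingConfig()
        ws = tile_region(iv(start, start + L), cfg)
        assert all(len(w) == cfg.window for w in ws)
        assert ws[0].start >= start and ws[-1].end <= start + L
        covered = ws[-1].end - ws[0].start
        assert covered >= (1 - 2 * cfg.edge_threshold) * L - 1
        # consecutive windows always overlap or abut (no gaps)
        for a, b in zip(ws, ws[1:]):
            assert b.start <= a.end

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        native=st.integers(0, 10_000),
        delta=st.integers(-2000, 2000),
    )
    def test_reciprocal_filter_symmetric_band(self, native, delta):
        lifted = native + delta
        if lifted < 0:
            return
        kept = reciprocal_count_filter(native, lifted)
        assert kept == (abs(lifted - native) <= 0.10 * native if native else lifted == 0)


class TestUnionTopPeaks:
    def sample(self, name="s1"):
        return SampleMeta(name, "human", "fibroblast", name)

    def test_single_sample_merges(self):
        ps = ScoredPeakSet(self.sample(), [(iv(100, 400), 5.0), (iv(300, 600), 4.0)])
        out = union_top_peaks([ps], k=10)
        assert [(o.start, o.end) for o in out] == [(100, 600)]

    def test_cross_sample_merge(self):
        a = ScoredPeakSet(self.sample("a"), [(iv(100, 400), 1.0)])
        b = ScoredPeakSet(SampleMeta("b", "chimp", "fibroblast", "b"), [(iv(300, 600), 1.0)])
        out = union_top_peaks([a, b], k=10)
        assert [(o.start, o.end) for o in out] == [(100, 600)]

    def test_top_k_by_score(self):
        peaks = [(iv(i * 1000, i * 1000 + 100), float(5 - i)) for i in range(5)]
        ps = ScoredPeakSet(self.sample(), peaks)
        out = union_top_peaks([ps], k=2)
        assert [(o.start, o.end) for o in out] == [(0, 100), (1000, 1100)]

    def test_k_nonpositive_errors(self):
        ps = ScoredPeakSet(self.sample(), [(iv(0, 100), 1.0)])
        with pytest.raises(ValueError):
            union_top_peaks([ps], k=0)


class TestCountCuts:
    def test_half_open_boundary(self):
        ws = WindowSet([(iv(100, 400), "r0")])
        cuts = {"s1": {"chr1": np.array([99, 100, 399, 400])}}
        cm = count_cuts(ws, cuts)
        assert cm.values()[0, 0] == 2  # 100 and 399 in; 99 and 400 out

    def test_no_cuts_zero(self):
        ws = WindowSet([(iv(0, 300), "r0"), (iv(500, 800), "r1")])
        cm = count_cuts(ws, {"s1": {}})
        assert (cm.values() == 0).all()

    def test_counts_inside_only(self):
        ws = WindowSet([(iv(100, 400), "r0")])
        cuts = {"s1": {"chr1": np.array([10, 150, 200, 250, 300, 350, 900])}}
        assert count_cuts(ws, cuts).values()[0, 0] == 5


class TestZeroCountFilter:
    def meta(self):
        return [
            SampleMeta(f"{sp}{i}", sp, "fibroblast", f"{sp}{i}")
            for sp in ("human", "chimp", "macaque")
            for i in (1, 2, 3)
        ]

    def make(self, rows):
        df = pd.DataFrame(rows, columns=[m.sample_id for m in self.meta()])
        return CountMatrix(df)

    def test_species_without_signal_dropped(self):
        cm = self.make([[0, 0, 0, 5, 5, 5, 9, 9, 9]])
        assert not zero_count_filter(cm, self.meta())[0]

    def test_minimal_one_read_per_species_kept(self):
        cm = self.make([[1, 0, 0, 0, 1, 0, 0, 0, 1]])
        assert zero_count_filter(cm, self.meta())[0]

    def test_all_positive_kept(self):
        cm = self.make([[3] * 9])
        assert zero_count_filter(cm, self.meta())[0]


class TestSharpPeakFilter:
    def test_all_reads_one_position_flagged(self):
        region = iv(0, 300)
        assert sharp_peak_filter(region, {"s": np.full(10, 150)})

    def test_uniform_reads_not_flagged(self):
        region = iv(0, 300)
        assert not sharp_peak_filter(region, {"s": np.arange(300)})

    def test_just_under_threshold_not_flagged(self):
        # 74 of 100 reads in one 30 bp span: below the 75% rule
        pos = np.concatenate([np.full(74, 150), np.arange(26)])
        assert not sharp_peak_filter(iv(0, 300), {"s": pos})

    def test_exactly_threshold_flagged(self):
        pos = np.concatenate([np.full(75, 150), np.arange(25)])
        assert sharp_peak_filter(iv(0, 300), {"s": pos})

    def test_low_count_samples_cannot_trigger(self):
        # two coincident basal reads are not evidence of a PCR artifact
        assert not sharp_peak_filter(iv(0, 300), {"s": np.array([150, 151])})

    def test_zero_reads_everywhere_not_flagged(self):
        assert not sharp_peak_filter(iv(0, 300), {"s": np.array([])})


class TestReciprocalCountFilter:
    @pytest.mark.parametrize(
        "native,lifted,kept",
        [(100, 105, True), (100, 110, True), (100, 120, False), (0, 0, True), (0, 3, False)],
    )
    def test_tolerance(self, native, lifted, kept):
        assert reciprocal_count_filter(native, lifted) is kept
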