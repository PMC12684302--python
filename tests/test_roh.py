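import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gerode import (
    DatingParams,
    GenomeLayout,
    RoHParams,
    RoHSegment,
    SnpRoHParams,
    bin_roh_by_generation,
    call_roh_snp,
    call_roh_windows,
    froh,
    het_froh_correlation,
    merge_segments,
    roh_age_generations,
)
from gerode.roh import _snp_eligibility

from conftest import track_from_counts, vt_from_arrays

LAYOUT_100MB = GenomeLayout(scaffolds=(("scaf1", 100_000_000),))


# ---------------------------------------------------------------------------
# Brute-force oracles, written independently of the implementation


def oracle_window_caller(track, params):
    """Linear scan over every window, per individual."""
    segments = []
    for sw in track.scaffolds.values():
        he = sw.he(track.denominator, track.window_bp)
        mf = sw.missing_fraction()
        for j, ind in enumerate(track.samples):
            thr = params.low_het_factor * track.mean_he[ind]
            run = []
            for i in range(len(sw.starts) + 1):
                ok = (
                    i < len(sw.starts)
                    and mf[i, j] <= params.max_window_missing
                    and sw.n_callable[i, j] > 0
                    and np.isfinite(he[i, j])
                    and he[i, j] < thr
                )
                if ok:
                    run.append(i)
                else:
                    if len(run) >= params.min_consecutive_windows:
                        start = int(sw.starts[run[0]]) + 1
                        end = int(sw.ends[run[-1]])
                        if end - start + 1 >= params.min_length_bp:
                            segments.append((ind, sw.scaffold, start, end, len(run)))
                    run = []
    return sorted(segments)


def oracle_snp_caller(g, pos, params):
    """Window-by-window scan of one individual's genotype string."""
    n = len(g)
    W = params.window_snps
    if n < W:
        return []
    passes = []
    for i in range(n - W + 1):
        w = g[i:i + W]
        passes.append(
            int((w == 1).sum()) <= params.max_het_per_window
            and int((w == -1).sum()) <= params.max_missing_per_window
        )
    eligible = []
    for j in range(n):
        overlapping = [passes[i] for i in range(max(0, j - W + 1), min(j, n - W) + 1)]
        eligible.append(sum(overlapping) / len(overlapping) > params.hit_threshold)
    segments = []
    run = []
    for j in range(n + 1):
        if j < n and eligible[j]:
            run.append(j)
        else:
            if len(run) >= params.min_snp_per_roh:
                start, end = int(pos[run[0]]), int(pos[run[-1]])
                if end - start + 1 >= params.min_length_bp:
                    segments.append((start, end, len(run)))
            run = []
    return segments


# ---------------------------------------------------------------------------
# Window caller


class TestWindowCaller:
    def _uniform_track(self, low_windows, n_total=40, base_het=50, n_callable=1000):
        """base He 0.05 everywhere except zero-het in `low_windows`."""
        n_het = np.full((n_total, 1), base_het)
        n_het[list(low_windows), 0] = 0
        return track_from_counts(n_het=n_het, n_callable=np.full(n_total, n_callable))

    def test_twelve_low_windows_one_600kb_segment(self):
        track = self._uniform_track(range(10, 22))
        segs = call_roh_windows(track)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end) == (10 * 50_000 + 1, 22 * 50_000)
        assert s.length_bp == 600_000 and s.n_support == 12

    def test_nine_low_windows_no_segment(self):
        assert call_roh_windows(self._uniform_track(range(10, 19))) == []

    def test_uniform_track_no_segment(self):
        track = track_from_counts(n_het=np.full((40, 1), 50), n_callable=np.full(40, 1000))
        assert call_roh_windows(track) == []

    def test_high_missing_window_breaks_run(self):
        n_het = np.zeros((30, 1), dtype=int)
        n_het[:5] = 50  # establish a non-zero mean He
        n_callable = np.full((30, 1), 1000)
        n_callable[17, 0] = 100  # 0.9 missing vs n_sites 1000 -> unusable
        track = track_from_counts(n_het=n_het, n_callable=n_callable,
                                  n_sites=np.full(30, 1000))
        segs = call_roh_windows(track)
        # low-het run 5..29 is split at window 17; left part 12 windows, right 12
        assert [(s.n_support) for s in segs] == [12, 12]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n_win = int(rng.integers(20, 200))
        n_ind = int(rng.integers(1, 4))
        n_call = rng.integers(0, 300, size=(n_win, n_ind))
        n_het = rng.binomial(n_call, rng.uniform(0.001, 0.05))
        # sprinkle low-het stretches so segments actually occur
        for _ in range(int(rng.integers(1, 4))):
            a = int(rng.integers(0, n_win))
            b = min(n_win, a + int(rng.integers(5, 30)))
            n_het[a:b] = 0
        track = track_from_counts(n_het=n_het, n_callable=n_call,
                                  n_sites=np.full(n_win, 300))
        params = RoHParams(
            low_het_factor=float(rng.uniform(0.1, 0.5)),
            min_consecutive_windows=int(rng.integers(2, 12)),
            max_window_missing=float(rng.uniform(0.3, 0.9)),
            min_length_bp=int(rng.choice([50_000, 300_000, 500_000])),
        )
        got = sorted(
            (s.individual, s.scaffold, s.start, s.end, s.n_support)
            for s in call_roh_windows(track, params)
        )
        assert got == oracle_window_caller(track, params)


# ---------------------------------------------------------------------------
# SNP caller


class TestSnpCaller:
    def test_long_homozygous_stretch_called(self):
        # 300 homozygous SNPs spanning ~800 kb
        pos = np.linspace(1, 800_000, 300).astype(np.int64)
        vt = vt_from_arrays(pos, np.zeros((300, 1), dtype=np.int8))
        segs = call_roh_snp(vt)
        assert len(segs) == 1
        assert segs[0].n_support == 300
        assert segs[0].length_bp >= 500_000

    def test_short_span_rejected(self):
        pos = np.linspace(1, 300_000, 300).astype(np.int64)
        vt = vt_from_arrays(pos, np.zeros((300, 1), dtype=np.int8))
        assert call_roh_snp(vt) == []

    def test_alternating_het_no_roh(self):
        pos = np.arange(1, 1001) * 2000
        gt = np.tile([0, 1], 500).astype(np.int8)[:, None]
        vt = vt_from_arrays(pos, gt)
        assert call_roh_snp(vt) == []

    def test_scaffold_with_too_few_snps_skipped(self):
        pos = np.arange(1, 51) * 1000
        vt = vt_from_arrays(pos, np.zeros((50, 1), dtype=np.int8))
        assert call_roh_snp(vt) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_strings(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(150, 2500))
        pos = np.sort(rng.choice(np.arange(1, 4_000_000), size=n, replace=False))
        p_het = float(rng.uniform(0.0, 0.2))
        g = rng.choice([0, 1, 2, -1], size=n,
                       p=[0.82 - p_het, p_het, 0.15, 0.03]).astype(np.int8)
        # plant a homozygous stretch
        a = int(rng.integers(0, max(1, n - 300)))
        g[a:a + int(rng.integers(100, 300))] = rng.choice([0, 2])
        params = SnpRoHParams(
            min_snp_per_roh=int(rng.integers(20, 120)),
            window_snps=int(rng.integers(20, 120)),
            max_het_per_window=int(rng.integers(0, 3)),
            max_missing_per_window=int(rng.integers(0, 20)),
            min_length_bp=int(rng.choice([10_000, 200_000, 500_000])),
            hit_threshold=float(rng.uniform(0.01, 0.5)),
        )
        vt = vt_from_arrays(pos, g[:, None])
        got = [(s.start, s.end, s.n_support) for s in call_roh_snp(vt, params)]
        assert got == oracle_snp_caller(g, pos, params)


# ---------------------------------------------------------------------------
# F_RoH


class TestFroh:
    def test_no_segments_zero(self):
        assert froh([], LAYOUT_100MB, individuals=["i1"])["i1"] == 0.0

    def test_two_segments_arithmetic(self):
        segs = [RoHSegment("i1", "scaf1", 1, 2_000_000, 1),
                RoHSegment("i1", "scaf1", 10_000_001, 13_000_000, 1)]
        assert froh(segs, LAYOUT_100MB)["i1"] == pytest.approx(0.05)

    def test_full_genome_is_one(self):
        segs = [RoHSegment("i1", "scaf1", 1, 100_000_000, 1)]
        assert froh(segs, LAYOUT_100MB)["i1"] == pytest.approx(1.0)

    def test_overlaps_merged(self):
        segs = [RoHSegment("i1", "scaf1", 1, 1_000_000, 1),
                RoHSegment("i1", "scaf1", 500_001, 2_000_000, 1)]
        assert froh(segs, LAYOUT_100MB)["i1"] == pytest.approx(0.02)

    @given(st.integers(min_value=2, max_value=9_999_999))
    def test_split_invariance(self, cut):
        whole = [RoHSegment("i1", "scaf1", 1, 10_000_001, 1)]
        split = [RoHSegment("i1", "scaf1", 1, cut, 1),
                 RoHSegment("i1", "scaf1", cut + 1, 10_000_001, 1)]
        assert froh(whole, LAYOUT_100MB)["i1"] == pytest.approx(froh(split, LAYOUT_100MB)["i1"])

    def test_per_scaffold_values(self):
        lay = GenomeLayout(scaffolds=(("a", 10_000_000), ("b", 10_000_000)))
        segs = [RoHSegment("i1", "a", 1, 5_000_000, 1)]
        per = froh(segs, lay, per_scaffold=True).set_index("scaffold")
        assert per.loc["a", "froh"] == pytest.approx(0.5)
        assert per.loc["b", "froh"] == 0.0

    def test_zero_genome_raises(self):
        lay = GenomeLayout(scaffolds=(("a", 1_000_000),))  # below 5 Mb cutoff
        with pytest.raises(ValueError):
            froh([], lay)


def test_lower_threshold_never_increases_roh():
    rng = np.random.default_rng(5)
    n_call = np.full((120, 2), 500)
    n_het = rng.binomial(500, 0.02, size=(120, 2))
    n_het[30:60] = rng.binomial(500, 0.001, size=(30, 2))
    track = track_from_counts(n_het=n_het, n_callable=n_call, n_sites=np.full(120, 500))
    totals = []
    for f in (0.5, 0.4, 0.3, 0.2, 0.1, 0.05):
        segs = call_roh_windows(track, RoHParams(low_het_factor=f, min_length_bp=100_000,
                                                 min_consecutive_windows=2))
        totals.append(sum(s.length_bp for s in segs))
    assert all(a >= b for a, b in zip(totals, totals[1:]))


# ---------------------------------------------------------------------------
# Dating and binning


class TestDating:
    def test_ten_mb_is_five_generations(self):
        assert roh_age_generations(10.0, 1.0) == pytest.approx(5.0)

    def test_half_mb_is_hundred_generations(self):
        assert roh_age_generations(0.5, 1.0) == pytest.approx(100.0)

    def test_doubling_r_halves_g(self):
        assert roh_age_generations(3.0, 2.0) == pytest.approx(roh_age_generations(3.0, 1.0) / 2)

    @pytest.mark.parametrize("L,r", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_non_positive_inputs_raise(self, L, r):
        with pytest.raises(ValueError):
            roh_age_generations(L, r)


class TestBinning:
    def test_boundary_goes_to_older_bin(self):
        segs = [RoHSegment("i1", "a", 1, 10_000_000, 1)]  # g = 5 exactly
        out = bin_roh_by_generation(segs)
        assert list(out[["bin_left", "bin_right"]].iloc[0]) == [5, 10]
        assert out["total_mb"].iloc[0] == pytest.approx(10.0)

    def test_no_segments_empty(self):
        assert len(bin_roh_by_generation([])) == 0

    def test_equal_g_segments_sum(self):
        segs = [RoHSegment("i1", "a", 1, 8_000_000, 1),
                RoHSegment("i1", "b", 1, 8_000_000, 1)]
        out = bin_roh_by_generation(segs)
        assert len(out) == 1 and out["total_mb"].iloc[0] == pytest.approx(16.0)
        assert out["n_segments"].iloc[0] == 2

    def test_bin_totals_sum_to_total_length(self):
        rng = np.random.default_rng(3)
        segs = [RoHSegment("i1", "a", 1, int(rng.integers(500_000, 30_000_000)), 1)
                for _ in range(50)]
        out = bin_roh_by_generation(segs)
        assert out["total_mb"].sum() == pytest.approx(sum(s.length_mb for s in segs))


class TestHetFrohCorrelation:
    def test_perfect_anticorrelation(self):
        het = pd.Series([0.003, 0.002, 0.001], index=list("abc"))
        fr = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        r, p = het_froh_correlation(het, fr)
        assert r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        v = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        r, _ = het_froh_correlation(v, v + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = np.array([0.1, 0.25, 0.3, 0.45, 0.5])
        y = np.array([2.0, 1.9, 1.5, 1.2, 1.1])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, p = het_froh_correlation(
            pd.Series(x, index=list("abcde")), pd.Series(y, index=list("abcde"))
        )
        assert r == pytest.approx(r_hand)
        assert 0 <= p <= 1

    def test_errors(self):
        with pytest.raises(ValueError):
            het_froh_correlation(pd.Series([1.0, 2.0], index=list("ab")),
                                 pd.Series([1.0, 2.0], index=list("ab")))
        with pytest.raises(ValueError):
            het_froh_correlation(pd.Series([1.0, 1.0, 1.0], index=list("abc")),
                                 pd.Series([1.0, 2.0, 3.0], index=list("abc")))
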