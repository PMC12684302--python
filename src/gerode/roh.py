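"""Runs-of-homozygosity calling, F_RoH, and tract dating.

Two callers are provided.  The window caller classifies 50-kb windows as
low-heterozygosity when their He falls below one fifth of the
individual's mean He and requires at least 10 consecutive qualifying
windows; the SNP caller slides a 100-SNP window (at most 1 heterozygote
and 15 missing calls per window) and marks SNPs whose passing-window
hit rate exceeds a threshold, PLINK-style.  Both enforce a 500-kb
minimum tract length: shorter tracts reflect background relatedness
rather than recent consanguinity.

A tract of length L Mb is dated with g = 100 / (2 r L) generations since
the two haplotypes' common ancestor, with r in cM/Mb (default 1, an
average mammalian recombination rate): a 10-Mb tract points to an
inbreeding event within the last 5 generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, GenomeLayout, VariantTable
from .window_het import WindowTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoHParams:
    """Window-caller thresholds."""

    low_het_factor: float = 0.2          # fraction of the individual's mean He
    min_consecutive_windows: int = 10
    max_window_missing: float = 0.7
    min_length_bp: int = 500_000
    caller: str = "window"

    def __post_init__(self):
        if min(self.low_het_factor, self.min_consecutive_windows, self.min_length_bp) <= 0:
            raise ValueError("RoHParams thresholds must be positive")


@dataclass(frozen=True)
class SnpRoHParams:
    """SNP-caller thresholds (PLINK-style parameterization)."""

    min_snp_per_roh: int = 100
    window_snps: int = 100
    max_het_per_window: int = 1
    max_missing_per_window: int = 15
    min_length_bp: int = 500_000
    hit_threshold: float = 0.05          # fraction of overlapping windows passing
    caller: str = "snp"

    def __post_init__(self):
        if self.window_snps < self.max_het_per_window:
            raise ValueError("window_snps must be >= max_het_per_window")


@dataclass(frozen=True)
class RoHSegment:
    """One homozygous tract; coordinates 1-based inclusive."""

    individual: str
    scaffold: str
    start: int
    end: int
    n_support: int               # qualifying windows or SNPs
    caller: str = "window"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass(frozen=True)
class DatingParams:
    r: float = 1.0               # recombination rate, cM/Mb
    bin_width: int = 5           # generations per bin

    def __post_init__(self):
        if self.r <= 0 or self.bin_width <= 0:
            raise ValueError("r and bin_width must be positive")


def segments_to_frame(segments: list[RoHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": s.individual,
                "scaffold": s.scaffold,
                "start": s.start,
                "end": s.end,
                "length_bp": s.length_bp,
                "length_mb": s.length_mb,
                "n_support": s.n_support,
                "caller": s.caller,
            }
            for s in segments
        ],
        columns=[
            "individual", "scaffold", "start", "end",
            "length_bp", "length_mb", "n_support", "caller",
        ],
    )


# ---------------------------------------------------------------------------
# Window caller


def _runs(mask: np.ndarray):
    """Yield (start_index, end_index_inclusive) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b])


def call_roh_windows(track: WindowTrack, params: RoHParams = RoHParams()) -> list[RoHSegment]:
    """Call RoH as runs of consecutive low-He, usable windows.

    A window qualifies when usable (missing fraction ≤
    ``max_window_missing``) and He < ``low_het_factor`` × the
    individual's mean He; runs of at least ``min_consecutive_windows``
    qualifying windows become segments spanning the first window's start
    to the last window's end.  Unusable windows break runs (no
    bridging), runs never cross scaffolds, and segments shorter than
    ``min_length_bp`` are dropped.
    """
    if params.max_window_missing != track.usable_max_missing:
        # recompute usability at the caller's cutoff
        pass
    if params.min_consecutive_windows * track.window_bp < params.min_length_bp:
        log.info(
            "call_roh_windows: %d windows of %d bp is below min_length_bp %d; "
            "length filter dominates",
            params.min_consecutive_windows, track.window_bp, params.min_length_bp,
        )
    segments: list[RoHSegment] = []
    mean_he = track.mean_he
    for sw in track.scaffolds.values():
        he = sw.he(track.denominator, track.window_bp)
        usable = (sw.missing_fraction() <= params.max_window_missing) & (sw.n_callable > 0)
        for j, ind in enumerate(track.samples):
            thr = params.low_het_factor * mean_he[ind]
            if not np.isfinite(thr):
                continue
            low = usable[:, j] & (he[:, j] < thr)
            for a, b in _runs(low):
                if b - a + 1 < params.min_consecutive_windows:
                    continue
                start = int(sw.starts[a]) + 1
                end = int(sw.ends[b])
                if end - start + 1 < params.min_length_bp:
                    continue
                segments.append(
                    RoHSegment(
                        individual=ind, scaffold=sw.scaffold,
                        start=start, end=end,
                        n_support=b - a + 1, caller=params.caller,
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# SNP caller


def call_roh_snp(
    vt: VariantTable,
    params: SnpRoHParams = SnpRoHParams(),
    layout: GenomeLayout | None = None,
) -> list[RoHSegment]:
    """Call RoH from the SNP sequence with a sliding 100-SNP window.

    For each individual and scaffold a window of ``window_snps``
    consecutive SNPs slides one SNP at a time; it passes with at most
    ``max_het_per_window`` heterozygotes and ``max_missing_per_window``
    missing calls.  A SNP is RoH-eligible when the fraction of
    overlapping windows that pass exceeds ``hit_threshold``; maximal
    eligible stretches with at least ``min_snp_per_roh`` SNPs spanning
    at least ``min_length_bp`` bp become segments (first to last SNP).
    """
    names = layout.included_names if layout is not None else list(dict.fromkeys(vt.sites["scaffold"]))
    scaffold_col = vt.sites["scaffold"].to_numpy()
    pos_all = vt.sites["pos"].to_numpy()
    W = params.window_snps
    segments: list[RoHSegment] = []

    for name in names:
        on = scaffold_col == name
        pos = pos_all[on]
        n = pos.size
        if n < W:
            if n:
                log.info("call_roh_snp: scaffold %s has %d < %d SNPs; skipped", name, n, W)
            continue
        gt = vt.gt[on]
        for j, ind in enumerate(vt.samples):
            g = gt[:, j]
            elig = _snp_eligibility(g, params)
            for a, b in _runs(elig):
                if b - a + 1 < params.min_snp_per_roh:
                    continue
                start, end = int(pos[a]), int(pos[b])
                if end - start + 1 < params.min_length_bp:
                    continue
                segments.append(
                    RoHSegment(
                        individual=ind, scaffold=name, start=start, end=end,
                        n_support=b - a + 1, caller=params.caller,
                    )
                )
    return segments


def _snp_eligibility(g: np.ndarray, params: SnpRoHParams) -> np.ndarray:
    """Per-SNP RoH eligibility from the hit rate of passing windows."""
    n = g.size
    W = params.window_snps
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(mis)))
    hsum = ch[W:] - ch[:-W]                      # window i covers SNPs i..i+W-1
    msum = cm[W:] - cm[:-W]
    passes = (hsum <= params.max_het_per_window) & (msum <= params.max_missing_per_window)
    cp = np.concatenate(([0], np.cumsum(passes.astype(np.int64))))
    j = np.arange(n)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n - W)
    hits = cp[hi + 1] - cp[lo]
    frac = hits / (hi - lo + 1)
    return frac > params.hit_threshold


# ---------------------------------------------------------------------------
# F_RoH and dating


def merge_segments(segments: list[RoHSegment]) -> list[RoHSegment]:
    """Merge overlapping segments per individual and scaffold."""
    out: list[RoHSegment] = []
    by_key: dict[tuple[str, str], list[RoHSegment]] = {}
    for s in segments:
        by_key.setdefault((s.individual, s.scaffold), []).append(s)
    for (ind, scaf), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        cur_start, cur_end, cur_sup, cur_caller = segs[0].start, segs[0].end, segs[0].n_support, segs[0].caller
        for s in segs[1:]:
            if s.start <= cur_end:
                cur_end = max(cur_end, s.end)
                cur_sup += s.n_support
            else:
                out.append(RoHSegment(ind, scaf, cur_start, cur_end, cur_sup, cur_caller))
                cur_start, cur_end, cur_sup, cur_caller = s.start, s.end, s.n_support, s.caller
        out.append(RoHSegment(ind, scaf, cur_start, cur_end, cur_sup, cur_caller))
    return out


def froh(
    segments: list[RoHSegment],
    layout: GenomeLayout,
    individuals: list[str] | None = None,
    per_scaffold: bool = False,
):
    """F_RoH: fraction of the included autosomal genome inside RoH.

    Overlapping segments are merged first so no base is counted twice.
    With ``per_scaffold`` a DataFrame of scaffold-specific values is
    returned instead of the genome-wide Series.
    """
    total = layout.total_included_length
    if total <= 0:
        raise ValueError("layout has zero included genome length")
    merged = merge_segments(segments)
    if individuals is None:
        individuals = sorted({s.individual for s in merged})
    if per_scaffold:
        lengths = layout.lengths
        rows = []
        for name in layout.included_names:
            for ind in individuals:
                covered = sum(s.length_bp for s in merged if s.individual == ind and s.scaffold == name)
                rows.append({"individual": ind, "scaffold": name, "froh": covered / lengths[name]})
        return pd.DataFrame(rows)
    vals = {ind: 0 for ind in individuals}
    for s in merged:
        if s.individual in vals:
            vals[s.individual] += s.length_bp
    return pd.Series({ind: v / total for ind, v in vals.items()}, name="froh")


def roh_age_generations(length_mb: float, r: float = 1.0) -> float:
    """Expected generations since the tract's common ancestor: 100/(2 r L)."""
    if np.any(np.asarray(length_mb) <= 0) or r <= 0:
        raise ValueError("tract length and recombination rate must be positive")
    return 100.0 / (2.0 * r * np.asarray(length_mb))


def bin_roh_by_generation(
    segments: list[RoHSegment],
    dating: DatingParams = DatingParams(),
) -> pd.DataFrame:
    """Aggregate RoH length (Mb) per individual into generation bins.

    Each segment is dated with g = 100/(2rL) and assigned to the
    half-open bin [k·w, (k+1)·w) containing g (a boundary g falls in the
    older bin's left edge: g = 5 with width 5 lands in [5, 10)).
    """
    rows = []
    for s in segments:
        g = roh_age_generations(s.length_mb, dating.r)
        k = int(np.floor(g / dating.bin_width))
        rows.append(
            {
                "individual": s.individual,
                "bin_left": k * dating.bin_width,
                "bin_right": (k + 1) * dating.bin_width,
                "g": g,
                "length_mb": s.length_mb,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["individual", "bin_left", "bin_right", "total_mb", "n_segments"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["individual", "bin_left", "bin_right"], as_index=False)
        .agg(total_mb=("length_mb", "sum"), n_segments=("length_mb", "size"))
        .sort_values(["individual", "bin_left"])
        .reset_index(drop=True)
    )
    return out


def het_froh_correlation(het: pd.Series, froh_values: pd.Series) -> tuple[float, float]:
    """Pearson correlation between genome-wide He and F_RoH across individuals.

    In an eroding population this is strongly negative: the genome
    fraction locked in RoH carries no heterozygosity.
    """
    common = het.index.intersection(froh_values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 individuals")
    x = het.loc[common].to_numpy(dtype=float)
    y = froh_values.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in heterozygosity or F_RoH")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
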