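"""Per-individual heterozygosity in non-overlapping fixed-length windows.

Windows (default 50 kb) tile each included scaffold.  Per individual and
window we count heterozygous genotypes and callable (genotyped) sites;
He is reported per callable site by default, with a per-bp variant
available, since window-based RoH callers differ on the denominator and
the callable-site form is robust to site-density variation introduced
by masks and filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenomeLayout, VariantTable

log = logging.getLogger(__name__)


@dataclass
class ScaffoldWindows:
    """Window counts for one scaffold (arrays indexed window × individual)."""

    scaffold: str
    starts: np.ndarray          # 0-based window starts
    ends: np.ndarray            # half-open window ends, clipped to scaffold length
    partial: np.ndarray         # trailing window shorter than window_bp
    n_sites: np.ndarray         # sites listed in the table, per window
    n_het: np.ndarray           # (n_windows, n_individuals)
    n_callable: np.ndarray      # genotyped sites, same shape

    def missing_fraction(self) -> np.ndarray:
        """1 − callable proportion relative to the sites listed per window.

        Windows with no listed sites have missing fraction 1.
        """
        with np.errstate(invalid="ignore", divide="ignore"):
            mf = 1.0 - self.n_callable / self.n_sites[:, None]
        mf[self.n_sites == 0] = 1.0
        return mf

    def he(self, denominator: str = "callable", window_bp: int | None = None) -> np.ndarray:
        if denominator == "callable":
            with np.errstate(invalid="ignore", divide="ignore"):
                he = self.n_het / self.n_callable
            he[self.n_callable == 0] = np.nan
            return he
        if denominator == "per_bp":
            return self.n_het / float(window_bp)
        raise ValueError(f"unknown He denominator {denominator!r}")


@dataclass
class WindowTrack:
    """He track over all included scaffolds for every individual."""

    window_bp: int
    samples: list[str]
    scaffolds: dict[str, ScaffoldWindows]
    usable_max_missing: float = 0.7
    denominator: str = "callable"
    mean_he: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def usable(self, sw: ScaffoldWindows) -> np.ndarray:
        """Windows entering means and RoH calling: enough data, full length."""
        return (sw.missing_fraction() <= self.usable_max_missing) & (sw.n_callable > 0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format track (one row per individual × window)."""
        frames = []
        for sw in self.scaffolds.values():
            he = sw.he(self.denominator, self.window_bp)
            mf = sw.missing_fraction()
            nw = len(sw.starts)
            for j, ind in enumerate(self.samples):
                frames.append(
                    pd.DataFrame(
                        {
                            "individual": ind,
                            "scaffold": sw.scaffold,
                            "start": sw.starts,
                            "end": sw.ends,
                            "partial": sw.partial,
                            "n_sites": sw.n_sites,
                            "n_het": sw.n_het[:, j],
                            "n_callable": sw.n_callable[:, j],
                            "missing_fraction": mf[:, j],
                            "he": he[:, j],
                        }
                    )
                )
        cols = [
            "individual", "scaffold", "start", "end", "partial",
            "n_sites", "n_het", "n_callable", "missing_fraction", "he",
        ]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)[cols]


def compute_window_track(
    vt: VariantTable,
    layout: GenomeLayout,
    window_bp: int = 50_000,
    usable_max_missing: float = 0.7,
    denominator: str = "callable",
) -> WindowTrack:
    """Tile included scaffolds with windows and count het/callable sites.

    Every genotyped site falls in exactly one window.  Trailing partial
    windows are kept in the track but flagged and excluded from each
    individual's mean He, which averages window He over usable
    (missing fraction ≤ ``usable_max_missing``), full-length windows.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n_ind = vt.n_samples
    scaffold_col = vt.sites["scaffold"].to_numpy()
    pos = vt.sites["pos"].to_numpy()

    scaffolds: dict[str, ScaffoldWindows] = {}
    for name, length in layout.included_scaffolds():
        n_win = int(np.ceil(length / window_bp))
        starts = np.arange(n_win, dtype=np.int64) * window_bp
        ends = np.minimum(starts + window_bp, length)
        partial = (ends - starts) < window_bp

        on = scaffold_col == name
        widx = (pos[on] - 1) // window_bp
        gt = vt.gt[on]
        n_sites = np.bincount(widx, minlength=n_win).astype(np.int64)
        n_het = np.zeros((n_win, n_ind), dtype=np.int64)
        n_call = np.zeros((n_win, n_ind), dtype=np.int64)
        for j in range(n_ind):
            g = gt[:, j]
            n_het[:, j] = np.bincount(widx[g == 1], minlength=n_win)
            n_call[:, j] = np.bincount(widx[g != MISSING], minlength=n_win)
        scaffolds[name] = ScaffoldWindows(
            scaffold=name, starts=starts, ends=ends, partial=partial,
            n_sites=n_sites, n_het=n_het, n_callable=n_call,
        )

    track = WindowTrack(
        window_bp=window_bp,
        samples=list(vt.samples),
        scaffolds=scaffolds,
        usable_max_missing=usable_max_missing,
        denominator=denominator,
    )
    track.mean_he = _mean_he(track)
    return track


def _mean_he(track: WindowTrack) -> pd.Series:
    """Per-individual mean of window He over usable full windows."""
    sums = np.zeros(len(track.samples))
    counts = np.zeros(len(track.samples))
    for sw in track.scaffolds.values():
        he = sw.he(track.denominator, track.window_bp)
        ok = track.usable(sw) & ~sw.partial[:, None] & np.isfinite(he)
        sums += np.where(ok, he, 0.0).sum(axis=0)
        counts += ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    return pd.Series(mean, index=track.samples, name="mean_he")


def genomewide_het(track: WindowTrack) -> pd.DataFrame:
    """Genome-wide heterozygosity per individual.

    ``het_pooled`` is total het count / total callable count over usable
    windows (the headline number); ``het_window_mean`` is the unweighted
    mean of window He over the same windows.
    """
    n = len(track.samples)
    tot_het = np.zeros(n)
    tot_call = np.zeros(n)
    he_sum = np.zeros(n)
    he_n = np.zeros(n)
    for sw in track.scaffolds.values():
        ok = track.usable(sw)
        tot_het += np.where(ok, sw.n_het, 0).sum(axis=0)
        tot_call += np.where(ok, sw.n_callable, 0).sum(axis=0)
        he = sw.he(track.denominator, track.window_bp)
        full = ok & ~sw.partial[:, None] & np.isfinite(he)
        he_sum += np.where(full, he, 0.0).sum(axis=0)
        he_n += full.sum(axis=0)
    if np.any(tot_call == 0):
        bad = [s for s, c in zip(track.samples, tot_call) if c == 0]
        raise ValueError(f"no callable sites in usable windows for: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = he_sum / he_n
    return pd.DataFrame(
        {
            "individual": track.samples,
            "het_pooled": tot_het / tot_call,
            "het_window_mean": wmean,
            "n_het": tot_het.astype(np.int64),
            "n_callable": tot_call.astype(np.int64),
        }
    )
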