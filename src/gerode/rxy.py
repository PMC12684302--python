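"""The Rxy relative derived-allele statistic with bootstrap CIs.

Rxy compares the accumulation of derived alleles in one population (x)
versus another (y) for a variant category, normalized by the same ratio
at putatively neutral intergenic sites.  With per-site derived-allele
frequencies d:

    L_xny(S) = sum over sites i in S of d_i^x (1 - d_i^y)
    L_ynx(S) = sum over sites i in S of d_i^y (1 - d_i^x)

    Rxy = [L_xny(cat) / L_ynx(cat)] / [L_xny(neutral) / L_ynx(neutral)]

Rxy = 1 means no frequency difference between the populations; > 1 an
excess of derived alleles in x.  The neutral normalization cancels any
site-independent inflation common to both site classes (e.g., reference
or mapping bias), which is the reason the statistic is used at all.
Confidence intervals come from resampling sites with replacement and
taking percentiles of the replicate estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING
from .polarize import PolarizedTable

log = logging.getLogger(__name__)


@dataclass
class FrequencyTable:
    """Per-site, per-population derived-allele frequencies.

    ``df`` columns: scaffold, pos, category, then per population
    ``derived_<pop>``, ``called_<pop>``, ``d_<pop>`` (derived count,
    called allele count, frequency).  Sites with zero called alleles in
    any population are excluded; ``n_excluded`` counts them.
    """

    df: pd.DataFrame
    populations: list[str]
    n_excluded: int = 0

    def category_index(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.df["category"].to_numpy() == category)

    def d(self, pop: str) -> np.ndarray:
        return self.df[f"d_{pop}"].to_numpy()


@dataclass(frozen=True)
class RxyResult:
    category: str
    pop_x: str
    pop_y: str
    estimate: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_category_sites: int
    n_neutral_sites: int
    seed: int | None = None


def site_frequencies(pt: PolarizedTable, populations: dict[str, str]) -> FrequencyTable:
    """Observed derived-allele frequencies per population at every site.

    Frequencies use the called (non-missing) allele count at each site;
    unlabelled samples raise.
    """
    missing_label = [s for s in pt.samples if s not in populations]
    if missing_label:
        raise ValueError(f"samples without population label: {missing_label}")
    pops = sorted(set(populations[s] for s in pt.samples))
    cols = {
        "scaffold": pt.sites["scaffold"].to_numpy(),
        "pos": pt.sites["pos"].to_numpy(),
        "category": pt.sites["impact"].to_numpy(),
    }
    ok = np.ones(pt.n_sites, dtype=bool)
    for pop in pops:
        j = [i for i, s in enumerate(pt.samples) if populations[s] == pop]
        d = pt.derived[:, j]
        called = 2 * (d != MISSING).sum(axis=1)
        derived = np.where(d == MISSING, 0, d).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = derived / called
        cols[f"derived_{pop}"] = derived
        cols[f"called_{pop}"] = called
        cols[f"d_{pop}"] = freq
        ok &= called > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("site_frequencies: excluded %d sites with an uncalled population", n_excluded)
    df = pd.DataFrame(cols)[ok].reset_index(drop=True)
    return FrequencyTable(df=df, populations=pops, n_excluded=n_excluded)


def sample_neutral_set(
    ft: FrequencyTable,
    n: int = 100_000,
    seed: int | np.random.Generator | None = None,
    category: str = "intergenic",
) -> np.ndarray:
    """Uniform, seed-deterministic subset of intergenic sites (indices).

    Drawn without replacement; if fewer than ``n`` intergenic sites
    exist all are taken with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = ft.category_index(category)
    if idx.size == 0:
        raise ValueError(f"no {category!r} sites available for normalization")
    if idx.size <= n:
        if idx.size < n:
            log.warning("sample_neutral_set: only %d < %d %s sites; using all", idx.size, n, category)
        return np.sort(idx)
    return np.sort(rng.choice(idx, size=n, replace=False))


def _lsums(dx: np.ndarray, dy: np.ndarray) -> tuple[float, float]:
    return float(np.sum(dx * (1 - dy))), float(np.sum(dy * (1 - dx)))


def rxy_statistic(
    ft: FrequencyTable,
    category_idx: np.ndarray,
    neutral_idx: np.ndarray,
    pop_x: str,
    pop_y: str,
) -> float:
    """Point estimate of the intergenic-normalized Rxy double ratio."""
    if len(category_idx) == 0 or len(neutral_idx) == 0:
        raise ValueError("category and neutral site sets must be non-empty")
    dx, dy = ft.d(pop_x), ft.d(pop_y)
    c_xy, c_yx = _lsums(dx[category_idx], dy[category_idx])
    n_xy, n_yx = _lsums(dx[neutral_idx], dy[neutral_idx])
    for name, v in (("L_xny(cat)", c_xy), ("L_ynx(cat)", c_yx),
                    ("L_xny(neutral)", n_xy), ("L_ynx(neutral)", n_yx)):
        if v == 0:
            raise ValueError(f"{name} is zero; Rxy undefined for {pop_x} vs {pop_y}")
    return (c_xy / c_yx) / (n_xy / n_yx)


def rxy_bootstrap(
    ft: FrequencyTable,
    category: str,
    pop_x: str,
    pop_y: str,
    n_neutral: int = 100_000,
    n_rep: int = 100,
    seed: int | None = None,
    joint: bool = False,
    max_redraws: int = 1000,
) -> RxyResult:
    """Rxy with a percentile bootstrap CI over sites.

    Category and neutral sites are resampled with replacement
    (independently by default, jointly with ``joint=True``), the
    statistic recomputed ``n_rep`` times, and the 2.5/97.5 percentiles
    of the replicates reported.  A replicate with a zero sum is redrawn
    (logged); everything is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    cat_idx = ft.category_index(category)
    neu_idx = sample_neutral_set(ft, n=n_neutral, seed=rng)
    point = rxy_statistic(ft, cat_idx, neu_idx, pop_x, pop_y)

    reps = np.empty(n_rep)
    n_redrawn = 0
    for b in range(n_rep):
        for _ in range(max_redraws):
            if joint:
                all_idx = np.concatenate([cat_idx, neu_idx])
                take = all_idx[rng.integers(0, all_idx.size, size=all_idx.size)]
                rc = take[np.isin(take, cat_idx)]
                rn = take[np.isin(take, neu_idx)]
            else:
                rc = cat_idx[rng.integers(0, cat_idx.size, size=cat_idx.size)]
                rn = neu_idx[rng.integers(0, neu_idx.size, size=neu_idx.size)]
            try:
                reps[b] = rxy_statistic(ft, rc, rn, pop_x, pop_y)
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise ValueError("bootstrap replicate kept producing zero sums")
    if n_redrawn:
        log.info("rxy_bootstrap: redrew %d degenerate replicates", n_redrawn)

    lo, hi = np.percentile(reps, [2.5, 97.5])
    return RxyResult(
        category=category, pop_x=pop_x, pop_y=pop_y,
        estimate=point, ci_low=float(lo), ci_high=float(hi),
        n_bootstrap=n_rep,
        n_category_sites=int(cat_idx.size), n_neutral_sites=int(neu_idx.size),
        seed=seed,
    )


def rxy_report(results: list[RxyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category, "pop_x": r.pop_x, "pop_y": r.pop_y,
                "rxy": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "n_bootstrap": r.n_bootstrap,
                "n_category_sites": r.n_category_sites,
                "n_neutral_sites": r.n_neutral_sites,
                "seed": r.seed,
            }
            for r in results
        ]
    )
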