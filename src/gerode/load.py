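"""Masked / realised genetic-load proxies and group comparisons.

Per individual and impact category (LoF, missense, intergenic) we count
heterozygous derived genotypes (masked load — deleterious alleles
partially hidden from selection), homozygous-derived genotypes
(realised load — expressed now), and the additive total
2 × hom-derived + het (each homozygote carries two derived copies).
Groups are compared with two-sided Mann–Whitney U tests (exact null by
enumeration for small samples) and load is regressed on F_RoH with
ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING
from .polarize import PolarizedTable

log = logging.getLogger(__name__)

DEFAULT_CATEGORIES = ("LoF", "missense", "intergenic")


def count_load(pt: PolarizedTable, categories=DEFAULT_CATEGORIES) -> pd.DataFrame:
    """Tally load proxies per individual × category.

    Returns columns ``individual, category, n_het, n_hom_derived,
    total_derived, n_callable`` plus per-callable-site rates.  Missing
    genotypes enter neither the numerators nor the callable count.
    A category with no sites yields a zero row (warned).
    """
    cat_col = pt.sites["impact"].to_numpy()
    warning = pt.sites["warning"].to_numpy() if "warning" in pt.sites else np.zeros(len(cat_col), bool)
    rows = []
    for cat in categories:
        on = (cat_col == cat) & ~warning
        if not on.any():
            log.warning("count_load: no sites in category %r", cat)
        d = pt.derived[on]
        n_het = (d == 1).sum(axis=0)
        n_hom = (d == 2).sum(axis=0)
        n_call = (d != MISSING).sum(axis=0)
        for j, ind in enumerate(pt.samples):
            rows.append(
                {
                    "individual": ind,
                    "category": cat,
                    "n_het": int(n_het[j]),
                    "n_hom_derived": int(n_hom[j]),
                    "total_derived": int(2 * n_hom[j] + n_het[j]),
                    "n_callable": int(n_call[j]),
                }
            )
    df = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in ("n_het", "n_hom_derived", "total_derived"):
            df[c + "_rate"] = df[c] / df["n_callable"]
    return df


# ---------------------------------------------------------------------------
# Rank-sum comparison


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with an exact enumeration null.

    All C(n1+n2, n1) assignments of the observed (mid-ranked) values to
    the two groups are enumerated, so the null distribution conditions
    on the observed tie pattern.  The two-sided p-value is
    P(|U − n1·n2/2| ≥ |U_obs − n1·n2/2|), using the symmetry of U about
    its mean under exchangeability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    d_obs = abs(u_obs - mu)

    total = comb(n1 + n2, n1)
    hit = 0
    base = n1 * (n1 + 1) / 2
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - base
        if abs(u - mu) >= d_obs - 1e-9:
            hit += 1
    return float(u_obs), hit / total


def compare_groups(
    report: pd.DataFrame,
    populations: dict[str, str],
    metric: str = "total_derived",
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-category two-sided rank-sum test between the two populations.

    Uses the exact enumeration null when the smaller group has at most
    ``exact_max_n`` members, the tie-corrected normal approximation
    otherwise.  Returns columns ``category, metric, group_x, group_y,
    n_x, n_y, U, p, method``.
    """
    pops = sorted(set(populations.values()))
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {pops}")
    gx, gy = pops
    rows = []
    for cat, sub in report.groupby("category", sort=False):
        sub = sub.set_index("individual")[metric]
        x = sub[[i for i in sub.index if populations.get(i) == gx]].to_numpy(dtype=float)
        y = sub[[i for i in sub.index if populations.get(i) == gy]].to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in category {cat!r}")
        if min(len(x), len(y)) <= exact_max_n:
            u, p = exact_mannwhitney(x, y)
            method = "exact"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            method = "normal"
        rows.append(
            {
                "category": cat, "metric": metric,
                "group_x": gx, "group_y": gy,
                "n_x": len(x), "n_y": len(y),
                "U": u, "p": p, "method": method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Load ~ inbreeding regression


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def regress_load_on_froh(
    report: pd.DataFrame,
    froh_values: pd.Series,
    category: str,
    metric: str = "n_hom_derived",
) -> RegressionResult:
    """OLS of a load metric on F_RoH across individuals.

    With predominantly recessive deleterious variation, inbreeding
    converts masked into realised load, so hom-derived counts rise and
    het counts fall with F_RoH.
    """
    sub = report[report["category"] == category].set_index("individual")[metric]
    common = sub.index.intersection(froh_values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 individuals")
    x = froh_values.loc[common].to_numpy(dtype=float)
    y = sub.loc[common].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero variance in F_RoH")
    if np.var(y) == 0:
        raise ValueError(f"zero variance in {metric}; correlation undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), n=len(common),
    )
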