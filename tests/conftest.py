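import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gerode import GenomeLayout, VariantTable
from gerode.simulate import SimConfig, simulate_dataset
from gerode.window_het import ScaffoldWindows, WindowTrack, _mean_he

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def vt_from_arrays(
    pos,
    gt,
    scaffold="scaf1",
    ref=None,
    alt=None,
    impact=None,
    warning=None,
    ann=None,
    dp=None,
    samples=None,
):
    """Hand-build a VariantTable for unit tests."""
    pos = np.asarray(pos, dtype=np.int64)
    gt = np.asarray(gt, dtype=np.int8)
    if gt.ndim == 1:
        gt = gt[:, None]
    m, n = gt.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "scaffold": scaffold if isinstance(scaffold, str) else list(scaffold),
            "pos": pos,
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "impact": impact if impact is not None else ["unannotated"] * m,
            "warning": warning if warning is not None else [False] * m,
            "ann": ann if ann is not None else [None] * m,
        }
    )
    dp = None if dp is None else np.asarray(dp, dtype=np.int32).reshape(m, n)
    return VariantTable(sites=sites, gt=gt, dp=dp, samples=list(samples))


def track_from_counts(n_het, n_callable, window_bp=50_000, scaffold="scaf1",
                      samples=None, n_sites=None, usable_max_missing=0.7):
    """Build a WindowTrack directly from per-window counts (one scaffold)."""
    n_het = np.atleast_2d(np.asarray(n_het, dtype=np.int64).T).T
    if n_het.ndim == 1:
        n_het = n_het[:, None]
    n_callable = np.asarray(n_callable, dtype=np.int64)
    if n_callable.ndim == 1:
        n_callable = np.broadcast_to(n_callable[:, None], n_het.shape).copy()
    n_win, n_ind = n_het.shape
    samples = samples or [f"s{i + 1}" for i in range(n_ind)]
    starts = np.arange(n_win, dtype=np.int64) * window_bp
    sw = ScaffoldWindows(
        scaffold=scaffold,
        starts=starts,
        ends=starts + window_bp,
        partial=np.zeros(n_win, dtype=bool),
        n_sites=(np.full(n_win, n_callable.max(initial=1)) if n_sites is None
                 else np.asarray(n_sites, dtype=np.int64)),
        n_het=n_het,
        n_callable=n_callable,
    )
    track = WindowTrack(
        window_bp=window_bp, samples=list(samples), scaffolds={scaffold: sw},
        usable_max_missing=usable_max_missing,
    )
    track.mean_he = _mean_he(track)
    return track


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(scaffolds=(("scaf1", 8_000_000),))


@pytest.fixture(scope="session")
def small_sim(small_layout):
    cfg = SimConfig(
        layout=small_layout,
        category_sites={"LoF": 200, "missense": 800, "intergenic": 5000},
        seed=42,
    )
    return cfg, simulate_dataset(cfg)
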