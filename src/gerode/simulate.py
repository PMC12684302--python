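"""Synthetic genotype datasets with known truth.

Two generation modes cover the pipeline's needs:

* **Direct planting** (:func:`simulate_dataset`): diploid genotypes over
  multi-Mb scaffolds with a configurable background heterozygosity,
  RoH tracts planted at stated coordinates (heterozygosity is
  structurally suppressed inside them), functional-category sites
  (LoF / missense / intergenic) with population-specific derived-allele
  frequency distributions, three outgroup allele columns for
  polarization, and per-genotype depth and missingness.

* **Pedigree mode** (:func:`simulate_pedigree`): founders drawn from a
  common gene pool transmit recombined gametes (Poisson crossovers at
  r cM/Mb) down an explicit pedigree, so offspring of related parents
  carry identity-by-descent tracts whose lengths follow the
  100/(2rg) expectation, and the truth set records the pedigree
  inbreeding coefficient F — ground truth the dating analysis needs
  that direct planting cannot supply.

Everything is deterministic under a fixed seed, down to the emitted
VCF bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenomeLayout, IndividualMeta, VariantTable

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])


def _default_layout() -> GenomeLayout:
    return GenomeLayout(scaffolds=(("scaf1", 25_000_000), ("scaf2", 25_000_000)))


def _default_category_sites() -> dict[str, int]:
    return {"LoF": 500, "missense": 2000, "intergenic": 20000}


@dataclass
class SimConfig:
    """Knobs of the synthetic generator.

    Defaults emulate the study design the pipeline targets: two
    populations of five resequenced diploids at ~21× mean coverage,
    a background heterozygous-site density of 2×10⁻⁴ per bp, and
    low-frequency deleterious categories (Beta(1, 9) derived-allele
    frequencies, mean 0.1).
    """

    layout: GenomeLayout = field(default_factory=_default_layout)
    n_individuals: dict[str, int] = field(default_factory=lambda: {"north": 5, "south": 5})
    background_het: float = 2e-4            # expected het sites per bp per individual
    background_site_density: float = 4e-4   # segregating background sites per bp
    planted_roh: list[tuple[str, str, int, int]] = field(default_factory=list)
    category_sites: dict[str, int] = field(default_factory=_default_category_sites)
    category_freq: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    default_freq_beta: tuple[float, float] = (1.0, 9.0)
    share_category_freqs: bool = False      # one frequency per site, shared by all populations
    missing_rate: float = 0.02
    mean_coverage: float = 21.4
    depth_dispersion: float = 10.0          # negative-binomial shape; larger = tighter
    ref_is_derived_rate: float = 0.3        # fraction of sites where VCF REF is the derived allele
    n_outgroups: int = 3
    outgroup_concordance: float = 0.99      # P(outgroup allele == true ancestral)
    outgroup_missing_rate: float = 0.05
    warning_rate: float = 0.01              # annotated sites flagged with an annotation warning
    multiallelic_rate: float = 0.005        # background sites given a second ALT allele
    seed: int | None = None

    def beta_params(self, category: str, population: str) -> tuple[float, float]:
        return self.category_freq.get(category, {}).get(population, self.default_freq_beta)


@dataclass
class TruthSet:
    """Ground truth emitted alongside every simulated dataset."""

    roh: pd.DataFrame                  # individual, scaffold, start, end (1-based inclusive)
    ancestral: pd.DataFrame            # scaffold, pos, ancestral
    frequencies: pd.DataFrame          # scaffold, pos, category, d_<pop>...
    pedigree_f: pd.Series | None = None


@dataclass
class SimResult:
    variants: VariantTable
    individuals: list[IndividualMeta]
    truth: TruthSet
    outgroups: pd.DataFrame            # scaffold, pos, og1..ogK
    layout: GenomeLayout | None = None


# ---------------------------------------------------------------------------
# Shared helpers


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n > length:
        raise ValueError(f"cannot place {n} sites on a {length}-bp scaffold")
    pool = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while pool.size < n:
        pool = np.unique(np.concatenate([pool, rng.integers(1, length + 1, size=n)]))
    take = rng.permutation(pool.size)[:n]
    return np.sort(pool[take])


def _ann_string(cat: str, allele: str, gene_i: int, warn: bool) -> str:
    effect, impact = {
        "LoF": ("stop_gained", "HIGH"),
        "missense": ("missense_variant", "MODERATE"),
        "intergenic": ("intergenic_region", "MODIFIER"),
    }[cat]
    fields = [allele, effect, impact, f"GENE{gene_i}", f"G{gene_i}", "transcript",
              f"T{gene_i}.1", "protein_coding", "1/1", "c.1A>G", "p.Lys1Glu",
              "1/100", "1/100", "1/33", "0",
              "WARNING_REF_DOES_NOT_MATCH_GENOME" if warn else ""]
    return "|".join(fields)


def _assemble(
    cfg: SimConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    derived_gt: np.ndarray,
    samples: list[str],
    truth: TruthSet,
) -> SimResult:
    """Shared emission path: allele labels, ANN, missingness, depth, outgroups."""
    m = len(sites)
    n_ind = len(samples)

    anc_idx = rng.integers(0, 4, size=m)
    der_idx = (anc_idx + rng.integers(1, 4, size=m)) % 4
    anc_base = _BASES[anc_idx]
    der_base = _BASES[der_idx]

    ref_is_derived = rng.random(m) < cfg.ref_is_derived_rate
    ref = np.where(ref_is_derived, der_base, anc_base)
    alt = np.where(ref_is_derived, anc_base, der_base).astype(object)

    gt = derived_gt.astype(np.int8).copy()
    flip = ref_is_derived
    gt[flip] = 2 - gt[flip]

    # second ALT allele on a small fraction of unannotated background sites
    cats = sites["impact"].to_numpy()
    bg = cats == "unannotated"
    multi = bg & (rng.random(m) < cfg.multiallelic_rate)
    third = _BASES[(anc_idx + rng.integers(1, 4, size=m)) % 4]
    for i in np.flatnonzero(multi):
        extra = third[i]
        if extra in (ref[i], alt[i]):
            extra = next(b for b in _BASES if b not in (ref[i], alt[i]))
        alt[i] = f"{alt[i]},{extra}"

    warn = np.zeros(m, dtype=bool)
    annotated = np.isin(cats, ["LoF", "missense", "intergenic"])
    warn[annotated] = rng.random(int(annotated.sum())) < cfg.warning_rate
    anns: list[str | None] = [None] * m
    for i in np.flatnonzero(annotated):
        anns[i] = _ann_string(cats[i], str(alt[i]).split(",")[0], i, bool(warn[i]))

    miss = rng.random((m, n_ind)) < cfg.missing_rate
    gt[miss] = MISSING

    k = cfg.depth_dispersion
    p = k / (k + cfg.mean_coverage)
    dp = rng.negative_binomial(k, p, size=(m, n_ind)).astype(np.int32)

    og_cols: dict[str, np.ndarray] = {}
    for o in range(cfg.n_outgroups):
        discord = rng.random(m) >= cfg.outgroup_concordance
        other = _BASES[(anc_idx + rng.integers(1, 4, size=m)) % 4]
        allele = np.where(discord, other, anc_base).astype(object)
        allele[rng.random(m) < cfg.outgroup_missing_rate] = "."
        og_cols[f"og{o + 1}"] = allele

    site_df = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": ref,
            "alt": alt.astype(str),
            "impact": cats,
            "warning": warn,
            "ann": anns,
        }
    )
    vt = VariantTable(sites=site_df, gt=gt, dp=dp, samples=samples)
    outgroups = pd.DataFrame(
        {"scaffold": site_df["scaffold"], "pos": site_df["pos"], **og_cols}
    )
    truth.ancestral = pd.DataFrame(
        {"scaffold": site_df["scaffold"], "pos": site_df["pos"], "ancestral": anc_base}
    )
    meta = [
        IndividualMeta(id=s, population=s.rsplit("_", 1)[0], mean_coverage=cfg.mean_coverage)
        for s in samples
    ]
    return SimResult(
        variants=vt, individuals=meta, truth=truth, outgroups=outgroups, layout=cfg.layout
    )


# ---------------------------------------------------------------------------
# Direct-planting mode


def _validate_planted(cfg: SimConfig):
    lengths = cfg.layout.lengths
    by_ind: dict[str, list[tuple[int, int, str]]] = {}
    for ind, scaf, s, e in cfg.planted_roh:
        if scaf not in lengths:
            raise ValueError(f"planted RoH on unknown scaffold {scaf!r}")
        if not (1 <= s < e <= lengths[scaf]):
            raise ValueError(f"planted RoH {ind}:{scaf}:{s}-{e} outside scaffold bounds")
        by_ind.setdefault(ind, []).append((s, e, scaf))
    for ind, tracts in by_ind.items():
        per_scaf: dict[str, list[tuple[int, int]]] = {}
        for s, e, scaf in tracts:
            per_scaf.setdefault(scaf, []).append((s, e))
        for scaf, iv in per_scaf.items():
            iv.sort()
            for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping planted RoH for {ind} on {scaf}")
    if cfg.planted_roh and cfg.background_site_density * 50_000 < 1:
        log.warning(
            "simulate_dataset: background site density %.2g gives < 1 expected site "
            "per 50-kb window; planted RoH may be invisible",
            cfg.background_site_density,
        )


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Generate a two-population dataset with planted RoH and known truth.

    Background sites segregate at frequency ½ in every population (so
    each individual is heterozygous at half of them, giving the
    configured per-bp heterozygosity); category sites get per-population
    derived-allele frequencies drawn from Beta distributions.  Inside a
    planted RoH tract the individual's two allele copies are a single
    draw doubled, so no heterozygous genotype is ever emitted there.
    """
    _validate_planted(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pops = list(cfg.n_individuals)
    samples = [f"{p}_{i + 1}" for p in pops for i in range(cfg.n_individuals[p])]
    pop_of = np.array([pops.index(s.rsplit("_", 1)[0]) for s in samples])

    included = cfg.layout.included_scaffolds()
    if not included:
        raise ValueError("layout includes no scaffolds")
    lengths = np.array([l for _, l in included], dtype=float)
    probs = lengths / lengths.sum()

    # per-scaffold site counts: background by density, categories multinomial
    cat_names = list(cfg.category_sites)
    cat_alloc = {c: rng.multinomial(n, probs) for c, n in cfg.category_sites.items()}

    frames = []
    freqs = []  # per-site per-pop derived frequency
    for si, (name, length) in enumerate(included):
        n_bg = int(round(cfg.background_site_density * length))
        counts = [n_bg] + [int(cat_alloc[c][si]) for c in cat_names]
        total = sum(counts)
        pos = _sample_positions(rng, length, total)
        labels = np.repeat(["unannotated"] + cat_names, counts)
        rng.shuffle(labels)
        f = np.empty((total, len(pops)))
        bg_mask = labels == "unannotated"
        f[bg_mask] = 0.5
        for c in cat_names:
            cm = labels == c
            k = int(cm.sum())
            if cfg.share_category_freqs:
                a, b = cfg.beta_params(c, pops[0])
                shared = rng.beta(a, b, size=k)
                for q in range(len(pops)):
                    f[cm, q] = shared
            else:
                for q, p in enumerate(pops):
                    a, b = cfg.beta_params(c, p)
                    f[cm, q] = rng.beta(a, b, size=k)
        frames.append(pd.DataFrame({"scaffold": name, "pos": pos, "impact": labels}))
        freqs.append(f)

    sites = pd.concat(frames, ignore_index=True)
    freq = np.vstack(freqs)
    m = len(sites)

    derived_gt = np.empty((m, len(samples)), dtype=np.int8)
    for j in range(len(samples)):
        derived_gt[:, j] = rng.binomial(2, freq[:, pop_of[j]])

    # suppress heterozygosity inside planted tracts: one allele draw, doubled
    scaf_col = sites["scaffold"].to_numpy()
    pos_col = sites["pos"].to_numpy()
    roh_rows = []
    for ind, scaf, s, e in cfg.planted_roh:
        j = samples.index(ind)
        mask = (scaf_col == scaf) & (pos_col >= s) & (pos_col <= e)
        one = rng.binomial(1, freq[mask, pop_of[j]])
        derived_gt[mask, j] = (2 * one).astype(np.int8)
        roh_rows.append({"individual": ind, "scaffold": scaf, "start": s, "end": e})

    freq_df = pd.DataFrame(
        {
            "scaffold": scaf_col,
            "pos": pos_col,
            "category": sites["impact"].to_numpy(),
            **{f"d_{p}": freq[:, q] for q, p in enumerate(pops)},
        }
    )
    truth = TruthSet(
        roh=pd.DataFrame(roh_rows, columns=["individual", "scaffold", "start", "end"]),
        ancestral=pd.DataFrame(),
        frequencies=freq_df,
    )
    return _assemble(cfg, rng, sites, derived_gt, samples, truth)


# ---------------------------------------------------------------------------
# Pedigree mode


Pedigree = list[tuple[str, str | None, str | None]]


def full_sib_pedigree(n_offspring: int, n_families: int = 1, prefix: str = "off") -> Pedigree:
    """Full-sib matings; every offspring has pedigree F = 1/4.

    Offspring are spread round-robin over ``n_families`` independent
    founder pairs.  Independent families keep realized-F estimates
    uncorrelated across offspring (offspring of a single sib pair share
    parental gametes, so their IBD fractions co-vary).
    """
    ped: Pedigree = []
    for f in range(n_families):
        t = f"f{f + 1}"
        ped += [(f"{t}A", None, None), (f"{t}B", None, None),
                (f"{t}sib1", f"{t}A", f"{t}B"), (f"{t}sib2", f"{t}A", f"{t}B")]
    for i in range(n_offspring):
        t = f"f{i % n_families + 1}"
        ped.append((f"{prefix}_{i + 1}", f"{t}sib1", f"{t}sib2"))
    return ped


def cousin_pedigree(n_offspring: int, n_families: int = 1, prefix: str = "off") -> Pedigree:
    """First-cousin matings; every offspring has pedigree F = 1/16."""
    ped: Pedigree = []
    for f in range(n_families):
        t = f"f{f + 1}"
        ped += [
            (f"{t}A", None, None), (f"{t}B", None, None),
            (f"{t}C", None, None), (f"{t}D", None, None),
            (f"{t}sib1", f"{t}A", f"{t}B"), (f"{t}sib2", f"{t}A", f"{t}B"),
            (f"{t}k1", f"{t}sib1", f"{t}C"), (f"{t}k2", f"{t}sib2", f"{t}D"),
        ]
    for i in range(n_offspring):
        t = f"f{i % n_families + 1}"
        ped.append((f"{prefix}_{i + 1}", f"{t}k1", f"{t}k2"))
    return ped


def _topo_order(pedigree: Pedigree) -> list[str]:
    parents = {c: (f, m) for c, f, m in pedigree}
    depth: dict[str, int] = {}

    def d(ind: str, stack: tuple = ()) -> int:
        if ind in stack:
            raise ValueError(f"{ind!r} is listed as its own ancestor")
        if ind not in depth:
            f, m = parents.get(ind, (None, None))
            depth[ind] = 0 if f is None and m is None else 1 + max(
                d(f, stack + (ind,)), d(m, stack + (ind,))
            )
        return depth[ind]

    for c, _, _ in pedigree:
        d(c)
    return sorted(depth, key=lambda i: (depth[i], i))


def pedigree_f(pedigree: Pedigree) -> pd.Series:
    """Pedigree inbreeding coefficients via the kinship recursion.

    Founders are unrelated and non-inbred; F(child) equals the kinship
    of its parents; a full-sib-mating offspring has F = 0.25.
    """
    parents = {c: (f, m) for c, f, m in pedigree}
    order = _topo_order(pedigree)
    depth = {ind: i for i, ind in enumerate(order)}
    memo: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        key = (a, b) if depth[a] >= depth[b] else (b, a)
        if key in memo:
            return memo[key]
        a, b = key
        fa, ma = parents.get(a, (None, None))
        if a == b:
            val = 0.5 * (1 + (phi(fa, ma) if fa is not None else 0.0))
        elif fa is None:
            val = 0.0  # both founders (a has max depth, so b is a founder too)
        else:
            val = 0.5 * (phi(fa, b) + phi(ma, b))
        memo[key] = val
        return val

    out = {}
    for ind in order:
        f, m = parents.get(ind, (None, None))
        out[ind] = phi(f, m) if f is not None else 0.0
    return pd.Series(out, name="pedigree_f")


class _Ancestry:
    """Piecewise-constant founder-haplotype labels along one scaffold."""

    __slots__ = ("bounds", "ids")

    def __init__(self, bounds: np.ndarray, ids: np.ndarray):
        self.bounds = bounds  # ascending breakpoints ending at scaffold length
        self.ids = ids

    @classmethod
    def founder(cls, length: int, hap_id: int) -> "_Ancestry":
        return cls(np.array([length], dtype=np.int64), np.array([hap_id], dtype=np.int64))

    def at(self, positions: np.ndarray) -> np.ndarray:
        return self.ids[np.searchsorted(self.bounds, positions)]


def _gamete(h0: _Ancestry, h1: _Ancestry, length: int, r_cm_per_mb: float,
            rng: np.random.Generator) -> _Ancestry:
    """Recombine two parental haplotypes: Poisson crossovers at r cM/Mb."""
    morgans = length * r_cm_per_mb / 1e8
    k = rng.poisson(morgans)
    cuts = np.sort(rng.integers(1, length, size=k)) if k else np.empty(0, dtype=np.int64)
    cur = int(rng.integers(0, 2))
    haps = (h0, h1)
    bounds: list[int] = []
    ids: list[int] = []
    prev = 0
    for cut in list(cuts) + [length]:
        if cut == prev:
            cur = 1 - cur
            continue
        h = haps[cur]
        i0 = int(np.searchsorted(h.bounds, prev + 1))
        for i in range(i0, len(h.bounds)):
            b = min(int(h.bounds[i]), cut)
            if ids and ids[-1] == int(h.ids[i]):
                bounds[-1] = b
            else:
                bounds.append(b)
                ids.append(int(h.ids[i]))
            if b == cut:
                break
        prev = cut
        cur = 1 - cur
    return _Ancestry(np.array(bounds, dtype=np.int64), np.array(ids, dtype=np.int64))


def _ibd_segments(h0: _Ancestry, h1: _Ancestry, length: int) -> list[tuple[int, int]]:
    """1-based inclusive intervals where both haplotypes share a founder haplotype."""
    bounds = np.unique(np.concatenate([h0.bounds, h1.bounds]))
    same = h0.at(bounds) == h1.at(bounds)
    segs: list[tuple[int, int]] = []
    prev = 0
    for b, s in zip(bounds, same):
        if s:
            if segs and segs[-1][1] == prev:
                segs[-1] = (segs[-1][0], int(b))
            else:
                segs.append((prev + 1, int(b)))
        prev = int(b)
    return segs


def simulate_pedigree(
    cfg: SimConfig,
    pedigree: Pedigree,
    r_cm_per_mb: float = 1.0,
    seed: int | None = None,
    population_label: str = "pedigree",
) -> SimResult:
    """Transmit founder gene-pool haplotypes down a pedigree with recombination.

    Founder haplotype alleles are Bernoulli draws from per-site derived
    frequencies (½ at background sites, category Betas at annotated
    sites, the ``population_label`` column of ``category_freq`` if
    present).  The truth set records the pedigree F of every individual
    and the realized IBD tracts (regions where the two haplotypes
    descend from the same founder haplotype) as RoH truth.
    """
    order = _topo_order(pedigree)
    parents = {c: (f, m) for c, f, m in pedigree}
    fvals = pedigree_f(pedigree)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    included = cfg.layout.included_scaffolds()
    lengths = np.array([l for _, l in included], dtype=float)
    probs = lengths / lengths.sum()
    cat_names = list(cfg.category_sites)
    cat_alloc = {c: rng.multinomial(n, probs) for c, n in cfg.category_sites.items()}

    founders = [i for i in order if parents.get(i, (None, None))[0] is None]
    hap_ids = {ind: (2 * k, 2 * k + 1) for k, ind in enumerate(founders)}
    n_haps = 2 * len(founders)

    site_frames = []
    freq_all = []
    hap_alleles = []  # per scaffold: (n_sites, n_haps)
    ancestries: dict[str, dict[str, tuple[_Ancestry, _Ancestry]]] = {ind: {} for ind in order}

    for si, (name, length) in enumerate(included):
        n_bg = int(round(cfg.background_site_density * length))
        counts = [n_bg] + [int(cat_alloc[c][si]) for c in cat_names]
        pos = _sample_positions(rng, length, sum(counts))
        labels = np.repeat(["unannotated"] + cat_names, counts)
        rng.shuffle(labels)
        f = np.empty(len(pos))
        f[labels == "unannotated"] = 0.5
        for c in cat_names:
            cm = labels == c
            a, b = cfg.beta_params(c, population_label)
            f[cm] = rng.beta(a, b, size=int(cm.sum()))
        site_frames.append(pd.DataFrame({"scaffold": name, "pos": pos, "impact": labels}))
        freq_all.append(f)
        hap_alleles.append((rng.random((len(pos), n_haps)) < f[:, None]).astype(np.int8))

        for ind in order:
            fa, mo = parents.get(ind, (None, None))
            if fa is None:
                a, b = hap_ids[ind]
                ancestries[ind][name] = (
                    _Ancestry.founder(length, a), _Ancestry.founder(length, b),
                )
            else:
                gp = _gamete(*ancestries[fa][name], length, r_cm_per_mb, rng)
                gm = _gamete(*ancestries[mo][name], length, r_cm_per_mb, rng)
                ancestries[ind][name] = (gp, gm)

    sites = pd.concat(site_frames, ignore_index=True)
    samples = [f"{population_label}_{ind}" for ind in order]

    derived_gt = np.empty((len(sites), len(order)), dtype=np.int8)
    roh_rows = []
    row0 = 0
    for si, (name, length) in enumerate(included):
        pos = site_frames[si]["pos"].to_numpy()
        H = hap_alleles[si]
        for j, ind in enumerate(order):
            h0, h1 = ancestries[ind][name]
            dose = H[np.arange(len(pos)), h0.at(pos)] + H[np.arange(len(pos)), h1.at(pos)]
            derived_gt[row0:row0 + len(pos), j] = dose
            for s, e in _ibd_segments(h0, h1, length):
                roh_rows.append(
                    {"individual": f"{population_label}_{ind}", "scaffold": name,
                     "start": s, "end": e}
                )
        row0 += len(pos)

    freq = np.concatenate(freq_all)
    freq_df = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "category": sites["impact"].to_numpy(),
            f"d_{population_label}": freq,
        }
    )
    truth = TruthSet(
        roh=pd.DataFrame(roh_rows, columns=["individual", "scaffold", "start", "end"]),
        ancestral=pd.DataFrame(),
        frequencies=freq_df,
        pedigree_f=pd.Series(
            {f"{population_label}_{ind}": fvals[ind] for ind in order}, name="pedigree_f"
        ),
    )
    res = _assemble(cfg, rng, sites, derived_gt, samples, truth)
    res.individuals = [
        IndividualMeta(id=s, population=population_label, mean_coverage=cfg.mean_coverage)
        for s in samples
    ]
    return res


# ---------------------------------------------------------------------------
# File emission


def write_vcf(sim: SimResult, path: str) -> None:
    """Emit the dataset as a VCF 4.2 text file (GT:DP, ANN INFO)."""
    vt = sim.variants
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    layout = sim.layout if sim.layout is not None else _infer_layout(sim)
    for name, length in layout.scaffolds:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        s = vt.sites
        for i in range(vt.n_sites):
            ann = s["ann"].iloc[i]
            info = f"ANN={ann}" if ann else "."
            fields = [
                s["scaffold"].iloc[i], str(s["pos"].iloc[i]), ".",
                s["ref"].iloc[i], s["alt"].iloc[i], ".", "PASS", info, "GT:DP",
            ]
            for j in range(vt.n_samples):
                d = vt.dp[i, j] if vt.dp is not None else MISSING
                fields.append(f"{gt_str[int(vt.gt[i, j])]}:{d if d != MISSING else '.'}")
            fh.write("\t".join(fields) + "\n")


def _infer_layout(sim: SimResult) -> GenomeLayout:
    """Fallback layout from the emitted scaffolds (lengths from max pos)."""
    seen = dict.fromkeys(sim.variants.sites["scaffold"])
    pos = sim.variants.sites.groupby("scaffold", sort=False)["pos"].max()
    return GenomeLayout(
        scaffolds=tuple((name, int(pos[name])) for name in seen),
        min_scaffold_length=0,
    )


def write_dataset(sim: SimResult, cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Write VCF + population/outgroup/truth side tables; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "layout": os.path.join(outdir, "layout.tsv"),
        "populations": os.path.join(outdir, "populations.tsv"),
        "outgroups": os.path.join(outdir, "outgroups.tsv"),
        "truth_roh": os.path.join(outdir, "truth_roh.bed"),
        "truth_ancestral": os.path.join(outdir, "truth_ancestral.tsv"),
        "truth_frequencies": os.path.join(outdir, "truth_frequencies.tsv"),
    }
    write_vcf(sim, paths["vcf"])
    cfg.layout.to_frame().to_csv(paths["layout"], sep="\t", index=False)
    pd.DataFrame(
        {
            "individual": [m.id for m in sim.individuals],
            "population": [m.population for m in sim.individuals],
            "mean_coverage": [m.mean_coverage for m in sim.individuals],
        }
    ).to_csv(paths["populations"], sep="\t", index=False)
    sim.outgroups.to_csv(paths["outgroups"], sep="\t", index=False)
    with open(paths["truth_roh"], "w") as fh:
        for _, row in sim.truth.roh.iterrows():
            fh.write(f"{row['scaffold']}\t{row['start'] - 1}\t{row['end']}\t{row['individual']}\n")
    sim.truth.ancestral.to_csv(paths["truth_ancestral"], sep="\t", index=False)
    sim.truth.frequencies.to_csv(paths["truth_frequencies"], sep="\t", index=False)
    if sim.truth.pedigree_f is not None:
        p = os.path.join(outdir, "truth_pedigree_f.tsv")
        sim.truth.pedigree_f.rename_axis("individual").reset_index().to_csv(p, sep="\t", index=False)
        paths["truth_pedigree_f"] = p
    return paths
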