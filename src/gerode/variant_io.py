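"""Genotype data model and standard-format I/O.

The in-memory model is a :class:`VariantTable`: a sites × individuals
matrix of diploid alt-allele dosages (0/1/2, ``MISSING`` = -1) with
per-genotype sequencing depth and per-site annotations.  Variant
coordinates are 1-based inclusive (VCF convention); interval records
(RoH segments, masks) convert to 0-based half-open BED only at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype (and for absent depth).
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeLayout:
    """Scaffold names/lengths plus which scaffolds enter the analysis.

    Only autosomal scaffolds at least ``min_scaffold_length`` bp long are
    included; by default that is 5 Mb, so that retained scaffolds stand in
    for full chromosomes rather than unplaced fragments.
    """

    scaffolds: tuple[tuple[str, int], ...]
    autosomal: tuple[bool, ...] = ()
    min_scaffold_length: int = 5_000_000

    def __post_init__(self):
        if not self.autosomal:
            object.__setattr__(self, "autosomal", tuple(True for _ in self.scaffolds))
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        if len(self.autosomal) != len(self.scaffolds):
            raise ValueError("autosomal flags must match scaffolds")
        for name, length in self.scaffolds:
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)

    def included_scaffolds(self) -> list[tuple[str, int]]:
        """Scaffolds that pass the autosomal and minimum-length filters."""
        return [
            (name, length)
            for (name, length), auto in zip(self.scaffolds, self.autosomal)
            if auto and length >= self.min_scaffold_length
        ]

    @property
    def included_names(self) -> list[str]:
        return [n for n, _ in self.included_scaffolds()]

    @property
    def total_included_length(self) -> int:
        """Total autosomal length used as the F_RoH denominator."""
        return sum(length for _, length in self.included_scaffolds())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [n for n, _ in self.scaffolds],
                "length": [l for _, l in self.scaffolds],
                "autosomal": list(self.autosomal),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_scaffold_length: int = 5_000_000) -> "GenomeLayout":
        auto = df["autosomal"].astype(bool) if "autosomal" in df else [True] * len(df)
        return cls(
            scaffolds=tuple(zip(df["scaffold"].astype(str), df["length"].astype(int))),
            autosomal=tuple(auto),
            min_scaffold_length=min_scaffold_length,
        )


@dataclass(frozen=True)
class IndividualMeta:
    """Sample identity, population label and mean sequencing coverage (×)."""

    id: str
    population: str
    mean_coverage: float = float("nan")


def populations_of(meta: list[IndividualMeta]) -> dict[str, str]:
    return {m.id: m.population for m in meta}


@dataclass
class VariantTable:
    """Sites × individuals diploid genotype matrix.

    Attributes
    ----------
    sites : DataFrame with columns ``scaffold, pos, ref, alt, impact,
        warning, ann`` — ``pos`` is 1-based; ``alt`` is a comma-joined
        string for multi-allelic sites; ``impact`` is one of ``LoF``,
        ``missense``, ``intergenic``, ``other``, ``unannotated``.
    gt : int8 array (n_sites, n_samples) of alt-allele dosages; -1 missing.
    dp : int32 array of per-genotype depths, or None when absent.
    samples : sample ids, column order of ``gt``.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    samples: list[str]
    dp: np.ndarray | None = None

    def __post_init__(self):
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites/samples")
        if self.dp is not None and self.dp.shape != self.gt.shape:
            raise ValueError("depth matrix shape does not match genotypes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_biallelic(self) -> np.ndarray:
        alts = self.sites["alt"].to_numpy()
        return np.array(["," not in a and a != "." for a in alts])

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.gt == MISSING).sum(axis=1) / self.n_samples

    def subset(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(np.asarray(mask))
        return VariantTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx].copy(),
            dp=None if self.dp is None else self.dp[idx].copy(),
            samples=list(self.samples),
        )

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)


# ---------------------------------------------------------------------------
# VCF input


def read_variants(vcf_path: str, layout: GenomeLayout) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Sites on scaffolds excluded by *layout* (non-autosomal, shorter than
    the minimum length, or absent from the layout) are skipped; the skip
    count is logged.  GT is required; per-genotype DP and SnpEff-style
    ANN INFO strings are read when present.
    """
    from cyvcf2 import VCF

    included = set(layout.included_names)
    known = set(layout.lengths)

    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)

    scaffolds: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    anns: list[str | None] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    any_dp = False
    n_skipped = 0
    n_unknown = 0

    for v in vcf:
        if v.CHROM not in included:
            n_skipped += 1
            if v.CHROM not in known:
                n_unknown += 1
            continue
        scaffolds.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        anns.append(v.INFO.get("ANN"))
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        d = v.format("DP")
        if d is not None:
            d = d.reshape(-1).astype(np.int32)
            d[d < 0] = MISSING
            any_dp = True
        else:
            d = np.full(len(samples), MISSING, dtype=np.int32)
        dps.append(d)
    vcf.close()

    if n_skipped:
        log.info(
            "read_variants: skipped %d sites on excluded scaffolds (%d on scaffolds absent from layout)",
            n_skipped,
            n_unknown,
        )

    sites = pd.DataFrame(
        {
            "scaffold": pd.Series(scaffolds, dtype=str),
            "pos": pd.Series(positions, dtype=np.int64),
            "ref": pd.Series(refs, dtype=str),
            "alt": pd.Series(alts, dtype=str),
            "impact": "unannotated",
            "warning": False,
            "ann": pd.Series(anns, dtype=object),
        }
    )
    gt = np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)
    dp = np.vstack(dps) if dps else np.empty((0, len(samples)), dtype=np.int32)
    vt = VariantTable(sites=sites, gt=gt, dp=dp if any_dp else None, samples=samples)
    return _sort_sites(vt, layout)


def _sort_sites(vt: VariantTable, layout: GenomeLayout) -> VariantTable:
    order = {name: i for i, (name, _) in enumerate(layout.scaffolds)}
    key = vt.sites["scaffold"].map(order).to_numpy()
    idx = np.lexsort((vt.sites["pos"].to_numpy(), key))
    if np.array_equal(idx, np.arange(len(idx))):
        return vt
    return VariantTable(
        sites=vt.sites.iloc[idx].reset_index(drop=True),
        gt=vt.gt[idx],
        dp=None if vt.dp is None else vt.dp[idx],
        samples=vt.samples,
    )


# ---------------------------------------------------------------------------
# Filters


def filter_genotype_depth(
    vt: VariantTable,
    meta: list[IndividualMeta],
    min_dp: int = 8,
    max_factor: float = 2.0,
) -> VariantTable:
    """Mask genotypes with aberrant depth.

    A genotype is set to MISSING when its depth is below ``min_dp`` reads
    or above ``max_factor`` × that individual's mean coverage — the low
    end removes undercovered calls, the high end collapsed repeats.
    Retained genotypes are never altered.
    """
    if vt.dp is None:
        raise ValueError("depth filtering requested but the table carries no DP")
    cov = {m.id: m.mean_coverage for m in meta}
    means = np.empty(vt.n_samples)
    for j, s in enumerate(vt.samples):
        if s not in cov or not np.isfinite(cov[s]) or cov[s] <= 0:
            raise ValueError(f"mean_coverage missing or non-positive for sample {s!r}")
        means[j] = cov[s]

    dp = vt.dp
    bad = (dp != MISSING) & ((dp < min_dp) | (dp > max_factor * means[None, :]))
    gt = vt.gt.copy()
    gt[bad] = MISSING
    log.info("filter_genotype_depth: masked %d genotypes", int(bad.sum()))
    return VariantTable(sites=vt.sites.copy(), gt=gt, dp=dp.copy(), samples=list(vt.samples))


def filter_sites(
    vt: VariantTable,
    max_missing_fraction: float = 0.2,
    biallelic_only: bool = True,
    drop_warnings: bool = True,
) -> VariantTable:
    """Drop multi-allelic, high-missingness and annotation-warning sites.

    ``max_missing_fraction`` is the largest tolerated fraction of missing
    genotypes per site; the default 0.2 keeps sites called in at least
    80% of individuals.  Pass 0.8 for the permissive reading (at least
    20% call rate).
    """
    keep = vt.missing_fraction() <= max_missing_fraction
    if biallelic_only:
        keep &= vt.is_biallelic()
    if drop_warnings:
        keep &= ~vt.sites["warning"].to_numpy()
    log.info("filter_sites: kept %d of %d sites", int(keep.sum()), vt.n_sites)
    return vt.subset(keep)


# ---------------------------------------------------------------------------
# Functional-impact annotation


#: SnpEff impact → load category.
_IMPACT_MAP = {"HIGH": "LoF", "MODERATE": "missense"}


def _parse_ann_entry(ann: str) -> tuple[str, bool]:
    """Classify one ANN INFO string; returns (category, warning_flag).

    The most severe annotation wins: HIGH → LoF, MODERATE → missense,
    an intergenic_region annotation → intergenic, anything else → other.
    A non-empty trailing ERRORS/WARNINGS/INFO subfield flags the site.
    """
    best = "other"
    rank = {"LoF": 0, "missense": 1, "intergenic": 2, "other": 3}
    warning = False
    ok = False
    for entry in ann.split(","):
        parts = entry.split("|")
        if len(parts) < 3:
            continue
        ok = True
        effect, impact = parts[1], parts[2]
        if impact in _IMPACT_MAP:
            cat = _IMPACT_MAP[impact]
        elif "intergenic_region" in effect:
            cat = "intergenic"
        else:
            cat = "other"
        if rank[cat] < rank[best]:
            best = cat
        if len(parts) >= 16 and parts[15].strip():
            warning = True
        elif any(p.startswith(("WARNING_", "ERROR_")) for p in parts):
            warning = True
    if not ok:
        raise ValueError("no parseable ANN entry")
    return best, warning


def parse_impact_annotations(vt: VariantTable) -> VariantTable:
    """Fill ``impact`` and ``warning`` from SnpEff-style ANN strings.

    Sites with no ANN string, or an unparseable one, stay ``unannotated``
    (the latter is logged).
    """
    sites = vt.sites.copy()
    impacts = sites["impact"].to_list()
    warnings_ = sites["warning"].to_list()
    n_bad = 0
    for i, ann in enumerate(sites["ann"]):
        if ann is None or (isinstance(ann, float) and np.isnan(ann)):
            continue
        try:
            impacts[i], warnings_[i] = _parse_ann_entry(str(ann))
        except ValueError:
            impacts[i] = "unannotated"
            n_bad += 1
    if n_bad:
        log.warning("parse_impact_annotations: %d unparseable ANN strings", n_bad)
    sites["impact"] = impacts
    sites["warning"] = warnings_
    return VariantTable(
        sites=sites,
        gt=vt.gt.copy(),
        dp=None if vt.dp is None else vt.dp.copy(),
        samples=list(vt.samples),
    )


# ---------------------------------------------------------------------------
# Tabular / BED output


def write_report_tsv(table: pd.DataFrame, path: str) -> None:
    """Write a DataFrame as a headered, tab-separated file."""
    table.to_csv(path, sep="\t", index=False)


def read_report_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_bed(segments, path: str) -> None:
    """Write segment records as BED (0-based half-open).

    Segments carry 1-based inclusive ``start``/``end``; the BED line for
    1-based 1..500000 is therefore ``scaffold<TAB>0<TAB>500000``.  An
    optional 4th column holds the individual id.
    """
    with open(path, "w") as fh:
        for seg in segments:
            name = getattr(seg, "individual", None)
            cols = [seg.scaffold, str(seg.start - 1), str(seg.end)]
            if name is not None:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def read_segments_bed(path: str) -> pd.DataFrame:
    """Read a BED file back into 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = {
                "scaffold": parts[0],
                "start": int(parts[1]) + 1,
                "end": int(parts[2]),
            }
            if len(parts) > 3:
                row["individual"] = parts[3]
            rows.append(row)
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "individual"][: 4 if rows and "individual" in rows[0] else 3])


# ---------------------------------------------------------------------------
# Simple key=value config files (pipeline plumbing)


def read_kv_config(path: str) -> dict[str, str]:
    """Parse a plain ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
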