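# Methods

This note documents the statistical procedures `gerode` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter when
comparing output against other tools.

## Genotype model and filtering

Variants are held as a sites × individuals matrix of alt-allele dosages
(0/1/2; −1 missing) with per-genotype read depth, read from VCF via
cyvcf2.  Coordinates are 1-based inclusive internally (VCF convention);
interval output converts to 0-based half-open BED only at the I/O
boundary.  Only autosomal scaffolds ≥5 Mb enter the analysis — shorter
scaffolds are unanchored fragments that distort window statistics and
the F_RoH denominator.

Genotype-level depth filtering masks calls with depth <8× or more than
2× the individual's mean coverage (undercovered and collapsed-repeat
genotypes respectively); it never alters a retained genotype, only its
missingness.  Site-level filtering drops multi-allelic sites, sites
flagged by annotation warnings, and sites whose missing-genotype
fraction exceeds `max_missing_fraction`.  The default is 0.2 (≥80% call
rate); a "maximum missing rate of 0.8" convention from PLINK-style
workflows is selectable by passing 0.8 — the two readings of that
phrase differ and both are supported rather than adjudicated.
Repeat-mask exclusion, when wanted, is supplied as a BED of excluded
intervals; the package never runs a masker.

Functional impact comes from SnpEff-style ANN strings: HIGH → LoF,
MODERATE → missense, an `intergenic_region` annotation → intergenic,
anything else → other; the most severe annotation at a site wins, and a
non-empty trailing errors/warnings subfield sets the site's warning
flag.  Load and Rxy computations use only warning-free sites.

## Windowed heterozygosity

He is computed in non-overlapping 50-kb windows as heterozygous
genotypes ÷ genotyped sites in the window.  The callable-site
denominator is the default because it is robust to the site-density
variation that masking and filtering introduce; a per-bp variant
(n_het / window length) is available and labelled in output headers,
since window tools differ on this and results are not comparable across
denominators.  Missing fraction per window is measured against the
sites listed in the table for that window (true callable-bp masks from
gVCFs are out of scope; a callable-mask BED can override).  Trailing
partial windows are flagged and excluded from per-individual mean He,
which averages He over usable windows (missing fraction ≤0.7, matching
the RoH usability cutoff for internal consistency).  Genome-wide He is
reported both pooled (Σhet / Σcallable — the headline value) and as the
unweighted mean of window He.

## RoH calling

**Window caller.**  A window qualifies when usable and its He is
strictly below `low_het_factor` (default ⅕) × the individual's mean He;
maximal runs of ≥10 consecutive qualifying windows become segments
spanning the first window's start to the last window's end.  Segments
shorter than 500 kb are discarded as background relatedness.  Three
conventions are deliberate and explicit, since window tools rarely
publish them: segment ends are window-resolution (no sub-window
refinement); an unusable window breaks a run (no bridging across
high-missingness windows — conservative and testable); mean He is
recomputed from the current track on every call, never cached.

**SNP caller** (PLINK-style parameterization).  A window of 100
consecutive SNPs slides one SNP at a time; it passes with ≤1
heterozygote and ≤15 missing calls.  A SNP is RoH-eligible when the
fraction of windows overlapping it that pass exceeds 0.05 (the
referenced tool's hit-rate convention, exposed as a knob); maximal
eligible runs with ≥100 SNPs spanning ≥500 kb become segments from
first to last SNP.  Scaffolds with fewer SNPs than the window are
skipped with a log message.

Both callers are verified against exhaustive brute-force scans on
randomized inputs (100 parameter draws in the test suite).  The two
callers genuinely differ — the SNP caller's segment ends sit on SNPs
while the window caller's sit on window edges — and both outputs are
reported without adjudication.

**F_RoH** is Σ merged segment length ÷ total included autosomal length;
a per-scaffold variant is available.  Overlapping segments are merged
first, so F_RoH is invariant to splitting a segment into adjacent
pieces.

**Dating.**  A tract of length L Mb is assigned
g = 100 / (2 r L) generations since the two haplotypes' common
ancestor, with r in cM/Mb defaulting to 1 (an average mammalian
recombination rate).  Tracts are aggregated per individual into
half-open generation bins [k·w, (k+1)·w) with w = 5; a boundary value
(g = 5 for a 10-Mb tract) falls in the older bin [5, 10).

## Polarization

The ancestral state per site is the strict plurality allele among up to
three outgroup calls; ties and all-missing sites are unresolved, a
single surviving voter decides (logged with provenance n = 1), and
non-nucleotide symbols abstain.  This per-species majority is a
deliberate substitute for alignment-pileup consensus: shredding
outgroup genomes into 70-bp reads every 10 bp (`make_pseudo_reads`,
provided) and mapping them is an external-aligner workflow, and the
per-site allele table is the supported ingestion point, which isolates
the polarization logic from third-party alignment.

Variants are then oriented: derived dosage equals alt dosage where REF
is ancestral and 2 − alt dosage where ALT is ancestral.  Sites whose
consensus matches neither allele are dropped (never force-assigned) and
tallied by reason, as are unresolved and uncalled sites.  Polarizing an
already-polarized table re-expressed with REF = ancestral is a no-op,
and total derived dosage is invariant to which allele the input VCF
happened to call REF — the reference-bias neutralization that motivates
the whole step.

## Genetic load

Per individual and category: n_het (masked load — deleterious alleles
partially hidden from selection if recessive), n_hom_derived (realised
load — expressed now), and total_derived = 2·n_hom_derived + n_het
(additive-effects accounting; each homozygote carries two copies).
Missing genotypes enter neither numerators nor the callable count.
Counts are reported raw (the convention when individuals are sequenced
to similar coverage) and per callable site, since synthetic or uneven
data can vary callable counts; neither is asserted as the "right"
normalization.

Group differences use a two-sided Mann–Whitney U test.  When the
smaller group has ≤10 members the null is computed exactly by
enumerating all C(n₁+n₂, n₁) group assignments of the observed
mid-ranks — so the null conditions on the observed tie pattern — with
p = P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|), using the symmetry of U under
exchangeability.  Larger groups fall back to the tie-corrected normal
approximation.  Load ~ F_RoH relationships use ordinary least squares;
zero variance in either variable is an error, not a silent NaN.

## Rxy

With per-site derived-allele frequencies d estimated from observed
(non-missing) allele counts,

    L_xny(S) = Σ_{i∈S} d_i^x (1 − d_i^y)
    L_ynx(S) = Σ_{i∈S} d_i^y (1 − d_i^x)
    Rxy = [L_xny(cat) / L_ynx(cat)] ÷ [L_xny(neu) / L_ynx(neu)]

The neutral set is a seed-deterministic uniform sample of 100,000
intergenic SNPs (all of them, with a warning, if fewer exist).  Sites
with zero called alleles in either population are excluded and counted;
sites monomorphic ancestral in both populations contribute zero to all
sums and are retained harmlessly.  Swapping x and y inverts the
statistic; identical frequencies give exactly 1.

Confidence intervals are 2.5/97.5 percentiles over 100 bootstrap
replicates, resampling category and neutral sites with replacement,
independently by default (a joint mode exists behind a flag).
Percentile CIs at 100 replicates undercover slightly; the test suite's
null calibration accordingly requires coverage of 1 in ≥85/100
simulated datasets rather than 95.  A replicate producing a zero sum is
redrawn and counted.  The normalization's purpose — cancelling
population-specific, site-independent bias such as mapping bias toward
the reference lineage — is exact when category and neutral sites share
the same frequency composition and holds to first order otherwise; the
suite demonstrates both regimes.

## Synthetic data

The generator's defaults emulate the study design the pipeline targets:
two populations of five diploids at 21.4× mean coverage, background
heterozygous-site density 2×10⁻⁴ per bp, deleterious categories at
Beta(1, 9) derived-allele frequencies (mean 0.1), 2% genotype
missingness, negative-binomial depth (dispersion 10), three outgroups
at 0.99 per-site concordance with 5% missing calls, 30% of sites with
the derived allele as VCF REF (so polarization has real work), 1%
annotation-warning and 0.5% multi-allelic sites.

**Direct-planting mode.**  Background sites segregate at frequency ½
(each individual heterozygous at half of them, i.e. site density
2 × background het density); category sites draw per-population
frequencies from Betas, shareable across populations for null
experiments.  Inside a planted RoH the individual's two allele copies
are a single Bernoulli draw doubled — heterozygosity is structurally
impossible there, which is the planted-truth guarantee unit tests rely
on.  Planted tracts must lie in bounds and not overlap.

**Pedigree mode.**  Founders are unrelated draws from a common gene
pool; gametes recombine with Poisson crossovers at r cM/Mb (default 1)
and transmit down an explicit, acyclicity-checked pedigree.  The truth
set records pedigree F (kinship recursion; full-sib offspring 0.25,
first-cousin offspring 1/16) and the realized IBD tracts.  Convenience
builders spread offspring across independent founder families because
offspring of a single couple share parental gametes and their realized
F values are correlated — with a single family the family mean is
itself random with sd ≈ 0.04, which would swamp a ±0.05 recovery check.
Mean IBD tract length follows 100/(2rg) Mb with g the generations to
the common ancestor (2 for full sibs, 3 for first cousins), shortened a
few percent by chromosome-end truncation; the suite checks both within
20%.

What the generator does **not** emulate: linkage disequilibrium beyond
pedigree recombination, realistic demographic history or site-frequency
spectra, selection and purging dynamics, mutation within the pedigree,
and sequencing error beyond depth/missingness.  Passing tests therefore
show the estimators are correct under their own assumptions — RoH
boundaries, dating, load accounting, Rxy calibration — not that real
data meet those assumptions.

## Problem sizes and numerics

The test suite runs at deliberately desk-scale sizes chosen as the
smallest that leave the statistical checks well-powered: the Rxy null
uses 100 datasets of 1,000 category + 10,000 intergenic sites over ten
individuals; planted-RoH recovery uses five tracts of 0.6–4 Mb on two
25-Mb scaffolds; pedigree-F recovery uses 30 independent full-sib
families on eight 50-Mb chromosomes (≈4 Morgans).  Acceptance targets
report the problem size actually used.  Window He uses exact integer
counts throughout; degenerate cases (no callable sites, zero variance,
zero genome length, empty tracks) raise or return empty containers
explicitly rather than propagating NaN.
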