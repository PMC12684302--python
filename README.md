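# gerode — genomic-erosion analysis for conservation genomics

Small, fragmented populations erode genetically along three fronts at
once: genome-wide diversity falls, inbreeding concentrates the genome
into long runs of homozygosity (RoH), and deleterious variants drift in
frequency and become exposed in homozygous state.  `gerode` is a Python
toolkit that quantifies all three from a multi-sample VCF, the way
whole-genome resequencing studies of endangered species do it — e.g.,
comparing two isolated lineages of a threatened mammal sequenced at
~20× each.

It computes, per individual and per population:

* **Windowed heterozygosity** — heterozygous genotypes per callable
  site in non-overlapping 50-kb windows.
* **Runs of homozygosity** by two callers: a window caller (a window is
  low-heterozygosity when He falls below ⅕ of the individual's mean He;
  ≥10 consecutive usable windows, ≤0.7 missing data per window) and a
  PLINK-style SNP caller (100-SNP sliding window, ≤1 heterozygote and
  ≤15 missing calls per window).  Both keep only tracts ≥500 kb.
* **F_RoH** — the fraction of the autosomal genome inside RoH — and
  tract **dating**: a tract of length *L* Mb coalesces on average
  *g* = 100 / (2 *r* *L*) generations ago (*r* in cM/Mb; default 1),
  aggregated into 5-generation bins.
* **Ancestral-allele polarization** from up to three outgroup species
  (per-site majority consensus), turning genotypes into derived-allele
  dosages and neutralizing reference bias.
* **Genetic load proxies** per impact category (LoF, missense,
  intergenic from SnpEff-style ANN annotations): heterozygous count
  (masked load), homozygous-derived count (realised load) and the
  additive total 2·hom + het, with exact Mann–Whitney group tests and
  load ~ F_RoH regressions.
* **Rxy** — the relative accumulation of derived alleles in population
  *x* vs *y* per category, normalized by a random subset of 100,000
  intergenic SNPs and bootstrapped (100 replicates) for 95% CIs.
  Rxy = 1 means no difference; >1 an excess in *x*.

A first-class synthetic-data generator (`gerode.simulate`) produces
VCF-ready datasets with known truth — planted RoH tracts, true
ancestral alleles, per-population derived-allele frequencies, and a
pedigree mode with explicit recombination whose offspring carry IBD
tracts obeying the 100/(2rg) expectation — so every stage is testable
end to end.

## Worked example

Simulate two populations of five diploids on two 10-Mb scaffolds, with
three RoH tracts planted in northern individuals, then run the whole
pipeline:

```bash
gerode simulate --out demo/data --seed 11 --scaffold-mb 10 --n-per-pop 5 \
    --planted-roh north_1:scaf1:2000001:4500000 \
    --planted-roh north_1:scaf2:1000001:2200000 \
    --planted-roh north_2:scaf1:6000001:7000000
gerode run --vcf demo/data/variants.vcf --layout demo/data/layout.tsv \
    --populations demo/data/populations.tsv --outgroups demo/data/outgroups.tsv \
    --out demo/results --neutral-n 10000 --reps 100 --seed 1
```

`demo/results/roh_window.tsv` recovers the three planted tracts at
window resolution:

```
individual  scaffold  start    end      length_mb  n_support  caller
north_1     scaf1     2000001  4500000  2.5        50         window
north_2     scaf1     6000001  7000000  1.0        20         window
north_1     scaf2     1000001  2200000  1.2        24         window
```

`froh_window.tsv` gives F_RoH = 0.185 for north_1 (3.7 Mb of RoH on a
20-Mb genome), 0.05 for north_2, 0 elsewhere, and
`het_froh_correlation.tsv` shows the expected strong anticorrelation
between genome-wide He and F_RoH across the ten individuals
(Pearson R = −0.993, p = 7.9×10⁻⁹): bases locked in RoH contribute no
heterozygosity.  The dated tracts land in `roh_bins_window.tsv` — the
2.5-Mb tract in the [20, 25)-generation bin (g = 100/(2·1·2.5) = 20),
the 1.0-Mb tract in [50, 55).

With both populations simulated under identical derived-allele
frequency distributions, `rxy.tsv` is a null result — the CIs straddle
1:

```
category  rxy    ci_low  ci_high  n_category_sites  n_neutral_sites
LoF       1.102  0.914   1.362    487               10000
missense  1.018  0.910   1.104    1939              10000
```

Plots (`he_vs_froh.png`, `roh_generation_bins.png`, `load_bars.png`,
`rxy_ci.png`) are rendered from the TSVs alone.

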