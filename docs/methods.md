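# Methods

## Scope

`frostmas` re-implements, as a tested library, a bulked-segregant analysis
(BSA) and marker-assisted selection (MAS) workflow for frost tolerance in a
tetraploid potato half-diallel population. Read cleaning, alignment and
variant calling are out of scope: real data enter as a two-sample VCF with
per-bulk allelic depths (AD), plus TSV phenotype and marker-genotype tables.
Because the original sequencing and field data are not publicly deposited,
the package ships a synthetic-data generator that reproduces the study
*design* with known ground truth; all statistical guarantees quoted below are
statements about that generator, not about any real dataset.

## Synthetic population model

**Mating design.** 16 founders — 8 frost-tolerant interspecific lines
("FT01"…"FT08") and 8 frost-sensitive cultivars ("CV01"…"CV08") — form a
16×16 half-diallel (136 crosses including selfs). 23 crosses are viable,
drawn uniformly among pairs with at least one tolerant parent (the study
attributes cross failure to incompatibility without modelling it). Progeny
counts per cross sum to 406 (15 crosses of 18, 8 of 17, configurable).

**Inheritance.** Tetrasomic, random chromosome segregation, no double
reduction: a gamete receives 2 of the parent's 4 homologues without
replacement, so transmitted alternate-copy counts are hypergeometric
(4, dosage, 2). Unlinked loci segregate independently.

**Causal loci and linkage blocks.** Three causal loci sit at chr02:41.0 Mb,
chr05:33.5 Mb and chr09:40.5 Mb on a DM-reference-like coordinate system.
Around each locus a 6 Mb linkage block co-segregates as a unit (one 2-of-4
homolog draw per block and meiosis — the no-recombination limit for
co-located sites). Founder blocks are explicit 4-haplotype structures: 60%
of block variants ("tagging") carry their alternate allele on exactly the
homologues that carry the causal allele, the rest are background variation
with uniform(0.05, 0.95) allele frequencies independent of class. Tolerant
founders carry the causal (tolerant) allele in simplex–triplex dosage
(1 + Binomial(2, p) with class mean frequency 0.5): the tolerant lines were
*selected* for tolerance and share the introgressed wild haplotype, so the
locus always segregates in that class. Sensitive cultivars carry the causal
allele at frequency 0 — the premise of the study is that cultivated potato
lacks frost-tolerance variability. Neutral variants (default 12 000,
density ≈ 16/Mb) get class-independent uniform(0.05, 0.95) frequencies;
a neutral variant landing inside a block joins it.

**Phenotype model.** The latent injury of an individual in an environment is
`severity − Σ effect·g(dosage)` plus Gaussian noise per replicate plant,
rounded and clamped to the integer 0–6 scale. The default effect model is
additive in dosage, `g = dosage/2` (a dominant carrier mode, `g = 1[dosage≥1]`,
is a flag). Defaults: three effects of 1.2 injury units, noise SD 1.0, five
replicate plants per genotype, and two environments with severities 4.8 and
5.3 (frost in the second environment was harsher). These were
chosen so the progeny AS distribution matches the regime the study reports —
means ≈ 2.2/2.7 with CV ≈ 45–51% — and so the tolerant and sensitive parent
groups separate cleanly. Additive-in-dosage was adopted as the default after
the dominant mode proved unable to sustain a bulk allele-frequency contrast
at study scale (30+30 pools, 23×): with ~80% of progeny being carriers,
extreme selection barely shifts carrier frequency, while dosage selection
shifts pooled frequency robustly.

**Sequencing model.** Pool allele frequency is mean(dosage)/4 over the 30
members; total site depth is Poisson(23.47) (negative-binomial with variance
mean·(1+dispersion) when overdispersion is configured) and alternate reads
are binomial. Equal DNA contribution per member is assumed.

## Analysis conventions

- **AS** is the mean of replicate scores; the scale-tally form
  `Σ Xi·Ni / Σ Ni` is implemented as an independent cross-check route.
- **SD is the sample SD (n−1) everywhere** — this is the only convention
  that reproduces the published pool-frequency summaries (e.g. 4.00 ± 2.20,
  3.75 ± 6.30) from their printed counts.
- **Pool ranking** uses the mean AS across environments (configurable); ties
  at the pool boundary break by genotype id for determinism. The balance
  step greedily swaps boundary members (within `rank_tolerance` = 10 ranks)
  when a swap reduces the absolute difference in total tolerant-parent
  contribution between bulks. In the simulated population the resistant bulk
  is structurally dominated by tolerant×tolerant progeny (each contributing
  two tolerant-parent counts), so the residual imbalance stays larger than
  the near-perfect 33 vs 32 balance the study reports; the greedy step only
  helps when comparable candidates exist near the boundary.
- **ED** is used at power 1 (`ed_power` configurable); at a biallelic site
  ED = √2·Δ(SNP-index), and both statistics are computed so either can be
  cross-checked against the other.
- **Windows** are [k·step, k·step + window) in 0-based half-open
  coordinates (VCF positions 1-based, BED output half-open; conversions are
  centralised in `frostmas.io`). The window statistic is the mean ED of the
  variants in the window (median behind a flag). Windows with fewer than
  `min_window_variants` = 3 variants are emitted with a missing statistic —
  sparse windows otherwise dominate the upper tail of the threshold.
- **Threshold** = genome-wide median + 3·sample SD over scorable windows.
  **Regions** are maximal runs of super-threshold windows; `merge_gap`
  (default 0) can bridge nearby runs, which also governs whether the two
  printed chromosome-IX intervals would merge.
- **Site filters**: both bulks need ≥ `min_depth` = 8 reads; multiallelic
  records are skipped (or rejected) with counts logged.
- **Marker selection** takes variants with Δ(SNP-index) strictly > 0.25
  inside regions and thins them by greedy farthest-point selection (largest
  gap ≤ ~2× ideal spacing); names are `chrNNVk` with k by position rank.
- **Parent screen**: a genotype string observed only in tolerant parents
  codes 1; observed only in sensitive parents, or shared, codes 0 (shared
  forms are not treated as missing — published validation tables carry a
  single code for forms present in both bulks). Markers need at least one
  1-coded and one 0-coded form.
- **Spearman validation** uses midranks and the t-approximation p-value
  (an exact permutation option exists for very small panels); a marker
  passes at p < alpha (0.05) and |ρ| > 0.3 in *every* supplied environment.
  The expected sign is negative (code 1 lowers injury) and is reported, not
  enforced.
- **Tukey HSD** on genotype-level AS with Tukey–Kramer handling of unequal
  class sizes; classes with n < 3 are summarised but excluded from testing.
  The compact letter display assigns one letter per maximal clique of the
  not-significantly-different graph.

## Statistical behaviour at study scale

The acceptance suite re-derives these on every run (20 seeds at the default
configuration; they are properties of the generator + pipeline pair):

- ED ≡ √2·Δ(SNP-index) on 10⁴ random sites (dual-route identity).
- Null calibration: with no causal loci, ≤ 1% of scorable windows exceed the
  median+3SD threshold (measured ≈ 0.4%).
- Recovery: all three causal loci fall inside called regions in ≥ 90% of
  seeded runs (measured 20/20) with ≤ 1 false region per genome on average
  (measured ≈ 0.55).
- Spearman validation type-I error stays within alpha + 3·SE at n = 330 over
  1000 null replicates.

Problem sizes were chosen to make these checks cheap: 12 000 neutral
variants over a 730 Mb genome give ≈ 16 variants per 1 Mb window, and one
full simulate–pool–sequence–scan cycle takes well under a second.

## What the generator does not emulate

- Assay dropout: the study's capture-sequencing detected only 67/80 target
  sites in parents; the generator has no detection failure, so its parental
  detection rate is 100% and polymorphism rates of selected sites (~90%) sit
  above the study's 62.69%-of-detected. The screen's rejection logic is
  exercised through background variants and shared genotypes instead.
- Recombination inside linkage blocks (full linkage is the limit case) and
  linkage between blocks; EBN/ploidy crossing barriers; double reduction.
- Genotype-call uncertainty: tetraploid dosages collapse deterministically
  to hom-ref / het / hom-alt strings for the marker stage.
- Field heterogeneity beyond iid Gaussian replicate noise (no spatial or
  genotype×environment structure beyond the severity shift).

Passing tests therefore show that the *methods* behave correctly under the
stated design, not that any particular real dataset would reproduce the
published genomic coordinates — those depend on data that were never
deposited.

## Numerical and degenerate-input choices

- Gamete sampling uses the exact enumerated hypergeometric PMF via inverse
  CDF (validated against the closed form).
- Zero-depth sites are excluded, not scored; zero-variance codes or
  phenotypes fail validation with an explicit reason; two constant equal
  pools compare with p = 1 by convention.
- All randomness flows from a single integer seed per simulation; reruns are
  byte-identical, and the pipeline writes a run log with version, seed,
  config hash and per-stage record counts.
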