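# Methods

`spermpure` implements the analytical core of a sperm-methylome purity
study: detecting and quantifying somatic-DNA contamination in
swim-up-purified sperm samples, calling differentially methylated
regions (DMRs) between sample groups, screening a deep-bisulfite-
sequencing (DBS) cohort, and testing allele-specific methylation (ASM).
This note records the models, the defaults and why they were chosen,
and what the synthetic validation does and does not establish.

## The admixture model

Sperm and somatic cells differ drastically at a reproducible set of
loci: oocyte-methylated imprinting control regions (ICRs; sperm ~0%,
soma ~50%), sperm-methylated ICRs (sperm ~100%, soma ~50%),
promoters of germ-cell-specific genes (sperm ~0%, soma ~90%), and
X-linked/germline loci of the XIST/DDX4 type (sperm ~0%, soma ~85%).
A sample whose DNA is a mass fraction `f` somatic and `1-f` sperm shows
at marker `i` the level

    m_i = (1 - f) e_i + f s_i

where `e_i`, `s_i` are the pure-tissue levels. `f` is a fraction of DNA
mass (equivalently genome copies), because methylation fractions mix by
copies. Since sperm are haploid and somatic cells diploid, the somatic
*cell* fraction is `c = f / (2 - f)` (`somatic_cell_fraction`).

### Contamination estimation

`estimate_contamination` solves the model by weighted least squares:

    f_hat = sum w_i (m_i - e_i)(s_i - e_i) / sum w_i (s_i - e_i)^2

with `w_i = min(region read count per CpG, 30)` and the result clipped
to [0, 1]. The estimator is exact on noise-free mixtures for any `f`
(a property test asserts this) and, with a 500-marker panel at 15x
coverage, recovers `f` to within well under 0.01 across the full range
(the reproduction script measures ~0.003 worst-case over
f in {0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1}). A closed-form WLS was
chosen over a binomial maximum-likelihood fit for transparency; the
likelihood refinement would mainly matter at coverage far below what
the method targets. Per-marker-class estimates (ICRs vs promoters vs
XIST/DDX4-like) and their maximum pairwise difference ("consistency")
are reported because genuine contamination displaces *all* marker
classes coherently, which distinguishes it from a locus-specific
epimutation.

### Contamination classification

`classify_purity` flags a marker as aberrant when its observed level is
displaced from the sperm expectation **toward** the somatic level by
more than `tau = 0.06` — the "expected level below 6%" rule for loci
unmethylated in normal sperm, applied symmetrically (`m < e - tau`) to
sperm-methylated markers, for which the threshold direction is the
minimal extension. The verdict is:

* **contaminated** — at least `min_aberrant = 2` aberrant markers
  (contamination shows at multiple loci at once);
* **indeterminate** — exactly one aberrant marker: a single displaced
  locus cannot distinguish contamination from a true epimutation or a
  rare genetic variant, so the sample is neither cleared nor condemned;
* **clean** — no aberrant marker.

The flat 6% threshold comes from deep amplicon sequencing, where
thousands of reads make sampling noise negligible. When the same rule
is applied to WGBS region means (~10-20 CpGs at ~15x, i.e. a few
hundred reads), binomial noise alone can cross a flat 0.06 for markers
whose baseline sits away from 0 or 1. The classifier therefore requires
the displacement to exceed `max(tau, 4.5 * SE)`, where
`SE = sqrt(e(1-e)/n_reads)` is the binomial standard error at the
marker's observed read count (with `e` clipped to [0.01, 0.99]). For
DBS depths the guard is inactive and the rule reduces to the plain 6%
threshold; for WGBS it suppresses rare noise-driven flags without
affecting detection at `f >= 0.05`, where many markers are displaced at
once. By default aberrance is counted over the whole marker panel; a
`core_markers` argument restricts it to designated screening loci
(MEST/H19/XIST/DDX4 analogues) when only DBS data are available.

### Conversion rate

Bisulfite conversion is estimated from the unmethylated spike-in
contig as `1 - sum(n_meth)/sum(depth)`; every methylated call there is
an under-conversion event.

## DMR calling

The caller is a seed-and-extend segmentation over per-CpG group
differences, with region-level testing:

1. A CpG is *usable* if covered at `min_cov` (default 5) reads in every
   sample of both groups; the per-CpG difference `d_i` is the
   difference of group mean levels.
2. Candidates are maximal runs of consecutive usable CpGs with
   same-sign `d_i`, `|d_i| >= seed_frac * min_diff` (seed_frac 0.5),
   and at most `max_gap = 300` bp between consecutive members; runs
   shorter than `min_cpg` CpGs are dropped. The half-strength seed
   threshold exists because per-CpG noise at ~15x would otherwise
   fragment true regions; the full `min_diff` is still enforced at
   region level.
3. Each candidate gets per-sample coverage-weighted region means, the
   group difference of means, and a two-sided Mann-Whitney U p-value on
   the pooled per-CpG-per-sample levels (k CpGs x n_A samples vs
   k x n_B values). Pooling CpGs is what makes 2-vs-2 comparisons
   testable at all and follows common DMR-caller practice, but it
   treats CpGs within a region as independent replicates, which they
   are not; the resulting p-values are anti-conservative in absolute
   terms and should be read as a ranking device that, combined with the
   effect-size and coverage filters, controls the list. q-values are
   Benjamini-Hochberg across the candidates of one calling run.
4. Filters: `n_cpg >= min_cpg`, `|diff| >= min_diff`, every sample's
   mean region coverage `>= min_cov`, `q <= max_q`. The coverage
   requirement is applied both per-CpG (usability) and per-sample-mean
   (filter) because the source procedure is ambiguous between the two;
   applying both is the conservative reading.

Two presets exist: soma-vs-germline (10 CpGs / 0.80 / cov 5 / q 0.05)
and case-control (5 CpGs / 0.30 / cov 5 / q 0.05). One caller with two
presets replaces the original two-tool setup (a t-statistic caller plus
a rank-based caller); `merge_dmr_sets` retains the ability to combine
two DMR sets by interval union of overlapping or book-ended regions
(statistics recomputed over the union; an intersection mode keeps only
regions supported by both sets, since how single-caller regions were
reconciled is not specified).

Downstream: promoters are `TSS +/- 2000` bp (clipped at 0) of
protein-coding, lncRNA and miRNA genes; a DMR annotates to a gene on
>= 1 bp overlap. `range_filter` keeps case-control DMRs whose
reference-group per-sample means span strictly less than 0.3 — a guard
against genetic-background-driven regions with high within-group
spread. `rank_for_validation` orders DMRs by how many test-cohort
values fall outside the reference cohort's [min, max], ties broken by
larger |diff| then coordinate.

## DBS screening and ASM

`pca_screen_classify` runs a PCA on per-sample MEST-like and H19-like
DBS means. Covariance (unscaled) PCA is the default because both
variables are methylation fractions on the same scale; a `scale` option
exists because the original analysis does not state its choice. PC1 is
oriented so displacement toward the somatic profile (higher MEST, lower
H19) is positive; the threshold is the 95th percentile of PC1 over
**all** samples (again with a switch, since "the samples" could be read
as controls only), and an oligozoospermic sample strictly above it is
AMO, otherwise NMO. Normozoospermic samples are NC by definition —
class labels are diagnosis-conditional. Note an inherent property of a
strict percentile rule: in a cohort with no contaminated samples it
still flags ~5% of samples on measurement noise; only a fully
degenerate (identical-values) cohort yields zero AMO.

Amplicon reads are per-read CpG state vectors; CpG-SNP columns are
masked from every summary (the H19-like amplicon has 15 CpGs, one
masked, 14 analyzed). Epialleles are classified on the per-read mean
over non-missing unmasked CpGs with thresholds 0.9/0.1 — "completely"
methylated/unmethylated is given a tolerance because with 14 CpGs and
~1% per-CpG error a strict all-or-none definition would misclassify
~13% of canonical molecules.

ASM: reads are split by the base observed at the amplicon's SNP
position (allele pairs containing C are rejected as
conversion-confounded), and per-read binary states at one CpG are
compared between alleles by Mann-Whitney U. Sample-level
genotype-stratified analysis uses Kruskal-Wallis across genotypes,
pairwise Mann-Whitney with Bonferroni, and within-genotype
phenotype tests.

## Statistics

Mann-Whitney U uses the exact null distribution when the combined
sample size is <= 25 with no ties (covering every per-group cohort
comparison the workflow makes), else the normal approximation with tie
and continuity corrections. The Wilcoxon signed-rank test drops zero
differences; with <= 20 remaining it uses the exact sign-flip
permutation distribution computed by dynamic programming over doubled
midranks — exact even under tied |differences| — else the corrected
normal approximation. All-zero differences return p = 1 with a
degeneracy flag rather than an error. Kruskal-Wallis applies the tie
correction and returns H = 0, p = 1 for fully degenerate input.
Exactness is verified against independent brute-force enumeration
oracles for all group sizes up to 7, and all three tests hold their
empirical size within [0.03, 0.07] at alpha 0.05 under a simulated
null. Multiple testing: Bonferroni (`min(1, m p)`) and step-up
Benjamini-Hochberg.

## The synthetic-data generator

`build_references` lays out one main contig with ~20,000 background
CpGs (methylated ~0.8 in both tissues), 34 oocyte-methylated and 16
sperm-methylated ICRs, 200 germ-cell promoters, 10 reverse-direction
promoters, 2 XIST/DDX4-like loci, plus decoy promoters (no
soma-germ difference) and orphan differential regions (no gene) that
exercise the panel filters, and a 1000-CpG unmethylated spike-in
contig. CpGs are spaced geometrically (mean 150 bp inside regions,
capped below the caller's gap limit; mean ~500 bp in background).
Region levels get Gaussian jitter (sd 0.02 between regions, 0.01
between CpGs).

`simulate_wgbs_sample` draws depth ~ Poisson(15) per CpG (emulating
13-16x sequencing) and methylated counts binomially from the admixed
level after conversion error (under-conversion 0.005, over-conversion
0.002). `simulate_amplicon_reads` draws each read from a two-epiallele
mixture with per-CpG error 0.01, an optional somatic read component at
fraction f, per-read SNP bases, and a genotype-linked reduction
(`delta_g`, default 0.25) of the methylated-epiallele success
probability at the H19-like "CpG3" on G-allele reads; the adjacent
CpG-SNP column is missing on G reads and masked everywhere.

`simulate_screen_cohort` defaults to 40 normozoospermic (f = 0) and 93
oligozoospermic samples, 7 of which are contaminated with
f ~ U(0.1, 0.6). The `study_design()` preset refines the 7 into 6
heavily contaminated (f ~ U(0.2, 0.6)) plus one H19-epimutation-like
sample (f = 0, H19 shifted down 0.25), and adds 9 mildly contaminated
samples (f ~ U(0.09, 0.11)) that sit above the XIST/DDX4 6%
detectability point (f > ~0.07 given s ~ 0.85) but below the PC1
screen. This reproduces the downstream structure of the emulated
study — 7 AMO / 86 NMO, 77 XIST/DDX4-clean NMO, and a 118-sample
genotype-analysis set — as a consequence of the design, not as
hard-coded outputs. Genotype frequencies (TT/TG/GG = 0.34/0.41/0.25)
match the study's 40/49/29 split in expectation.

### Validation studies and problem sizes

The reproduction script and the acceptance tests run, at these sizes:

* contamination recovery: one 500-marker panel (reference pools at
  30x), 24 samples at 15x over an 8-point f grid;
* verdict operating characteristics: 50 seeded cohorts x (1 pure + 4
  contaminated at f in {0.05, 0.1, 0.2, 0.5}) samples;
* caller recovery: a 50,000-CpG background with 50 planted regions,
  2 vs 2 at 15x; planted levels (0.04 / 0.90) are used *without*
  between-region jitter so every planted region genuinely meets the
  0.80 threshold on the observed (conversion-compressed) scale
  (~0.854); with jitter a fraction of "planted" regions would sit
  below the threshold and not constitute recoverable truth;
* caller null: 20 runs of 5 vs 6 samples drawn from one reference;
* ASM: delta 0.25, 1000 reads per allele, Bonferroni over 14 CpGs; and
  1000 within-genotype label permutations for calibration.

### What the generator does not emulate

Biological replicate structure beyond level jitter (no haplotype or
batch effects), overdispersed coverage (Poisson, not negative
binomial), read-level WGBS (no fragments, no strand asymmetry,
hemimethylation or mapping artifacts), locus-specific conversion
efficiency, and inter-individual genetic variation outside the one
modelled SNP pair. Passing the synthetic studies therefore shows the
procedures are correct and well calibrated under the stated statistical
model; it does not by itself certify performance on real libraries,
where coverage dispersion and mapping bias will widen the error bars.

## Known limitations

* The region p-values pool CpGs (see above); they order candidates
  well but are not calibrated significance statements.
* The marker-panel expectations `e_i`, `s_i` are plug-in estimates from
  reference samples; their sampling error propagates into `f_hat`
  (negligible at the default pooled-reference depth).
* Contaminated samples are excluded, not corrected; the admixture
  inversion `(m - f s)/(1 - f)` is provided (`correct_levels`) but off
  by default because it amplifies noise at large f.
* The percentile screen's AMO capacity is ~5% of the cohort by
  construction; more pervasive contamination would require the
  panel-based classifier rather than the screen.
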