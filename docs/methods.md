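# Methods

## Model and procedure

The pipeline couples two independent sources of evidence for a regulatory
relationship between a variant and a gene.

**Spatial evidence.** Fragment-level Hi-C reports contacts between
restriction fragments, so the genome is digitally digested with the enzyme
used to prepare the contact libraries. Cut positions are
`site_start + cut_offset` over *all* matches of the recognition word
(overlapping matches included, duplicates collapsed); fragments are the
intervals between consecutive cuts plus the two terminal intervals, giving
an exact, gap-free tiling of each chromosome. Variants are assigned to the
unique fragment containing their position; genes to every fragment
overlapping their transcript span by at least one base, by exact interval
intersection with no binning or padding. A (variant, gene) pair is
spatially confirmed when any library records a contact between the
variant's fragment and a gene fragment, with one deliberate extension: a
variant lying on a gene-overlapping fragment is confirmed without a contact
record (a fragment trivially contacts itself), marked with the
pseudo-library `self`. Contacts are treated as presence/absence with
count ≥ 1 — no matrix normalisation, distance-decay background or loop
calling.

**Statistical evidence.** For each confirmed pair and tissue, ordinary
least squares of transformed expression on allele dosage with intercept;
two-sided p from t(n−2). Expression is rank-based inverse-normal
transformed per gene and tissue, `Φ⁻¹((rank − 0.5)/n)` with ties broken by
stable input order, which makes the test rank-based and robust to the
expression scale (a raw-scale option is retained). Cohort minor allele
frequency is computed on all genotyped samples and variants below the
threshold are removed before testing. Benjamini–Hochberg adjustment is
applied once across every test of a run (all pairs × all tissues, one
family per pass); `p_adj < α` with strict inequality declares significance.
An optional per-tissue family mode exists but the pooled family is the
default and the documented behaviour.

**Two passes.** The first pass maps all variants against the focal gene.
The variants significant in pass one are re-mapped against every annotated
gene — using the same contact set — and re-tested as a fresh BH family; the
hub is the set of genes other than the focal gene with at least one
significant second-pass association. The focal gene re-tests significant
internally but is excluded from the reported hub.

**Enrichment.** Loss-of-function-constraint enrichment is a one-sided
(greater) Fisher exact test on the 2×2 of {in set / not} × {pLI ≥ 0.9 /
not}, with the study set kept inside the universe, so the test is exactly
the hypergeometric upper tail on the catalogue margins. Genes with missing
pLI are "undetermined" and counted as not-intolerant, keeping the universe
at the catalogue's full size. LOEUF is reported at the reference points
0.35 (LoF-intolerant), 0.63 (mean of essential genes) and 1.34 (mean of
non-essential genes); percentages are round-half-up to one decimal.
Promoter-motif enrichment is the per-motif hypergeometric upper tail on
TSS ± 1 kb windows with BH across motifs, computed locally from a
hit/no-hit annotation table rather than by calling an external enrichment
service.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| enzyme | MboI (`^GATC`) | digestion enzyme; HindIII (`A^AGCTT`) bundled, custom via (word, cut offset) |
| `cis_window` | 1,000,000 bp | variant-to-TSS distance separating cis from trans-intrachromosomal; the conventional cis-eQTL window |
| `maf_min` | 0.05 | cohort MAF below which variants are excluded before testing |
| `alpha` | 0.05 | BH-adjusted significance level (strict `<`) |
| transform | inverse_normal | per-gene, per-tissue rank normalisation before OLS |
| `bh_family` | pooled | one BH family per pass across all tissues and pairs |
| promoter half-width | 1,000 bp | promoter window around the TSS for motif annotation |
| pLI threshold | 0.9 | LoF-intolerance definition |

Distance is measured variant position to TSS (not gene body), matching the
cis-window convention. Missing dosages are dropped pairwise per test.
Degenerate inputs are contracts, not crashes: constant expression
(untestable gene), zero dosage variance (monomorphic in sample) and zero
residual variance (perfect fit, t undefined) each raise a typed error that
the run loop converts into a row of the skipped-tests report.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **genome** — i.i.d. uniform bases; accidental recognition words are
  disrupted and a Poisson(`site_density`·L/1 kb) number of sites is planted
  at uniform non-overlapping positions, so fragment density is controlled
  and `site_density = 0` yields an undigestible chromosome;
* **genes** — non-overlapping intervals, one per equal-width slot, random
  strand; TSS at span start (+) or end − 1 (−);
* **genotypes** — biallelic SNPs, allele frequency uniform on `maf_range`
  (default (0.05, 0.5]), genotypes binomial(2, f) under Hardy–Weinberg;
* **expression** — `y = α + β·g + N(0, noise_sd)` with nonzero β only at
  planted (variant, gene, tissue) triples;
* **contacts** — per library, Poisson(rate × n-fragment-pairs) uniform
  background pairs aggregated to counts, plus planted pairs guaranteed
  present;
* **constraint** — an exact fraction of genes (default 15.5%) receives
  pLI ≥ 0.9 with LOEUF in (0.1, 0.35); the rest pLI < 0.9 with LOEUF in
  (0.35, 2.0);
* **motifs** — a focus motif hits target-set genes at a high rate and all
  other gene/motif combinations at a background rate.

One global seed drives named per-component substreams, so changing one
component's parameters leaves the others' draws untouched; fixed seeds give
byte-identical output files. The planted truth (effects, contacts, focal
gene, co-regulated genes) is written to a JSON manifest for recovery tests.

What the generator deliberately does **not** model: linkage
disequilibrium and population structure (the analysis tests marginal
associations), expression covariates and batch effects (a residualisation
hook exists but no covariates are generated), read-level Hi-C (contacts
are drawn at fragment level), and distance-dependent contact frequency.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under the stated model — independent genotypes, Gaussian
noise, presence/absence contacts — not robustness to LD-induced
confounding or normalisation artefacts in real cohort data.

### Study designs

`simulate_focal_study` mirrors the analysis design: non-coding regulator
SNPs (on fragments overlapping no gene, as a regulator search outside the
coding sequence implies) with planted effects on one focal gene, a subset
also regulating a small co-regulated hub, and planted contacts anchoring
each regulator's fragment to a gene-exclusive fragment of its target.
Roughly 20% of regulators sit on other chromosomes, producing
trans-interchromosomal pairs. The default regulator count is 8: the
regulators of one gene share its expression variance, so with k planted
regulators of equal β the per-SNP variance share decays as 1/k and very
large k makes individual effects undetectable at any sample size — a
property of the additive model itself. `simulate_planted_pairs_study`
spreads effects over distinct genes (one regulator each) for power and
false-discovery experiments where effects must not interact; its
`all_tissues` mode plants each effect in every tissue so that every
significant (pair, tissue) result is unambiguously true or false.

## Problem sizes and numerical choices

Default study scale is 2 chromosomes × 500 kb, 200 genes, 2,000 SNPs,
100 samples, 3 tissues — chosen so a full two-pass run finishes in a few
seconds and the complete validation suite in about a minute on one core.
Repeated-seed suites (false-discovery and null-calibration, 20 seeds each)
use a reduced scale of 2 × 200 kb, 100 genes, 1,000 SNPs, 60 samples,
2 tissues, which keeps ≥ 1,000 association tests per run while holding the
whole suite to under a minute.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted at the parsing boundary. Fragment lookup is binary search over
fragment starts and is property-tested against a linear scan; digestion is
property-tested against a scan-every-position IUPAC matcher and
cross-checked against an independent restriction-analysis implementation.
BH adjustment delegates to the standard step-up implementation and is
verified against a textbook reimplementation on random p-vectors; the
Fisher p is verified against an explicit hypergeometric tail sum.
`N` in the genome matches only the recognition code `N`; lowercase
(soft-masked) sequence is treated as ordinary sequence. Ties in the
inverse-normal transform are broken by stable input order, making the
transform permutation-equivariant. TSV outputs use one dialect
(tab-separated, UTF-8, `.` decimal, no quoting) so identical runs can be
compared byte for byte.

## Known limitations

* Contact support is presence/absence; a distance-decay significance model
  would be needed for noisy real Hi-C at scale.
* Spatial support in the second pass reuses the first pass's contact set;
  tissue-matched contact filtering is not implemented.
* No covariate generation, so the covariate hook is exercised only
  structurally, not statistically.
* The motif table is an annotation input; the package does not scan
  sequence for motif occurrences.
* MAF is computed on the full cohort, not per tissue.
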