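# Methods

This note documents the models and procedures implemented in `csslpipe`,
the defaults chosen where the underlying analysis left a decision open, and
what the synthetic-data tests do and do not demonstrate.

## Introgression scan

**Model.** A substitution line and its recurrent parent are called against a
common reference. SNP records identical in both call sets are discarded; the
remaining differential SNPs are counted in fixed windows along each
chromosome. Windows whose count strictly exceeds a threshold are flagged,
and maximal runs of flagged windows merge into candidate introgression
segments.

**Defaults.** Window 5,000 reference bp, step = window (non-overlapping
tiles), threshold 100. "Window of 5,000 background nucleotides" is read as
5,000 reference bp — the reproducible interpretation; a callable-position
reading would require the callable mask of the original alignments. With
step = window, window counts conserve the per-chromosome SNP total, a
property the tests pin; a smaller step gives a true sliding scan.

**Differencing is genotype-aware by default**: a site called homozygous in
one line and heterozygous in the other is differential, because the
comparison asks where the lines differ, not which alleles exist. A locus
differing only in genotype contributes one differential record (the line's).
Presence/absence differencing is available (`genotype_aware=False`) since
the convention used for published genome-wide counts is not recoverable from
a methods description. Indels are excluded: the scan is defined over SNPs.

**Coordinates** are 0-based half-open internally; VCF/GFF readers and TSV
writers convert at the boundary (BED output stays 0-based half-open, its
native convention).

## Co-expression network

Pearson correlation over pairwise-complete samples (≥ 3 required) for every
pair involving a seed (SNP-bearing) gene; an edge is kept when r ≥ 0.95. The
cutoff is inclusive and positive-only by default — the analysis targets
co-expression, not anti-correlation; an absolute-value mode exists for
sensitivity analysis. Correlation type (Pearson) is a documented default:
the original hub list came from an external expression database whose
correlation convention is not stated.

"Major node" is deliberately a parameter, not a guess baked in: `top_k`
(default k = 18, the size of the published hub list) or `degree_min`. Ranking
is by degree descending with lexicographic tie-break, so hub sets are
deterministic and top-k sets are prefixes of the ranking.

## Prioritization

QTL intervals are resolved from flanking marker names via a user-supplied
marker map (published QTLs are marker-defined; coordinates are
assembly-dependent, so the packaged marker/QTL fixtures carry synthetic
coordinates and are named `synthetic_*`). Gene–QTL membership is any overlap
with inclusive bounds. The homolog join is a left join that never drops
candidates and expands one-to-many homolog rows (one rice locus maps to two
Arabidopsis PGRL1 paralogs in the packaged table). Ranking is lexicographic
— QTL membership, then hub degree, then gene id — because the original
prioritization was a filter cascade, not a numeric score.

## Phenomics

Green area is the count of pixels whose HSV hue lies in [0.18, 0.45] with
saturation ≥ 0.25 and value ≥ 0.20 — saturated plant greens against neutral
backgrounds. The original image segmentation is unspecified, so this
criterion is also the contract the plate-image generator satisfies exactly,
closing the loop in tests.

Growth comparisons use Welch's unequal-variance t-test (pooled-variance
Student's available via flag): the safe default when equal variances were
never asserted. Stars: `**` for p < 0.01, `*` for 0.01 ≤ p < 0.05.

The stability index for a genotype is mean(stressed areas) / mean(control
areas) at an evaluation day (default 6). Plants are unpaired across
treatments, so the variance comes from the delta method for a ratio of
independent means, Var(S/C) ≈ Var(S̄)/C̄² + S̄²Var(C̄)/C̄⁴, with a
Student-t confidence interval on Welch–Satterthwaite degrees of freedom over
the two variance components — replicate counts are small (4–8), where a
normal quantile measurably undercovers (Monte-Carlo coverage ≈ 92% vs
94.5–95.5% for the t interval at n = 6). Genotypes are compared to the wild
type by a Welch t-test on replicate-wise ratios (each stressed replicate ÷
the genotype's control group mean). Mean-based and per-replicate choices are
exposed rather than hidden because the original index's exact estimator was
not stated.

## Physiology statistics

One-way ANOVA is computed by the classical decomposition, exposing MSE and
within-group df for the post-hoc test. Duncan's multiple range test uses
critical ranges R_p = q((1−α)^(p−1); p, df) · √(MSE/n_h): the studentized
range quantile at Duncan's special protection level, computed from
`scipy.stats.studentized_range` for any df (no table lookup), cached because
the ppf is expensive. The step-down applies the containment rule — a span
whose range is non-significant silences all its sub-spans — which makes
non-significant sets contiguous in the mean ordering; compact letters are
therefore the maximal non-significant intervals, lettered `a` from the
highest mean. Unbalanced designs use the harmonic mean of group sizes
(the packaged data are balanced, n = 4).

Summary-level tests (`dmrt_from_summary`) reconstruct the pooled error from
per-group SEs: s²ᵢ = nᵢ·SEᵢ², MSE = Σ(nᵢ−1)s²ᵢ / Σ(nᵢ−1). The letter tests
use only robustly separated contrasts, since some published letter
assignments are marginal given mean ± SE at n = 4. Percent changes are
100·(reference − new)/|reference| with a round-half-away-from-zero integer
companion, matching how the headline percentages were printed.

## Synthetic data: what it emulates, and what it does not

* **Genomes** — SNPs are Poisson-placed per region (background vs planted
  segments vs shared), positions unique per chromosome by rejection
  sampling. Realized counts sit within 4σ of the Poisson expectation by
  construction checks. Defaults (background 10⁻⁴/bp; segment 0.03/bp ≈ 150
  expected SNPs per 5 kb window) reproduce the regime where a real
  introgression saturates the window threshold. Not emulated: read-level
  error, linkage/recombination structure, indels/SVs, call-quality
  filtering — recovery results say nothing about variant-calling artifacts.
* **Expression** — module members are a shared latent profile plus
  calibrated Gaussian noise: for x = z + s·ε, pairwise r = 1/(1+s²), so
  s = √(1/r − 1) hits a target correlation analytically; background genes
  are independent. Real expression data have correlated backgrounds,
  batch structure and heavy tails; passing module-recovery tests shows the
  thresholding and hub logic are correct, not that r = 0.95 is a good cutoff
  for any particular real dataset.
* **Phenotypes** — log area grows linearly at rate × multiplier with
  lognormal multiplicative replicate noise (areas stay positive; the CV
  parameterization matches replicate scatter in plate phenotyping).
  Defaults: wild type + 7 mutants, 3 treatments, daily imaging for 7 days,
  baseline 500 px, growth rate 0.45/day, n = 6 replicates, CV 0.15 — a
  plausible 48-well-plate design. The implied noise-free stability index is
  exp(rate·(m−1)·day), which is what recovery tests check. Not emulated:
  germination failures, leaf overlap/occlusion, diurnal area fluctuation.
* **Plate images** — exactly k pixels satisfy the green criterion; the rest
  are neutral gray. This validates counting, not segmentation of real
  rosettes.

## Numerical and testing choices

Simulation sizes in tests and the acceptance script (20 genomes of 2 × 5 Mb;
20 expression seeds of 60 × 50; ~2,000 null growth tests; 100 stability
seeds) were chosen so each recovery or calibration estimate has small enough
Monte-Carlo error to be meaningful while the whole suite stays quick to run.
Degenerate inputs fail loudly and early: zero-variance genes are skipped
with warnings, zero control means and zero reference values raise, segment
and marker inconsistencies raise with the offending names. Determinism:
every generator is a pure function of its config and seed; pipeline reruns
with the same seed produce byte-identical tables.

## Known limitations

Genome-wide published counts (total differential SNPs, SNP-bearing genes,
the identity of the 18 hub genes) depend on the full sequencing data and an
external co-expression database and are not reproducible from this package's
inputs; the corresponding stages are instead held to exact oracle
equivalence and synthetic recovery. The Duncan letter display assumes the
step-down containment rule (SPSS-compatible); other software variants
(unprotected pairwise Duncan) can differ on marginal contrasts. The green
criterion is a fixed HSV band, not a trained segmenter.
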