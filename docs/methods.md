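# Methods

## Scope and data model

The package analyses longitudinal case/control bulk RNA-seq cohorts. The
unit of analysis is a `CohortDataset`: an integer gene × sample count
matrix, per-sample metadata (subject, group, visit ∈ {1, 8}, sex, age,
UPDRS III, LEDD, medication class 1–7 with blank → class 7 "no
medication"), and a gene annotation table carrying genomic coordinates and
an optional fragile-site label. Gene length is the full genomic span
`end − start` (introns included), stored 1-based inclusive; BED input
(0-based half-open) is shifted on read so both encodings of one interval
yield the same length.

## Differential expression

Per-gene negative-binomial regression with log link:

    K_gj ~ NB(mu_gj, alpha_g),  var = mu + alpha mu^2
    log mu_gj = log s_j + x_j' beta_g

* **Size factors** `s_j`: median-of-ratios over genes expressed in every
  sample, rescaled to geometric mean 1; upper-quartile fallback (with a
  warning) when no gene is common to all samples.
* **Dispersions** `alpha_g`: method of moments on normalized counts with
  variance pooled within design cells, clipped to [1e-8, 100], then shrunk
  halfway in log space toward a fitted `a0 + a1/mu` trend. The halfway
  shrinkage is a deliberate middle ground: raw moment estimates are noisy at
  n ≈ 20 per arm, while full trend replacement would erase genuine
  gene-level dispersion differences.
* **Fitting**: Fisher-scoring IRLS, vectorized across genes (the design
  matrix is shared; per-iteration work is one batched weighted least
  squares). Wald z on the contrast coefficient, reported in log2 units;
  p-values from the normal reference. Genes with no variation at all get
  log2FC = 0, p = 1.
* **Design**: intercept + case indicator + covariates. Numeric covariates
  with more than seven distinct values are standardized; others are
  treatment-coded indicator blocks. A rank-deficient design raises an error
  naming the aliased columns — jointly collinear medication variables must
  be modelled one at a time rather than silently dropped.
* **Multiple testing**: Benjamini–Hochberg step-up, implemented directly
  (monotonicity enforced, capped at 1) and cross-checked in the tests
  against statsmodels and a brute-force oracle.
* **DEG calling**: strict inequalities, |log2FC| > 0.322 (fold change 1.25)
  and adjusted p < 0.05. A gene at exactly 0.322 is not a DEG.
* No shrinkage of the log2FC point estimates is applied; estimates are
  plain maximum likelihood. Low-count genes are removed before testing
  (total count < 10 across samples), and BH runs over the filtered
  universe.

## ALBATRO (length-biased transcription)

Inputs are the up/down DEG lists and the annotation. Medians are reported
in bp; the normality screen (Shapiro–Wilk, seeded subsample above n = 5000)
and the kernel densities (Gaussian kernel, Silverman bandwidth, 512-point
grid spanning the data ± 3 bandwidths) operate on log10(length). The
screen documents the non-normality that motivates a rank test; the
pipeline proceeds with the rank-sum test regardless of its outcome.

The test of record is the two-sided *unpaired* Mann–Whitney rank-sum test
(a signed-rank test would require paired observations, which independent
gene lists cannot supply; the result metadata records this choice). When
both lists have ≤ 25 genes the p-value is exact: the full permutation null
of the midrank sum is computed by dynamic programming over doubled
midranks, which handles ties and is equivalent to enumerating all
C(n1+n2, n1) assignments; the two-sided p is
P(|W − E W| ≥ |w_obs − E W|). Larger lists use the normal approximation
with tie and continuity corrections.

A comparison is *informative* only when both directions carry at least
`min_genes` (default 100) annotated genes; below that the p-value is still
reported but flagged, and empty directions yield no p at all. If every
length is identical, p = 1.

## Fragile-site enrichment

Membership comes from a curated gene → fragile-site table (HumCFS-style
export); a gene in several sites counts once, genes absent from the table
count as non-members. The statistic is the pooled two-proportion z test
without continuity correction,

    z = (p̂_down − p̂_up) / sqrt(p̂(1−p̂)(1/n_down + 1/n_up)),

two-sided p from the normal reference, with the one-sided biological
hypothesis (damage ⇒ down-enrichment) carried in a separate direction
field evaluated at α = 0.05. Two-sided is the conservative reading of a
generically stated two-proportion test; z² equals the 2×2 Pearson
chi-square without continuity correction, which the tests verify
numerically. A pooled proportion of exactly 0 or 1 carries no information
and returns z = 0, p = 1; fewer than 20 DEGs triggers an
unreliable-approximation warning.

## Gene-set enrichment

* **Ranking metric**: signed log10 p. The default `conventional`
  orientation is `−log10(p)·sign(log2FC)` so significant upregulated genes
  rank most positive, the orientation classic GSEA expects. The literal
  source-workflow formula `log10(p)/sign(log2FC)` is available as
  `as_printed`; it inverts the axis, so defaults favour the coherent
  orientation and the literal one is opt-in. p = 0 is clamped to the
  smallest positive float; log2FC = 0 scores 0; ties in the statistic are
  broken by gene ID for determinism.
* **Enrichment score**: the classic weighted KS running sum with weight
  exponent 1 — hits add `|s|/Σ_hits|s|`, misses subtract `1/(N − N_hits)`;
  ES is the extremum, the leading edge is the hit genes up to (ES > 0) or
  after (ES < 0) it.
* **Null**: for each set, `n_perm` random gene sets of the same size drawn
  from the ranked universe — fresh draws per set, because sharing draws
  across equal-sized sets would correlate their p-values. The permutation
  p is `(1 + #{|null ES| ≥ |ES|})/(n_perm + 1)`: two-sided on the ES
  magnitude with the direction reported through ES/NES. This keeps null
  p-values uniform even when the null ES distribution is asymmetric and
  makes `1/(n_perm + 1)` the smallest attainable p. NES divides ES by the
  mean |null ES| of matching sign (absent, with a warning, when fewer than
  10 same-sign draws exist). BH runs across sets, and a max-statistic FWER
  estimate (per-permutation maximum of sign-normalized |null ES| over all
  sets) is reported alongside.
* **ORA**: one-sided Fisher exact test (upper tail) on the 2×2
  DEG × set table within a stated universe, BH across sets.
* **Overlap enrichment factor**: `observed / (|A||B|/N)` with an upper-tail
  hypergeometric p. The universe defaults to the genes passing the
  low-count filter in both compared runs.

## Cohort bookkeeping

ΔUPDRS = UPDRS III(visit 8) − UPDRS III(visit 1); severe iff ΔUPDRS > 1
(Δ = 1 is mild, improvements are mild). Only patient groups are labelled;
subjects missing a visit are excluded with a logged count. Contrast
assembly produces case-vs-HC sample subsets per visit under two schemes —
patient subgroups, or mild/severe progression strata — sharing the HC arm
within a visit, skipping arms below a minimum n, and emitting a manifest.
Retrospective power uses the noncentral t distribution
(ncp = d·√(n1 n2/(n1+n2)), df = n1+n2−2, two-sided α = 0.05); the pass
rule is the effect-size exclusion d ≥ 0.6, with the computed power
reported rather than thresholded.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, with one RNG
stream so a config + seed pair is byte-reproducible:

* **Genes**: lengths 10^N(4.2, 0.6) bp (≈ 10² – 10⁶ bp, matching the span
  of human genes), a `cfs_frac` fraction labelled as fragile-site members.
* **Baseline expression**: per-gene means log-normal (ln-scale location
  4.0, spread 1.5 — median ≈ 55 counts); library sizes log-normal with
  σ = 0.15 to force the DE stage to normalize.
* **Counts**: NB with `var = mu + alpha mu²`, default dispersion 0.1.
* **Planted effects**: a `frac_de` fraction of genes gets ±`base_lfc`
  (default 1.0) with the negative direction's probability boosted by
  `cfs_down_boost` for fragile-site genes. Transcription-stalling damage
  is modelled as a genome-wide mean shift of
  `−length_bias_beta·(log10 len − median log10 len)` log2 units in damaged
  samples: every gene in the damaged arm is suppressed in proportion to
  how far its length sits above the median, which is what makes called
  down-lists skew long. Damage is encoded in the mean, not the dispersion —
  the simplest mechanism consistent with length-biased suppression.
  `severe_only` restricts damage to severe-trajectory subjects and
  `visit_effect` rescales it in their visit-8 samples, so damage can be
  placed in any severity × visit cell.
* **Trajectories**: PD baselines N(20, 6); ΔUPDRS drifts N(0, 1) for mild
  and N(5, 2) for severe subjects (severe fraction 0.67, matching a
  roughly 1:2 mild:severe split), truncated at 0. The drawn drift is
  mapped to the integer score scale with a ceiling, so the integer
  classification Δ > 1 coincides exactly with the continuous rule
  drift > 1.
* **Truth**: the per-gene true log2FC (visit-1 damaged-arm value) and DE
  flag are always emitted; parameter recovery against this table is the
  package's calibration surface.

What the generator does **not** model: batch effects, isoform structure,
read-level noise, gene–gene correlation, or any realistic covariance
between age, sex, medication and expression (covariates are drawn
independently). Passing tests therefore demonstrate correctness and
calibration of the statistics under a clean NB world, not robustness to
confounding in real cohorts.

## Problem sizes used in the checks

Calibration and power runs use 5,000-gene cohorts with 20 subjects per
arm (the regime where ≥ 100 genes per DEG direction is routinely met);
ALBATRO null calibration uses 500 replicates (200 in the acceptance
script), power 100 replicates, DE recovery 2,000 genes, and the end-to-end
severity-restricted scenario 3,000 genes × 24 subjects per arm over 50
seeds (30 in the script). These sizes give binomial standard errors well
inside the asserted tolerances while keeping a full run in the
minutes range.

## Known limitations

* Wald p-values from the NB GLM are asymptotic; at very low counts or tiny
  n they are mildly anti-conservative, which the BH step largely absorbs
  (verified empirically in the null-FDR test).
* No log2FC shrinkage: effect estimates for weakly expressed genes are
  noisier than shrunk alternatives would be.
* Gene-set permutation tests sets against random gene sets, not against
  phenotype permutations; it answers "is this set more enriched than a
  random set of the same size", which is the appropriate null for the
  ranked-list design here but differs from sample-label permutation.
* The fragile-site test treats membership as given; no coordinate overlap
  is computed.
* UPDRS III scores are simulated as integer random walks with Gaussian
  drifts; floor effects near 0 are handled by truncation, not by a
  realistic score distribution.
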