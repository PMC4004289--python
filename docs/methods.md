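# Methods

## Model

### Codon context matrix

Input is a set of validated coding DNA sequences (standard nuclear genetic
code; DNA alphabet, `U` mapped to `T` on input). Validation strips a single
trailing stop codon and rejects (strict mode) sequences with a broken
reading frame, characters outside `ACGT`, or internal stops; lenient mode
accepts `N`-containing sequences but skips every codon containing `N` (and
the two pairs it participates in), reporting the skip count. Because stops
are stripped before counting, no stop codon can appear in any pair and the
matrix is exactly 61 × 61 over the sense codons.

For each gene of L codons, the L − 1 overlapping adjacent pairs are counted;
counts are pooled across genes with equal weight per occurrence (each pair
occurrence counts once, so long genes contribute proportionally more), and
pairs never span gene boundaries. The matrix entry is the conditional
probability

P(c2 | c1, aa2) = n(c1, c2) / Σ over c2′ synonymous with c2 of n(c1, c2′),

i.e. conditioned on **both** the first codon and the second amino acid. The
conditioning choice is forced by the single-codon amino acids: Met and Trp
columns must read 1 wherever observed, which conditioning on the first codon
alone would not produce. Contexts (c1, aa2) with zero observations are
stored as exact zeros — no pseudocounts — so that design-time behaviour for
unseen contexts is an explicit, separate policy rather than a hidden prior.

Rows and columns are labelled by the 61 sense codons in alphabetical order.
This canonical order is load-bearing: it fixes the file format, the
tie-break in table design, and the inversion order of the sampler, making
every output reproducible across machines.

The companion codon usage table stores per-codon counts, within-synonym-group
relative frequencies (summing to 1 per observed group), and per-1000-codon
frequencies; trailing-stop counts are tallied separately so all 64 codons
are reportable, but stops never enter relative frequencies.

### Probabilistic gene design

A design is generated left to right, one codon per residue:

* position 1: the codon is drawn from the training marginal of the first
  amino acid (second-codon occurrences pooled over all first codons). For a
  Met start this is necessarily ATG.
* position i > 1: the codon is drawn from P(previous codon, ·) restricted to
  the synonym group of residue i.
* unseen context (c1, aa): fall back to the amino acid's training marginal;
  if the amino acid was never observed at all, uniform over its synonym
  group. Each fallback increments a counter recorded in the result, so
  designs against sparse matrices are auditable.

RNG contract: a single NumPy `default_rng(seed)`; exactly one uniform draw
is consumed per codon position (including single-codon positions, which are
forced without a lookup), and the codon is selected by cumulative-probability
inversion over the synonym group in canonical codon order. Consuming a draw
even at forced positions keeps the draw index equal to the residue index,
so the stream alignment — and hence the output — is a pure function of
(protein, matrix, seed). `design_variants(n, seed)` uses derived seeds
seed, seed+1, …; duplicate variants are permitted (variants are independent
draws, not a de-duplicated set).

Table-based design maps each residue to its highest-relative-frequency
codon, ties broken to the alphabetically smallest codon. No sequence-level
post-filters (restriction sites, GC windows, RNA structure) are applied.

The pair-frequency audit tabulates, for every context used by a set of
designs, the empirical codon fractions against the matrix probabilities;
for a calibrated sampler the maximum absolute deviation shrinks as
O(1/sqrt(n)) in the number of designs.

### Drift and subsampling

Drift between two conditions is ‖A − B‖_F over the 61 × 61 probability
matrices — not the count matrices, which would scale with corpus size.
Cells for contexts unobserved in either matrix contribute their stored
zeros; no masking, so the metric is a plain entrywise difference of the
stored matrices and satisfies the norm axioms exactly.

The subsampling experiment draws, for each size in
{30, 50, 100, 150, 200, 250, 300} (5 replicates by default), a
without-replacement random gene sample, builds its context matrix, and
records drift to the reference; the mean/sample-sd per size form the drift
curve, and y = A·x^b is fitted by ordinary least squares on
(log10 x, log10 y), A = 10^intercept, b = slope. Standard errors of the
log-space coefficients are reported from the OLS covariance. Sizes with
zero mean drift (e.g. the whole genome subsampled at full size) are
excluded from the fit; the fit is omitted when fewer than two positive
sizes remain.

Much of drift at small n is pure sampling noise (unobserved contexts read
as 0 against a dense reference), which is exactly why the random-baseline
curve matters: a condition set is only interesting if it sits above the
baseline at its own size.

## Synthetic data

The generators emulate the workflow's real inputs — a genome-scale control
set, a top-N high-expression set, a differential-expression summary —
with known ground truth:

* **Genomes.** Each gene is a first-order Markov chain of codons: the
  amino-acid path is uniform i.i.d. over the 20 amino acids, and the codon
  at each step is drawn from the generator matrix's conditional given the
  previous codon (marginal at the first position). The uniform path keeps
  the generator's conditional structure exactly equal to what the estimator
  estimates, making parameter recovery a clean consistency check. Generator
  matrices are Dirichlet draws per context (concentration 1 by default;
  0.3 for "bias" matrices, giving the more extreme codon preferences
  expected of a highly expressed regulon). An optional bias mixture routes
  a known fraction of genes through a second matrix, creating a flagged
  subset with genuinely distinct codon-pair usage.
* **Expression tables.** Values are log-normal with a 2-natural-log-unit
  mean shift for biased genes and log-scale sd 0.6 for both groups. The
  shift is the documented effect-size default; the sd is set so that a
  top-100 selection from 1,000 genes recovers ≥ 80 of 100 biased genes
  (median over seeds) — strong but not deterministic recovery. Log-fold
  changes are N(2, 0.5) for biased and N(0, 0.3) for background genes;
  adjusted p-values uniform on [0, 0.01] vs [0, 1].
* **Proteins.** Uniform i.i.d. residues with a forced Met start.

What the synthetic data does **not** model: real gene-length distributions
(yeast genes average ~450 codons; simulations use 60–300), amino-acid
composition bias, GC isochores, correlated expression noise, probe-level
microarray artefacts. Passing tests therefore demonstrate correctness of
the estimators and samplers under the model's own assumptions, not that any
particular organism's condition-specific sets will show a given drift.

## Selection rules

Top-N selection ranks by descending value with ties broken by ascending
gene id. Differential selection applies strict inequalities
(adj_p < 0.05, |logFC| > 1 by default, direction up/down/both), ranks
survivors by descending |logFC|, and truncates to N when asked. Zero
survivors is a logged warning, not an error. Both selectors are
deterministic and independent of input row order. Ranking by |logFC| rather
than p-value is a package choice: the fold change is the thresholded
quantity, and the deterministic tie-break makes gene lists reproducible.

## Numerical and format choices

* Matrix TSV stores probabilities at 17 significant digits (lossless for
  float64) with a companion `.counts.tsv` of integer pair counts and
  `#`-prefixed metadata lines; reading verifies the 61-label canonical
  order and the [0, 1] probability range.
* All stochastic operations require an explicit seed; derived seeds are
  consecutive integers. CLI outputs are written via temp-file-and-rename.
* Drift on probability matrices is computed with `numpy.linalg.norm(
  A - B, ord="fro")`; tests cross-check it against an explicit
  3,721-cell double loop at 1e-12.

## Problem sizes used in tests

Unit tests use a 120-gene × 60-codon genome; the end-to-end checks use
300–1,000 genes of 60–300 codons, chosen as the smallest corpora at which
the estimators' behaviour (recovery, drift decay, biased-subset contrast)
is unambiguous.

## Known limitations

* The conditional-probability estimator is unbiased but noisy at realistic
  corpus sizes: a context observed n times carries binomial standard error
  sqrt(p(1−p)/n), so entrywise agreement with a generator at ±0.02
  requires thousands of observations per context — far more than a
  500-gene × 300-codon corpus provides (~400 observations at best for
  ATG/TGG rows). Tests therefore check calibration (errors within 5
  binomial standard errors, shrinking with corpus size) rather than a
  fixed small entrywise bound.
* First-codon choice and the unseen-context fallback are package policies;
  training corpora rarely constrain them, but they are recorded per design
  (method, seed, fallback count) for auditability.
* No statistical significance is attached to drift values; the random
  subsample baseline is the intended comparator.
* Single (standard nuclear) genetic code; no CAI/CBI/Nc metrics; no
  restriction-site or RNA-structure post-processing.
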