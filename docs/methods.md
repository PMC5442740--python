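# Methods

## Scope and model

`iquantdep` implements the desk side of a 4-plex iTRAQ differential
proteomics study: given scored peptide-spectrum matches (PSMs) with four
reporter-ion intensities per spectrum, it estimates per-protein relative
abundances (treated/control) at two timepoints, calls three classes of
differentially expressed proteins (DEPs), and tests DEP lists for
over-representation in functional gene sets and neural cell-type marker
sets. Channel semantics are fixed by the study design: 114 = control at
1 day, 115 = control at 2 months, 116 = treated at 1 day, 117 = treated at
2 months, with R = 3 replicate experiments.

## Target-decoy FDR

PSMs from a concatenated target+decoy search are filtered by the simple
count-ratio estimator: FDR(s) = #decoys(score ≥ s) / max(1, #targets(score ≥ s)),
capped at 1. The q-value of a PSM is the minimum FDR over thresholds at or
below its score, so q is monotone nonincreasing in score; targets with
q < 0.01 (strict) are retained. Decisions baked in:

* no +1 correction by default (the convention of the tool family the
  estimator descends from); `compute_fdr(..., plus_one=True)` enables it;
* tied scores share one threshold, so decoys at a tied score count against
  the targets there — the conservative tie policy;
* q-value filtering is the default, raw threshold FDR is available via
  `filter_fdr(..., use_q=False)`;
* PSM-level only; protein-level FDR is out of scope.

The estimator is calibrated under the usual concatenated-search
assumption: incorrect target matches and decoy matches are equinumerous
draws from the same null score distribution. `simulate_score_mixture`
builds a labelled mixture embodying exactly that assumption; on 10,000
target PSMs the realized false-discovery proportion at the nominal 1%
threshold lands within ±0.005 of nominal (measured by the acceptance
script). Real search engines violate the assumption in various ways
(score-dependent decoy bias, shared peptides); the calibration result is a
correctness check of the estimator, not a claim about any particular
engine.

## Quantitation

PSMs are collapsed to one row per (peptide, replicate) by summing raw
intensities per channel — standard reporter-ion practice. Peptides mapping
to more than one protein are excluded before any ratio is formed
(unique-peptide parsimony). Rows containing a zero or missing intensity in
any observed cell are dropped entirely, with no imputation; this is the
simplest defensible policy and is exercised by the generator's optional
`dropout_rate`. A consequence is that normalization operates on the
complete-case peptide matrix.

Quantile normalization is applied jointly across all 4 channels × R
replicates (12 columns) on the log2 scale: each column is mapped onto the
row-means of the column-sorted matrix, ties receiving the mean of the
reference values their ranks span. Per-replicate normalization (4 columns
at a time) is available as `mode="per_replicate"`. Whether normalization
is joint or per-replicate, it equalizes channel loading biases but, being
rank-based, it is not an exact operation when true differential signal
shifts ranks between channels: with planted effects the normalized values
differ from the unnormalized ones by a small rank-remapping distortion.
For that reason the noise-free exactness validation (below) runs with
`mode="none"`; on noise-free, unit-bias data there is nothing for
normalization to correct.

Per peptide and replicate, log2 ratios are 116−114 (1 day) and 117−115
(2 months). The protein-level log2 abundance per (protein, replicate,
timepoint) is the minimizer of the L1 objective Σ|rᵢ − ρ| over the
protein's peptide ratios. The closed form — median for odd n, midpoint of
the two central order statistics for even n (the documented tie policy on
the flat segment of the objective) — is the production path; an explicit
linear program (scipy `linprog` on the standard epigraph formulation) is
retained as `method="lp"` and cross-checked against the closed form and a
grid-search oracle in the tests. Peptide weighting is not applied;
"nonredundant peptides" counts distinct peptide sequences (modifications
and charge ignored), maximum over replicates.

## DEP selection

Per timepoint: mean replicate log2 fold-change, two-sided one-sample
Student's t against 0 (df = R−1), and fold-change magnitude
2^|mean log2FC| ≥ 1. A protein is a 1-day or 2-month DEP when p < 0.1, it
has ≥ 2 nonredundant peptides, and its magnitude strictly exceeds the 90th
nearest-rank percentile (k = ⌈q/100·n⌉-th smallest) of the magnitude
distribution over **all** quantified proteins at that timepoint — using
the full (mostly null) population makes the cutoff an adaptive estimate of
the null fold-change spread, which is what produces cutoffs in the
1.2–1.5-fold range on largely-null data. The 2-month/1-day class is
selected among 2-month DEPs by a two-sided pooled two-sample t on the
per-replicate log2 fold-changes (unpaired; pairing of replicates across
timepoints is not assumed) at p < 0.1, together with a normalized
fold-change — 2^(mean₂ₘ − mean₁d), folded to magnitude — above its own
90th nearest-rank percentile. Direction is the sign of the mean log2FC.

Deliberate choices: two-sided tests throughout (sidedness unstated in the
source convention; two-sided is conservative); nearest-rank rather than
interpolated percentiles (order-statistic exact, deterministic at small
n); **no multiple-testing correction** — the raw p < 0.1 rule reproduces
the analysis convention this pipeline encodes, and the output should be
read as a screening list, not an FDR-controlled discovery set. Zero
sample variance yields a degenerate p (1 if the mean equals the null, else
0) with a warning; this arises only on noise-free synthetic data.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) including the observed overlap, with the universe equal to the
quantified proteins intersected with the collection's namespace
(background correction in the CPDB style; gene symbol = protein id in
synthetic data). Functional sets pass at p < 0.1 with ≥ 3 overlapping
DEPs; a Benjamini–Hochberg column is emitted for information only.
Because the source convention is ambiguous about direction stratification,
results are emitted for up, down, and pooled ("all") queries per DEP
class. The cell-type profile tests exactly the neuron / astrocyte /
oligodendrocyte marker sets for up and down queries of each class
(18 results) and flags significance at p = 0.05, the reference line drawn
on the corresponding bar charts. Genes belonging to several marker sets
would be retained in all of them (the generator's sets are disjoint, real
marker panels overlap).

## Synthetic-data generator

The generator is first-class, tested code, not a fixture. Per protein: a
baseline log2 intensity ~ N(16, 2²) (≈65k-count reporter scale); 5–10
peptides, each with a N(0, 1) log2 offset; per replicate and channel, the
intensity is 2^(baseline + offset + channel log2 bias + condition effect
+ N(0, σ)) with σ = 0.2 by default. Planted effects: 10% of proteins per
timepoint receive a sign-symmetric effect of magnitude |N(1.0, 0)| = 1.0
on the log2 scale (half up, half down). Decoy rows (15% of PSMs) carry
`REV_`-prefixed accessions and scores from N(2, 1) against the target
N(8, 2); at these settings the 1% FDR filter removes essentially all
decoys and ~1–2% of genuine targets. Cell-type sets are filled to sizes
(144, 149, 137) for neuron / astrocyte / oligodendrocyte — a 1/10 scale of
the 1,441 / 1,489 / 1,371-gene marker panels typical of curated brain
cell-type catalogs, against the 1,000-protein universe — by weighted
draws in which an up-regulated 2-month protein joins the oligodendrocyte
set with 5× odds; remaining slots are filled uniformly, and the three sets
are disjoint. Ten random functional sets (20–60 genes) exercise the
gene-set path. All draws consume a single `default_rng(seed)` stream in a
fixed order, so identical configs are byte-identical.

These defaults are the benchmark condition the validation suite measures;
they were chosen as a realistic desk-scale stand-in (per-protein peptide
counts and intensity CVs are not published for the motivating design, so
noise parameters favor testability). What the benchmark does **not**
emulate: isotope impurity leakage between channels, intensity-dependent
(heteroscedastic) reporter noise, ratio compression from co-isolation,
missingness correlated with abundance, shared/degenerate peptides, and
protein inference ambiguity. Passing tests therefore demonstrate that the
pipeline's statistics do what they claim under the stated generative
model — not that the thresholds would achieve the same sensitivity or
error rates on real LC-MS/MS data.

## Problem sizes and numerics

The standard validation runs use 1,000 proteins × 3 replicates
(~26k PSMs), 10 seeds for the enrichment-recovery measurement, 10,000
target PSMs for FDR calibration, 1,000 random instances against the
grid-search L1 oracle (grid [−4, 4], step 1e-4), and exhaustive rational
enumeration of every hypergeometric parameter triple with universe ≤ 12
plus 200 large random triples against an exact big-integer reference.
p-values are floored at 1e-300 before −log10 transformation. Percentile
cutoffs use strict inequality, so at most 10% of proteins can pass a 90th
percentile filter even before the p-value and peptide-support conditions.

## Known limitations

* Protein inference is reduced to shared-peptide exclusion; a protein
  quantified only by shared peptides is silently absent from the output
  (counted in the run report).
* The complete-case missing-data policy discards an entire peptide row on
  a single missing cell; with high dropout this is wasteful, and an
  imputation-aware normalization would be needed.
* p < 0.1 without correction, by design, inflates family-wise error; the
  BH column is informational.
* The two-sample test at R = 3 per group has df = 4 and little power;
  the normalized-fold-change percentile filter does most of the work in
  the 2-month/1-day class.
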