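# Methods

`mutrec` detects positively selected non-coding somatic mutation hotspots in a
tumor cohort by comparing observed cross-patient recurrence against a
covariate-aware background mutation model. This note documents the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the problem sizes used by the shipped validation suite.

## Background mutation model

Each base j of the analyzable genome (everything left after masking coding
sequence, immunoglobulin loci, and poorly mappable regions) has, for tumor i,
a mutation probability

    q_ij = logit^-1( b0 + b_pid(i) + sum_c beta_c x_c(j) )

where `pid` is a per-patient fixed-effect intercept capturing mutation burden
and x_c are categorical genomic covariates: replication timing discretized
into 8 equal-occupancy bins, local mutation rate (cohort count per analyzable
bp in 100 kb bins) in 10 bins, binarized chromatin/TF tracks (p-value signal
tracks cut at p <= 1e-4), and reverse-complement-canonical sequence context
(1/3/5-mers plus 1-2 bp flank motifs; poly-A/T/G/C run flags for the indel
model). SNVs and indels get separate models. The fit is a binomial GLM on the
frequency table of mutated / non-mutated site counts per covariate
combination and patient — likelihood-identical to the per-site Bernoulli fit
(asserted in the tests to 1e-6) but orders of magnitude cheaper.

Numerical guards: a patient with zero mutated training sites has an
unbounded intercept MLE; it is assigned the minimum fitted patient effect and
flagged. Suspected separation (non-finite or absurdly large coefficients)
triggers a refit with a tiny L2 penalty (1e-6) and a warning. Unseen covariate
levels at prediction time raise an error by default; a reference-level
fallback is opt-in.

### Feature selection

Candidate continuous features (the mean track signal over an 11 bp window
centered at each site) are screened by L1-penalized logistic regression on
all mutated sites plus an equal number of uniformly sampled non-mutated
sites. The penalty is chosen per fit by 10-fold cross-validation at the
one-standard-error point on binomial deviance (the largest penalty whose CV
deviance is within one SE of the minimum), computed over a 15-point
log-spaced penalty grid from the analytic lambda_max down 3 decades, with
features standardized within each fit. The procedure is repeated on 100
bootstrap half-samples; features selected in more than 95% of bootstraps
enter the final categorical model. The two representations (continuous for
selection, categorical for the final fit) are mapped by track name.

### CBS-specific model

For CTCF binding sites (CBSs: PWM motif hits supported by a ChIP peak and,
for the tissue-specific set, a DNase site), the model universe narrows to
CBS +/- 5 bp and the covariates change: a loop-boundary indicator, tumor
molecular subtype (GS as reference level), per-tumor signature-1 and
signature-17 fractions as continuous covariates, plus re-selected sequence
context. Per-patient fixed effects are off by default in this model: subtype
and the signature fractions are themselves patient-level regressors, and
patient dummies would make them unidentifiable (rank-deficient design). They
can be enabled (`patient_effects=True`) when prediction alone matters, since
fitted probabilities remain well-defined under rank deficiency.

## Recurrence test

For a region of length l, tumor i carries at least one mutation with
probability `p_i = 1 - prod_j (1 - q_ij)`, computed in log space. The number
of mutated tumors K is Poisson-binomial; a region's p-value is the exact
upper tail Pr(K >= k) for k = the number of *distinct* mutated samples,
computed by truncated dynamic-programming convolution (O(n k), exact to
machine precision; verified against 2^n enumeration for n <= 12). A refined
normal approximation (continuity-corrected, with a skewness term:
CDF ~ Phi(z) + gamma (1 - z^2) phi(z)/6) is available as a prefilter for
large scans; reported p-values are always the exact tail. The prefilter
contract, asserted in the tests, is that keeping the top 2% of candidates by
the approximation retains every candidate in the exact top 1%.

Scans and their Bonferroni universes:

* focal windows — width 2*flank+1 (default 21 bp; 41 bp robustness flag) at
  every distinct mutated position, tested when >= 3 samples (SNVs) or >= 2
  (indels) are mutated; corrected by the analyzable-genome base count;
  overlapping significant windows merge into hotspots (minimum constituent
  p, union of samples).
* genes — each gene's merged non-coding region (span extended 1 kb at both
  boundaries, minus CDS and the genome mask), indel recurrence; corrected by
  the number of genes tested. The 1 kb extension is applied at both ends; the
  promoter is strand-ambiguous without transcript orientation, and the
  symmetric choice is conservative.
* CBSs — one test per CBS +/- 5 bp under the CBS-specific model; corrected by
  the CBS count.

The min-recurrence prefilter is a compute saver: windows below it could never
reach genome-wide significance at these cohort sizes, but it does make the
retained p-value population conservative rather than uniform, which is why
calibration diagnostics condition on the model rather than on the scan (see
below).

Because K is discrete, the exact tail evaluated at the observed k is
super-uniform under the null and cannot pass a literal uniformity test at any
sample size. Calibration diagnostics therefore use the standard randomized
(uniformized) p-value `Pr(K >= k+1) + U * Pr(K = k)` with U ~ Uniform(0,1),
which is exactly uniform when the model is correctly specified. Randomization
is used only in diagnostics, never in reported results.

## Artifact filters and sample QC

Somatic calls are removed when (1) population allele frequency > 1%,
(2) panel-of-normals fraction > 10%, (3) panel-of-normals fraction > 1% within
20 bp (edge-to-edge) of a common indel, or (4) an indel overlaps a reference
mononucleotide run >= 8 bp. Missing annotations pass (filters must not
silently drop unannotated cohorts); every removal carries its rule id.
Samples with < 400 calls are excluded, as are oxidative-damage outliers whose
pyrimidine-strand C>A fraction exceeds the cohort mean + 3 SD — the threshold
is a conservative outlier rule, configurable, and the check is skipped with a
warning for cohorts of fewer than 3 samples.

## Synthetic cohorts

The generator draws mutations as independent Bernoulli trials per
(base, patient) with exactly the logistic rate structure the inference
assumes — sampled as binomial counts per constant-rate segment with uniform
placement, which is distributionally identical and scales to tens of
megabases. It emulates: per-patient burden variation (log-normal multiplier,
mean 1), piecewise-constant covariate tracks with planted logit-scale
effects, focal hotspots (per-patient mutation probability in a window),
CBS-wide rate elevation with subtype-specific folds and a positively selected
CBS subset, TFBS rate depletion, clonal/subclonal VAFs (Beta mixtures around
purity/2), SCNA segments with breakpoints coupled to mutated CBSs, and
TAD-scoped expression shifts in mutated samples.

It does not emulate: realistic human sequence composition (the genome is
i.i.d. uniform ACGT), mutational-signature trinucleotide structure beyond an
optional A/T-biased CBS spectrum, kataegis or other clustered processes,
copy-number-driven VAF distortion, or caller artifacts. Passing tests
therefore demonstrate correctness of the statistics under the stated
generative model, not robustness to real-data model misspecification.

Preset study conditions (all on a 50 Mb, 5-chromosome genome unless noted):

* `null` — 50 patients, 1e-6/bp, no planted structure.
* `planted-hotspots` — null plus one 21 bp locus mutated with per-patient
  probability 0.2 (~10/50 patients).
* `cbs-rates` — 150 tumors (CIN 60 / GS 53 / EBV 22 / MSI 15), 100,000
  19 bp CBSs with 1 kb flanks. Per-subtype flank rates are solved at
  generation time so the pooled CBS rate is 11 mutations/Mb, the pooled flank
  rate 3.6/Mb, and the CBS/flank folds are CIN 7.1, GS 4.7, EBV 1.7, MSI 1.0
  (CIN/GS/EBV share a flank rate; MSI, mismatch-repair deficient, takes its
  own much higher rate, ~18.7/Mb). The CBS universe is sized so the pooled
  CBS-rate Monte-Carlo SE is below 2%; per-patient burden dispersion is 0 in
  this preset because unbudgeted between-patient variance would break that
  sizing.
* `tfbs-depletion` — 300 tumors, 10.6/Mb background, TFBSs covering 1% of the
  genome with the inside/outside rate ratio solved so the expected fraction
  of mutations inside TFBSs is 0.58%.
* `cbs-selection` — 2 Mb genome, 250 tumors, 4,010 CBSs with a genome-wide 3x
  CBS elevation (q = 5e-4/bp at CBSs) of which 10 carry an extra 10x
  selection multiplier; sized so a selected CBS clears Bonferroni (0.01 over
  the CBS count) while non-selected CBSs remain calibrated.

## Validation-suite problem sizes

The statistical acceptance tests run the full pipeline at desk scale: exact
tails against brute-force enumeration up to n = 12 and closed-form binomials
to n = 500; approximation quality and prefilter safety on 10,000 candidate
regions with n = 200; background-model coefficient recovery over 20
replicates of a 5 Mb, 50-patient cohort with 5 informative (+20 noise)
covariates aggregated in 5 kb blocks; LASSO stability over 2 replicates of
100 bootstraps on 5,000 sites x 25 features; hotspot FWER and power over
20 + 20 replicates of 5 Mb cohorts; and the CBS selection-vs-elevation
discrimination on the `cbs-selection` preset. `scripts/acceptance.py`
regenerates the `cbs-rates` and `tfbs-depletion` presets from the given seed
and reports the five cohort-level quantities above.

## Known limitations

* The genome-wide fit aggregates exhaustively over covariate combinations;
  with many high-cardinality covariates the table grows multiplicatively
  (subsampling is the intended escape hatch, configurable upstream).
* The CBS model treats the motif +/- 5 bp uniformly; within-region rate shape
  (motif core vs flank) is integrated out, which is correct for the
  region-level test but not for base-level inference.
* Patient intercepts are fixed effects; cohorts with very low per-patient
  counts would benefit from shrinkage the model does not implement.
* The LOD enrichment SE is the delta-method propagation of the binomial
  error of the observed fraction; the expected fraction (a bp share) is
  treated as exact.
* Window-scan p-values below ~1e-300 underflow to 0; they are far past any
  Bonferroni threshold, so only the reported magnitude, not significance, is
  affected.
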