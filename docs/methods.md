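# Methods

This note documents the models, conventions and design choices behind
`dosestrat`, in the order the pipeline runs. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## DVH representation and lateralization

A curve is a cumulative dose-volume histogram: for each dose `d` (Gy), the
fraction of organ volume receiving at least `d`. Curves live on arbitrary
strictly ascending grids with relative volume in [0, 1]; interpolation is
linear in both axes and volume is 0 beyond the last grid point, so
vendor-specific grid spacing does not matter (feature extraction is
invariant to grid refinement, asserted in the tests). A grid not starting
at 0 gets a (0, 1) point prepended; a supplied (0, v<1) point is kept,
encoding the fraction of the organ receiving any dose at all. Volume that
increases along the grid is rejected, or isotonically clipped (running
minimum) under an explicit repair flag.

Paired organs (parotid and submandibular glands) are stored side-neutrally.
One *global* primary side per patient is chosen — the side whose summed
mean dose over all paired organs is higher — and every pair is relabeled
ipsilateral/contralateral accordingly. A per-pair independent choice was
the design alternative; the single primary side was adopted because the
stratification concept is one dominant treatment side per patient, and it
makes lateralization idempotent and invariant to global left/right
relabeling. Exact ties go to the left side (an arbitrary but documented
deterministic rule).

## Dose features

Two conflicting community readings of "Vx" both appear in practice, and
both are implemented:

* `dose_at_volume(curve, x)` — the dose delivered to at least x% of the
  organ (inverse cumulative DVH), in Gy. Returns 0 when less than x% of
  the organ receives any dose, which is what makes rules like
  "contralateral parotid V45 > 0" meaningful (it reads "more than 45% of
  the gland is irradiated at all"). Cluster features use this reading.
* `volume_at_dose(curve, d)` — percent of volume receiving at least d Gy
  (QUANTEC-style). Published organ dose limits (e.g. larynx "V50 > 27 %")
  use this reading.

`mean_dose` is the trapezoidal integral of the cumulative curve over its
dose support (equal to the volume-weighted mean dose); `max_dose` is the
largest dose with positive volume (configurable volume epsilon).

Per symptom, patients are encoded organ-major as `organ:Vx` for a
contiguous x-window in 5% steps (drymouth: 5 organs x V25..V60 = 40
features; swallow V30–V65, mucus V25–V65, voice V45–V65). The shipped
windows are the defaults; `screen_vx_range` re-derives a window by
maximizing, over contiguous sub-windows, the mean per-feature sum of
mutual information between the median-dichotomized feature and the late
severe endpoints (the mean, not the sum, over window features — otherwise
the widest window trivially wins).

## Clustering and the high-dose group

Features are standardized (mean 0, sd 1; constant columns get unit scale)
and fit with a 3-component variational Bayesian Gaussian mixture:
full covariances with 1e-4 diagonal regularization (within-organ Vx
features are strongly correlated), Dirichlet-process weight prior with
concentration 1/k (starves superfluous components rather than force-
filling them — with k=3 on 2-group data one weight collapses, asserted in
tests), 5 initializations keeping the best lower bound, seed mandatory.
Patients are assigned to the component of maximum posterior
responsibility; ties resolve to the lower component id.

The high-dose (HD) component is identified in raw Gy, not z-space: per
patient the mean doses of the symptom's organs are summed; per component
that sum is *averaged* over members; HD is the argmax. Averaging (rather
than summing member totals) makes HD identity independent of cluster
size. A report-only check verifies HD also has the highest incidence of
the severe endpoint.

## Rule mining (simplified high-dose group)

Candidate thresholds for a feature are midpoints between consecutive
distinct observed values, thinned to at most 64 at evenly spaced
quantiles. Splits `feature > t` are scored by plug-in empirical mutual
information (bits, 0·log 0 := 0) with HD membership. The search is a beam
over conjunctions: depth 1 keeps the top 25 splits by MI; at depth d each
beam conjunction is extended by one split whose candidate thresholds are
recomputed on the sub-cohort already satisfying it, the MI of the full
conjunction is evaluated on the whole cohort, and the global top 25
conjunctions survive. Search stops at depth 2 (two-rule sets are the
intended output granularity) or when no extension strictly increases MI,
so the returned conjunction's MI never falls below its depth-1 prefix.
Ties break toward higher recall, then fewer rules, then lexicographic
feature names and thresholds — fully deterministic. Rule direction is
fixed to ">" (the target is the high-dose group). Patients exceeding all
thresholds form the SHD group; precision and recall are reported against
HD. Thresholds are reported at full precision with a rounded display
form. Because candidates are midpoint/quantile constructions, planted
thresholds are exactly recoverable only when feature values are
quantized (as 1-Gy-grid DVH features are); the beam equals exhaustive
search over the same candidate space (asserted against an independent
brute-force oracle).

## Outcomes, eligibility and imputation

Ratings are 0–10 integers per patient, symptom and timepoint (baseline,
7 weekly on-treatment ratings, 6-week and 6-month follow-ups). Endpoints
per symptom: `rating(6 mo) > 4` and `rating(6 mo) − baseline > 4`
(strict inequalities; thresholds 0/2/4 give any/moderate/severe tiers).
Eligibility requires a non-missing 6-month rating and at least 70% of all
items answered; the completeness denominator is the whole observation
window (a per-questionnaire denominator was the alternative; the
across-window reading was adopted and is logged per exclusion).
On-treatment ratings are used only as imputer inputs, never as endpoints.

Missing baselines are filled by a denoising autoencoder: inputs are all
ratings at all timepoints scaled to [0, 1] with missing entries as 0; two
fully connected ReLU layers (default 32, 16 — small relative to the
~280-dimensional input to avoid overfitting), Adam at learning rate 1e-3,
MSE loss, up to 2000 epochs with early stopping (patience 50 on a held-out
split). Training rows are patients with an observed baseline and >= 70%
completeness, each presented 10 times under Bernoulli zeroing corruption.
The corruption level of each presentation is drawn uniformly up to 0.5
rather than fixed at 0.5: with a fixed level every training input is
half-zeroed while inference inputs are nearly complete, and the network
compensates with a global up-scaling that overshoots at inference;
variable corruption keeps inference-time inputs in the training
distribution. Batch normalization is not applied; the [0, 1] input
scaling plays that conditioning role. Predictions are clipped to [0, 10],
rounded to integers, and written only into missing baseline cells
(observed values are never overwritten, asserted bitwise). With fewer
than 30 trainable patients the imputer falls back to per-symptom median
imputation with a warning. Everything is deterministic given the seed.

## Association testing

The baseline logistic model uses the clinical confounder indicators:
T-stage > 2, N-stage > 1, HPV/p16 positive, base-of-tongue subsite,
tonsil subsite, age >= 65, ECOG = 1, ECOG = 2 (unknown ECOG and unknown
HPV are reference level), and the parotid dose limit (mean > 20 Gy to
both parotids or > 25 Gy to one; identical by construction to the
published-limit flag). The extended model adds cluster indicators: for
the 3-level stratification, one indicator per non-reference cluster with
the lowest-dose cluster as reference; for HD/SHD a single indicator.

The LRT statistic is 2(lnL_ext − lnL_base) on chi-square with df = number
of added parameters; the odds ratio is the exponentiated coefficient of a
single added column. AIC = 2k − 2lnL and BIC = k·ln(n) − 2lnL with k
counting the intercept; deltas are extended minus base (BIC reduction
of >= 6 is flagged as the conventional "strong evidence"). Conventions
for degenerate designs: a column exactly collinear with earlier columns
is dropped (it adds no parameter — a duplicated predictor reproduces the
original fit); an all-zero column is kept as a *flat* parameter
(coefficient 0, no likelihood contribution, counted in k), so adding pure
noise costs exactly +2 AIC with statistic 0. Separation or
non-convergence falls back to a lightly ridged Newton fit (L2 1e-6,
intercept unpenalized) reporting the unpenalized log-likelihood. A linear
variant models the raw 0–10 rating by OLS with the F-test through the
same interface. Raw p-values are reported with no multiple-testing
adjustment (a reporting convention, documented rather than corrected).

Chi-square tests of covariates against cluster/SHD membership are Pearson
(no continuity correction) with a low-expected-count annotation; Fisher
2x2 odds ratios are ad/bc with a 0.5 Haldane correction on zero cells and
two-sided exact p.

## Cross-validated evaluation

Stratified 5-fold CV, folds re-drawn with a sub-seed (up to 10 times) if
any fold lacks positives. Clustering and rule mining are refit inside
every training fold — the leakage-safe reading; a `frozen_clusters` flag
reproduces the weaker fit-once variant for comparison. Risk models:

* All — clusters ranked by training-fold count of positive outcomes
  (ties by higher cluster mean dose), test risks 1 / 0.5 / 0 by rank;
* HD — high-dose membership (1/0);
* SHD — rule-set membership (1/0);
* NTCP — logistic regression on the clinical confounders plus the mean
  doses of the symptom's NTCP organ list, recalibrated per training fold.

AUC-ROC is the tie-aware Mann-Whitney form; MCC uses the zero-margin → 0
convention and equals the Pearson correlation of the binary vectors.
Multi-level risks are binarized at risk >= 1 (HD-vs-rest) for MCC; NTCP
probabilities at 0.5. Metrics are pooled across folds (per-fold values
retained for dispersion). The 3-level AUC uses risk scores {1, 0.5, 0}
including the low-risk level.

## Synthetic cohorts

The generator emulates the structure of an oropharyngeal radiotherapy
cohort at the study scale (default 349 patients): three latent dose
groups with weights (0.35, 0.35, 0.30) and per-organ mean-dose targets
built from group bases 20 / 45 / 70 Gy times an organ factor (salivary
glands near 1, lips ~0.4, cord ~0.45), plus a shared latent (loading 0.5)
and independent noise at sd 3 Gy; paired organs get a per-patient random
primary side and an asymmetry gap ~|N(8, 2.7)| Gy so lateralization is
non-trivial and ipsi/contra means are not collinear. DVHs are logistic
tails v(d) = 1/(1+exp(s(d−d50))) normalized to v(0)=1 on a 1-Gy grid,
with d50 solved by (vectorized) bisection so the curve mean hits its
target within 0.5 Gy, and per-curve jitter on the falloff steepness
(shape only, not the mean). Covariates are drawn with group enrichment
(more T4/N3, base-of-tongue primaries, VMAT/IMPT and fewer prior
surgeries in the high group, in the direction and rough magnitude of a
real cohort's demographics). The 6-month rating of the analysis symptom
is Binomial(10, p*) with p* inverted (dense monotone grid) so that
P(rating > 4) equals the configured logistic model on dose features and
covariates (default: contralateral submandibular and ipsilateral parotid
mean doses plus T-stage); all other ratings follow a low-rank latent
structure (patient frailty + symptom offset + timepoint trajectory +
dose loading) that makes baseline imputation learnable. Baselines are
missing completely at random for 17% of patients; other cells at 3%.

What the generator does **not** emulate: real 3-D anatomy and the strong
spatial correlation structure of adjacent organs; MDASI psychometrics
(the binomial rating model is an emulation, not a claim about item
response behavior); informative missingness; measurement error in DVH
extraction. Passing tests therefore show the pipeline recovers structure
of this planted kind — they are not evidence about effect sizes in real
cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script size simulations to the method, not the
cohort maximum: 50-seed loops use n = 300–500 patients, the CV
permutation null uses one 150-patient cohort with 50 outcome
permutations, the dose-signal check uses n = 600, and the imputer
benchmark masks 20% of baselines on a 250-patient table over 20 seeds.
Bisection solves means to < 1e-6 Gy (asserted tolerance 0.5 Gy includes
discretization); interpolation tolerances in invariants are 1e-9; MI
ties break by the deterministic key above; chi-square LRT p-values with
df = 0 are defined as 1.

## Known limitations

* The BGMM is a generic density model; with heavily overlapping dose
  groups the ARI degrades gracefully but HD identity can flip between
  near-tied components.
* Rule mining searches exceedance conjunctions only (no OR branches, no
  "<" rules); a low-dose-protective pattern would not be expressible.
* The NTCP comparison uses mean doses only, by design; gEUD/LKB
  summaries are out of scope.
* The ridge fallback for separated logistic fits reports finite but
  prior-shrunk coefficients; odds ratios from such fits should be read
  qualitatively.
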