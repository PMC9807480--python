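# Methods

This note documents the models, the parameter choices and the numerical
conventions behind `mbrisk`, and what the synthetic study conditions do and
do not establish.

## Copy-number calling

Input is a per-sample binned log2-ratio profile (conumee-style methylation
array output, or IGV SEG segments converted on read). Calls are made
against a per-sample **baseline**, the length-weighted median log2 over
autosomal bins. The weighted median tolerates up to half of the genome
being aberrant and shifts one-for-one with any uniform offset of the
profile, so all calls are invariant to global shifts. Sex chromosomes are
excluded from the baseline because patient sex is not modelled. A
trimmed-mean estimator is available as an option.

Thresholds (all closed, `>=` comparisons): arm-level gain/loss at 0.2 log2
units from baseline over at least 80% of the arm; amplification at 0.4
over the locus. Two operational decisions replace visual inspection:

* the 80% coverage rule is evaluated against the **profiled** arm length
  (bins clipped to arm boundaries), not the full genomic arm length, since
  array bins never tile an arm completely;
* amplification uses the length-weighted **median** over the locus rather
  than a single-bin maximum, for robustness to bin noise; "clearly distinct
  from baseline" is operationalised as the same 0.4 margin.

Arms without any overlapping bin yield an explicit `missing` status, never
a silent `neutral`; WCA flags that depend on a missing arm are `None`.
Acrocentric p arms (13/14/15/21/22) are excluded from calling — arrays have
no probes there. The genome model ships as an hg19 arm table derived from
the UCSC cytoband centromere boundaries, with MYC (8q24) and MYCN (2p24)
gene intervals; any build can be supplied as a BED of arms. Coordinates
are 0-based half-open throughout; SEG input (1-based inclusive) is
converted on read.

## Risk strata

The clinical rule and the clinico-molecular refinement are pure functions
of the covariates (see README for the tables). Numerical conventions:

* "older than 4 years" is implemented as `age >= 4.0` (closed), matching
  the age categories used in cohort tables; the cutoff is configurable;
* desmoplastic histology counts as non-anaplastic (SR-compatible); only
  LC/A triggers the histology criterion;
* samples failing the classifier-score gate (methylation-class-family
  score ≥ 0.9, group ≥ 0.8, subgroup ≥ 0.8, all closed) are **retained**
  with an `unclassifiable` sentinel — in practice roughly a quarter of
  samples fail methylation classification and still need a documented
  disposition;
* missing covariates raise an explicit missing-data outcome; there is no
  imputation;
* every assignment carries an ordered audit trail of the rules that fired.

A clinical-HR patient with subgroup VII or WCA-FR is *not* demoted: the
low-risk modifiers only act inside the clinical-SR stratum, and the
very-high-risk subgroups only inside clinical HR. This keeps the stratum
flow a refinement of the clinical partition.

## Survival machinery

Times are years since first surgery. PFS counts progression, relapse or
death from any cause; OS counts death; both censor at last follow-up.

*Kaplan–Meier* is the product-limit estimator with Greenwood variance
(reported as the standard error of the estimate, displayed as "±" on
survival rates); it supports delayed entry for the counting-process
cross-checks. *Log-rank* delegates to lifelines. *Pearson χ²* (no
continuity correction by default) and *Cohen's κ* are provided for cohort
composition and classifier-agreement tables.

*Cox regression* runs on counting-process rows `(start, stop]` so that CSI
enters as a 0/1 covariate switching on at its start time; a patient
irradiated at `t0` before exit `T` splits into `(0, t0]` unexposed and
`(t0, T]` exposed rows. RT at time 0 (or below a configurable epsilon)
yields a single exposed row; RT after exit is never counted. The solver is
a Newton iteration on the **Efron** partial likelihood, written directly on
suffix sums over rows sorted by start/stop — one fit on ~2600 rows takes a
few milliseconds, which is what makes bootstrap cross-validation with
hundreds of refits practical on one CPU. Covariates are standardised
internally for conditioning; convergence at max Newton step < 1e-9 or 50
iterations, with a trust-region cap and step halving. Exact collinearity
raises a rank error; a flat likelihood along a non-vanishing direction
(monotone likelihood, e.g. a stratum with zero events in a bootstrap
resample) is detected, warned about, and returned as a flagged
non-converged fit whose predictions remain usable. Wald 95% CIs on the log
scale; AIC = 2k − 2·loglik; the global p is a likelihood-ratio test.
Concordance generalises Harrell's C to counting-process rows (each event
compared with the subjects at risk at that time; predictor ties count ½)
and is computed by a Fenwick-tree sweep in O(n log n). The baseline
cumulative hazard uses Efron-consistent increments at the fitted
coefficients.

## Model evaluation

*Incident/dynamic AUC*: at each event time, the probability that the
failing subject's linear predictor exceeds that of a random at-risk
survivor (ties ½); the integrated AUC is the event-count-weighted mean up
to the horizon. This follows the risk-set ROC semantics; because "AUC for
five-year PFS" is ambiguous between AUC(5) and the integral, both are
reported and the integrated value is primary (it is also the model-ranking
criterion).

*Prediction error*: Graf's IPCW Brier estimator with the censoring
distribution estimated by a marginal reverse Kaplan–Meier; subjects with an
event before t contribute `S(t)²/G(T−)`, subjects still at risk
`(1−S(t))²/G(t)`, subjects censored before t contribute nothing. The
evaluation grid is every event time up to the horizon plus 0 and the
horizon; the integrated Brier score is the trapezoid time-average.
Predicted survival for a patient integrates the baseline hazard piecewise
over the known pre-/post-RT covariate path.

*Bootstrap cross-validation* resamples patients with replacement, refits
everything (including the counting-process construction) on the resample,
and evaluates IBS and horizon-truncated concordance on the out-of-bag
patients; the reported value is the mean over replicates. Replicates whose
resample has no events or whose fit degenerates are skipped and counted
(warning above 5%). The concordance "at 5 years" truncates comparable
pairs at the horizon; the untruncated version is also computed. *External
validation* freezes the discovery fit and recomputes both metrics on the
validation cohort; unseen categorical levels raise an error listing the
known ones. All stochastic steps derive from one seed and are
bit-reproducible.

## Synthetic cohort generator

The generator produces the covariate and outcome structure the analysis
assumes, with defaults chosen once to match a large published Group 3/4
cohort: subgroup frequencies (I…VIII = 2.4/11.6/13.6/9.9/8.8/11.2/14.3/
28.2%), metastasis rates per subgroup (72.5% in III, 80.8% in V, 48.3% in
IV, 66% elsewhere, marginal ≈ 66%), age < 4 in 19.7%, LC/A in 9.5%,
MYC amplification concentrated in subgroups II/III (marginal ≈ 8%), MYCN in
V/VI (≈ 7%), per-marker WCA rates tuned to a ≈ 21% WCA-FR marginal, and an
i17q rate of 63%. Subgroups II/III/IV map to Group 3, VIII is Group 3 with
probability 0.04, the rest Group 4; the mapping is configurable.

Survival is exponential per true CM stratum with rate
`λ = −ln(S₅)/5` calibrated to the stratum's 5-year PFS target (defaults
0.94/0.65/0.62/0.29; the SR/HR pair is deliberately close, reflecting
their near-identical published outcomes). Death is coupled to progression:
`T_death = T_prog + Exp(λ_post)`, with `λ_post` solved from the
hypoexponential closed form so the 5-year OS target is met; when the OS
target does not exceed the PFS target (the LR stratum), death coincides
with progression. Censoring is independent: with probability
`censor_rate` (0.25) uniform on (0, 12] years, otherwise administrative at
12 years. Patients ≥ 4 years receive primary-CSI-type therapy with RT
starting 0.25 years after surgery — this offset is what creates genuine
time-dependence for the Cox machinery; infants receive RT only as salvage
at progression (50% of progressing infants), which affects OS modelling
but, correctly, not PFS. Classifier scores are drawn above the eligibility
thresholds by default.

CNV ground truth per patient: the three WCA markers drawn per subgroup,
i17q, occasional extra single-arm events, and MYC/MYCN amplification
flags. Rendering tiles each non-acrocentric arm with `bin_size_bp` (1 Mb)
bins, shifts bins inside an aberration by ±0.35 (amplified loci by +1.0),
and adds Gaussian noise (sd 0.1). Per-sample RNG streams derive from
(seed, patient index), so profiles are reproducible regardless of
rendering order.

**What the generator does not emulate:** probe-level methylation data,
segmentation artefacts, focal CNVs beyond the two named loci, subclonality
or ploidy shifts, informative censoring, accrual patterns, or
relapse–salvage dynamics. Tests passing on this generator establish that
the *pipeline machinery* is correct and that the stratification separates
survival when the planted structure is present — they say nothing about
biological effect sizes in real cohorts, whose published headline metrics
are not reproducible without the patient-level data.

## Problem sizes in the test suite

The suite checks calibration at n = 10⁴, caller recovery on 200 rendered
genomes (exact at noise sd ≤ 0.05; ≥ 99% per-call accuracy at sd 0.1),
Cox parameter recovery (ln 2 ± 0.1, ~95% CI coverage) over 200 replicates
at n = 2000, and the end-to-end discrimination claim — the
clinico-molecular model beating the clinical backbone on out-of-bag IBS
and concordance — over 50 cohorts of n = 2000 with B = 50 bootstrap
replicates each, rendering chromosomes 1–8, 11 and 17 (the chromosomes the
caller needs plus neutral ballast that keeps the median baseline honest).

## Known limitations

* The Cox baseline hazard uses Efron-consistent increments but predictions
  assume the covariate path known in advance; internal time-dependent
  covariates other than pre-scheduled RT are out of scope.
* The censoring model for IPCW weights is marginal, not
  covariate-conditional.
* No competing-risks estimators, frailty, or stratified baselines.
* Whether the 80% arm-coverage rule should use full rather than profiled
  arm length is not decidable from the published description; the choice
  here is configurable in spirit (the denominators are exposed in
  `ArmCall`).
* No multiple-testing adjustment anywhere, by design (exploratory
  analyses).
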