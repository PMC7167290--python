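# Methods

This note documents the models, conventions and design choices behind
`ublsig`, in the spirit of a package's statistical-methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic array studies

The simulator emulates the reference experimental design: two AML cell
lines (HL-60, U937), each in parental, Ara-C-resistant (ARA-R) and
DNR-resistant (DNR-R) condition, probed on duplicate-spot two-channel
arrays in three independent experiments, with two NEM-treated control
arrays per experiment (NEM alkylates the E1/E2 enzymes, so control
arrays define the no-conjugation background). That is 3 x (2 x 3 + 2) =
24 arrays. The default panel is 1,000 proteins — a desk-speed stand-in
for the >9,000-protein commercial arrays; everything scales up by
config.

Signal model, in log2 units per (protein, array, channel):

```
log2 I = b_p + m_pc + d_pc(condition) + g_e + eps_spot
```

* `b_p` — per-protein baseline, Normal(9, 1). This is the nonspecific
  level common to all arrays, including NEM controls.
* `m_pc` — modification effect (default 2.0 log2) for planted modified
  (protein, channel) pairs, present only on conjugation-permissive
  arrays. Default planted fractions: 10% of the panel for ubiquitin, 5%
  for SUMO-1 (real arrays showed ~11% ubiquitylated and far fewer
  SUMOylated; the SUMO fraction is kept high enough for stable recovery
  statistics on a 1,000-protein panel).
* `d_pc` — differential effect (default 1.0 log2, sign split 50/50
  up/down) on 10% of the modified set, applied in the resistant
  conditions in scope (`global`, `per-line` or `per-drug`).
* `g_e` — per-experiment batch offset, Normal(0, 0.5), **centered to
  mean zero across the experiments of a study**. Batch effects are
  relative; without centering, the mean offset (SD 0.5/sqrt(3) log2)
  would rescale the whole study against the absolute 800 a.u. intensity
  floor and make recovery rates a per-seed lottery rather than a
  property of the method.
* `eps_spot` — per-spot noise, Normal(0, log2(1 + spot_cv)),
  spot_cv = 0.15 by default.

Raw intensities are `2^(log2 I) + B` with an additive per-spot scanner
background `B ~ Normal(60, 10)` clipped at 0; the GPR `B<λ> Median`
column carries `B` itself, so background correction recovers the signal
exactly up to integer rounding. Channels follow the conventional dye
wavelengths: 635 nm (red, Alexa-647 anti-mouse → anti-SUMO-1) and
532 nm (green, Alexa-546 anti-rabbit → anti-Flag/ubiquitin).

Neither spot-level noise nor background magnitudes are published for
the real scans; these defaults are free parameters chosen to look like
ordinary array data, not calibrated values. The simulator also models
no spatial artefacts (gradients, scratches, print-tip effects), no
enzyme kinetics and no saturation, so passing recovery tests says the
*statistical procedure* works under its own assumptions — not that the
wet-lab assay has these operating characteristics.

All randomness flows from one `rng_seed` through named
`numpy.random.SeedSequence` spawn keys (truth assignment, batch offsets,
one stream per array, bead events), so output is bitwise reproducible
and extending a design does not perturb earlier draws.

## Preprocessing

Order: background correction → duplicate averaging → within-experiment
quantile normalization → cross-experiment batch adjustment.

* Background: `max(F − B, floor)` with floor 1.0 a.u. (positive so log2
  is defined).
* Duplicates: arithmetic mean; one surviving spot passes through; both
  missing stays missing; more than two spots per protein is a grid
  violation and an error.
* Quantile normalization equalizes each array group's distributions to
  the mean-of-sorted reference; ties receive the mean of the reference
  values at their rank positions; missing values are excluded from the
  reference and stay missing (columns with fewer valid entries use a
  linearly resampled reference). The reference includes the NEM-control
  arrays of the experiment, as the array-processing package the original
  workflow delegates to does. This is deliberate but consequential: NEM
  arrays lack the modification boost, so the pooled reference deflates
  top-rank permissive values by roughly 20% and inflates top-rank NEM
  values — a protein that is both strongly modified and top-of-panel
  baseline can become undetectable. On default simulations this costs a
  percent or two of sensitivity and is visible in the recovery numbers.
* Batch adjustment defaults to log2 median-centering per experiment
  (monotone, hence rank-preserving, and idempotent); an empirical-Bayes
  location/scale variant (`eb_location_scale`) is available when batches
  differ in spread. The original workflow calls an unnamed internal
  method, so equivalence cannot be asserted; median-centering was chosen
  as the simplest monotone robust option.

## Statistical tests

`ublsig.stats` implements the tests directly so that exact small-sample
branches are available and auditable:

* Mann–Whitney U: exact null distribution by the standard two-index
  counting recurrence when n + m ≤ 16 and the pooled data are tie-free;
  otherwise normal approximation with tie correction and continuity
  correction. Two-sided p = 2·min(CDF, SF) including the point mass,
  capped at 1.
* Wilcoxon signed-rank: zeros dropped before ranking (Wilcoxon's
  convention; the source workflow is silent), exact distribution by
  polynomial convolution for n ≤ 20 without ties, otherwise the
  tie-corrected normal approximation.
* t tests: Welch–Satterthwaite closed form; paired reduces to one-sample
  on differences. Zero variance with equal locations ⇒ p = 1; with
  different locations ⇒ p = 0.
* Everything is two-sided by default (sidedness is never stated in the
  source analysis); exact-branch thresholds (16, 20) keep enumeration
  sub-millisecond and are module constants.

The null-calibration experiment uses n = (10, 10) for Welch and n = 30
for the rank tests — inside the normal-approximation regime, because the
exact branches are discrete and intrinsically conservative at tiny n, so
a 5% nominal level is not attainable there by construction.

## Signature calling

Stage 1 (modification): per (protein, modifier), permissive-array
intensities vs NEM-control intensities with both Welch and Mann–Whitney;
called iff both p < α (0.05), permissive mean > control mean, and
permissive mean > 800 a.u. (the published arbitrary floor). The two-test
requirement guards against the heteroscedasticity between permissive and
control conditions. Control arrays enter the tests as individual arrays
(n = 6 by default) rather than pre-averaged — averaging would leave too
few observations for a two-sample test; the "averaged" control signal of
the original description is interpreted as the reported control mean.

Stage 2 (differential): ratios pair each resistant array with the
parental array of the same cell line *and* experiment batch (pairing is
implied but unstated in the source; within-batch pairing makes the
signed-rank test well-defined and cancels batch terms exactly). Tests
run on log2 ratios against 0 — the symmetric treatment of up/down —
while thresholds (1.25/0.8 pooled, 1.5/0.66 separated) apply on the
ratio scale as printed; whether the original tested raw ratios against 1
is unknowable from the text. The ratio summary is the geometric mean,
consistent with log-scale testing. No multiple-testing correction by
default, matching the raw p < 0.05 usage; Benjamini–Hochberg is a config
flag. The signature is the union of pooled and per-line x drug calls,
with proteins modified by both UbLs counted once in distinct-protein
totals.

## The score

Variables are (protein, modifier) pairs — a dual-modified protein
contributes two variables (hence 7 SUMO + 9 Ub + 2 x 7 dual = 30).

LDA: pooled within-class covariance, coefficients Σ⁻¹(μ_R − μ_S),
posterior via the logistic of the linear score (exact for Gaussian
class-conditionals with shared covariance). Shrinkage toward the
diagonal uses the Schäfer–Strimmer analytic intensity by default
("auto"), since the variable count (≤ 30) can approach the sample count;
exactly-zero within-class variances are floored at 1e-9 of the mean
variance so perfectly separated data remain classifiable, while
rank-deficient covariances without shrinkage raise an error. Classes of
size 1 in a CV training fold contribute zero scatter but keep their
mean, which keeps leave-one-out on tiny cohorts well-defined.

GA: binary chromosomes over variables, fitness = cross-validated
accuracy − λ·|S|/n with λ = 0.05 (the original custom fitness is
unpublished; a parsimony-penalized CV accuracy matches its stated goal
of a parsimonious predictive model). Tournament selection (size 3),
uniform crossover (p = 0.8), per-bit mutation, 5% elitism, population
50, 100 generations; 40 runs with the mutation rate jittered uniformly
in [0.05, 0.2] emulate "repeated runs under different parameter
settings". Two robustness features: a cataclysmic restart (non-elite
population reinitialized after 15 stagnant generations) and a final
steepest single-bit hill climb on each run's best chromosome — subset
fitness landscapes contain deceptive attractors several bits from the
optimum, and both are standard remedies. All-zero chromosomes get
fitness −∞. Fitness values are memoized per subset within a call, which
changes nothing statistically (fitness is deterministic given the data
and CV scheme).

Selection frequency = fraction of runs whose best subset contains the
variable. The frequency ranking (ties broken by marginal single-variable
CV accuracy, then variable id) is cut into nested subsets at sizes
(4, 7, 11, 17, all-selected); only |subset 2| = 7 is anchored to the
reference analysis, the other cut points are uncalibrated defaults.
Subset evaluation reports cross-validated accuracy with ties going to
the smaller subset. Classification follows the 50% posterior rule, with
exactly 0.5 mapped to "indeterminate" (the rule is defined only by
strict inequalities).

Cross-validation: stratified LOOCV by default (suited to the 18-sample
cell-line design of the reference analysis); a seeded stratified
train/test split scheme `("split", train_frac, n_rep)` is used in the
larger validation experiments where LOOCV would dominate runtime.
Patient-type samples are scored with the cohort-trained model after the
same preprocessing — how the original normalized patient arrays against
cell-line training data is unstated, and this uniform treatment is the
assumption made here.

## Bead assay

Events carry two classification channels (bead color code → biomarker)
and two reporter channels. Gating is nearest-centroid (deterministic
when centroids are supplied; seeded k-means estimates them otherwise),
with an optional distance gate marking outliers unassigned. MFI is the
event median per (sample, region, reporter); regions under 30 events
(common cytometry floor) are flagged unusable. NEM subtraction floors at
1 a.u. and flags ratios whose parental denominator sits at the floor.
Group comparisons delegate to the t tests (Welch unpaired for
responder/refractory cohorts, paired for matched designs). The
"high modification" patient flag — value > responder mean + 2 SD on at
least one biomarker — is an explicit stand-in: the original reports the
flagged counts but never defines the threshold numerically; k_sd is
config. By construction this rule flags ~2.5% of the reference group per
biomarker on Gaussian noise.

## Validation experiment sizes

The experiments in `ublsig.validation` (used by the heavier tests and by
`scripts/acceptance.py`) run at sizes chosen to estimate their rates
stably on a single core in minutes: 10–20 simulated studies for
planted-signal recovery; 10,000 replicates for null calibration; a
12-variable instance (2^12 − 1 subsets exhaustively enumerated) for the
GA-vs-brute-force check; cohorts of 200 training / 80 held-out samples
with 7 informative variables among 14 (total class separation 3.29, i.e.
Bayes accuracy ≈ 0.95) for end-to-end score recovery; and a 39-patient
cohort with 6 planted high-modification refractory patients for the bead
assay. Larger sizes change runtimes, not conclusions.

## Known limitations

* The real study's protein identities (988/83 modified, the 122-protein
  signature, the 23-protein panel) derive from undeposited raw scans and
  cannot be reproduced; the package reproduces the *procedure* and its
  printed bookkeeping arithmetic.
* The quantile-normalization top-rank distortion described above is
  inherited from the normalize-everything-together convention, not
  removed.
* The GA fitness and the patient-flag threshold are documented
  stand-ins for unpublished components.
* FCS ingestion and image quantification are out of scope; events and
  scans enter as text tables.
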