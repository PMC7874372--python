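# Methods

This note documents the models, conventions and design choices behind
`dmn-subsys`, in the spirit of a statistical software vignette: what is
computed, under which assumptions, and what the synthetic validation
does and does not establish.

## The scientific setting

The default mode network (DMN) is modelled as 11 spherical ROIs (radius
8 mm) at fixed MNI coordinates, grouped a priori into three subsystems:
the medial temporal lobe (MTL) subsystem (vMPFC, pIPL, Rsp, PHC, HF),
the dorsal medial prefrontal (dMPFC) subsystem (dMPFC, TPJ, LTC, TempP)
and the PCC–aMPFC core (aMPFC, PCC).  The scientific question is whether
the modular organisation of this network — how separated the subsystems
are — differs between autistic (ASC) and comparison (CMP) individuals
and how that difference changes with age across childhood and
adolescence.  The headline quantity is the age × group interaction on
between-subsystem connection strength and on the modularity index Q.

## Connectivity estimation

Per subject, ROI time series (extracted from a 4D volume by unweighted
averaging over voxels whose centres fall within each sphere, or loaded
directly as tables) are processed in a fixed order:

1. **linear detrend** per column;
2. **nuisance regression**: OLS residuals against 32 regressors — six
   rigid-body motion parameters, CSF and white-matter mean signals,
   their backward-difference temporal derivatives, squares and squared
   derivatives (fMRIPrep column dialect: `trans_*`, `rot_*`, `csf`,
   `white_matter`) — optionally augmented with CompCor components (the
   first five principal time courses of the 5 % most variable voxels);
3. **band-pass filter** 0.008–0.1 Hz, implemented as a 4th-order
   Butterworth applied forward–backward (zero phase).

The order detrend → regress → filter is a deliberate choice: filtering
last guarantees that the regression cannot reintroduce energy at
removed frequencies.  Filter family and order are conventions, recorded
in output metadata; only the band itself is scientifically meaningful.

Connectivity is the Pearson correlation of the residual series for all
55 ROI pairs, Fisher-transformed (z = atanh r).  r is clipped to
±(1 − 1e-7) so degenerate inputs stay finite; the diagonal is defined
as 0.

## Network statistics

For a weighted undirected matrix W and the fixed partition c, the
modularity index is

Q = (1/2m) Σᵢⱼ [wᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ),

with node strength kᵢ = Σⱼ wᵢⱼ and 2m = Σᵢⱼ wᵢⱼ.  Fisher-z matrices can
contain negative weights and the classic formula is not defined for
them, so two conventions are implemented and the choice is recorded in
metadata:

* `positive_only` — negative weights zeroed, classic weighted Q;
* `signed_asymmetric` (default) — positive and negative parts scored
  separately, Q = Q⁺ − m⁻/(m⁺+m⁻) · Q⁻, penalising negative
  within-module weight without letting it dominate.

Module strengths are sums over **unordered** pairs (each edge counted
once): 10 MTL + 6 dMPFC + 1 core within-pairs, 38 between-pairs, 55
total.  Within + between always recompose the upper-triangle sum; the
test suite verifies this identity and checks Q against a brute-force
double-loop oracle to 1e-12.

## Quality control

* **FD** (framewise displacement): Σ|Δtrans| + 50 mm · Σ|Δrot|, first
  frame 0.  **DVARS**: RMS over voxels/ROIs of the backward temporal
  difference, standardized to percent of the grand mean signal.
* **Exclusions**, applied to subject means in this order (first match
  is the recorded reason): mean FD > 0.5 mm, mean DVARS > 5 %, FIQ < 83,
  FIQ > 130.  Thresholds are strict inequalities; applying the rules
  twice is a no-op.
* **Movement outliers**: subjects above the pooled 95th percentile of
  mean FD or mean DVARS, with the linear-interpolation percentile
  definition.  A consequence worth knowing: appending one extreme
  subject shifts the threshold by up to one order statistic and can
  unflag the single boundary subject.
* **Quality factors**: the 30 image-quality metrics are z-scored and
  reduced by unrotated PCA; the first four component scores (sign-fixed
  so each component's largest-|loading| metric loads positively) serve
  as nuisance covariates downstream.
* **Site leakage**: a linear SVM (C = 1) predicts acquisition site from
  the subject × edge matrix on a seeded, stratified two-thirds/one-third
  split, reporting balanced accuracy.  Feature z-scoring *and* any
  residualization (on quality factors or site indicators) are fitted on
  the training split only.  Residualizing on the pooled sample before
  splitting is deliberately avoided: it makes test-fold class means
  anti-correlated with the training fit and drives accuracy
  systematically below chance, which misrepresents how much site signal
  remains.

## Inference: the bootstrap-permutation GLM

Each outcome is modelled by OLS on standardized variables: outcome and
continuous predictors z-scored, group coded −0.5 (CMP) / +0.5 (ASC),
interaction formed as the product of the coded columns after centring.
Coefficients are therefore standardized effect sizes; the group and
interaction coefficients are per unit of a ±0.5-coded regressor.  A
linear rescaling of age (years → months) leaves every reported
coefficient unchanged.

Significance is assessed by resampling with `n_boot` draws (default
1000; scaled-down studies in this repository use 200):

* **bootstrap**: subjects resampled with replacement; the reported β is
  the median of the resulting coefficient distribution and the reported
  interval its 5th/95th percentiles;
* **null**: resamples in which the outcome is scrambled against the
  predictors; p = (1 + #{|β_null| ≥ |β_median|}) / (1 + n_boot),
  two-sided, never exactly zero.

Where the scrambling happens matters.  The default scrambles the
outcome **within each bootstrap resample**.  Permuting the full sample
first and then resampling stacks two independent layers of coefficient
variance (permutation + bootstrap) into the null while the test
statistic carries only one, which makes the test strongly conservative
(measured type-I ≈ 0.01 at nominal 0.05).  Within-resample scrambling
matches the null variance to the statistic's and is empirically
calibrated (measured 0.04–0.07 across coefficients over 500 null
datasets); the conservative variant remains available as
`null_scheme="permute_before"`.

Multiple testing: Benjamini–Hochberg FDR across the 55 edges,
separately per coefficient family (age; group; age × group); Bonferroni
with m = 4 across the four summed-strength outcomes; the modularity
index forms its own single-member family and is reported uncorrected.
Site is never a regressor (it is confounded with age by design, in the
synthetic cohorts as in the motivating data); between-site differences
are absorbed through the image-quality factors instead.  Symptom-score
models use the DMN measure as predictor with FIQ, the four quality
factors, and age both linear and squared (centred before squaring) as
nuisance.  Median splits of age exist for visualisation only; ties go
to "younger".

## The synthetic cohort

`SimulationConfig` defaults describe the emulated study conditions:
two groups of 200, ages uniform on 6–18 years, T = 200 frames at
TR = 2 s, FIQ ~ N(107, 11²) clipped to the inclusion window [84, 130],
three acquisition sites assigned by contiguous age band (deliberately
confounding site with age), white measurement noise with SD 0.4 on a
unit-variance signal, motion spikes with per-frame probability 0.02.
Symptom z-scores are generated for the ASC group only, unassociated
with the network measures (null association is the default truth).

Each subject's 11×11 target correlation matrix is block-structured:
1 on the diagonal, 0.5 within subsystems, and between subsystems
0.25 + β_age·(age − 12) + 1[ASC]·β_int·(age − 12), clipped to ±0.95 and
repaired to positive definiteness by eigenvalue clipping (floor 1e-8,
logged) if an extreme configuration requires it.  Defaults
β_age = β_int = −0.008/year plant the studied pattern: between-subsystem
coupling falls with age, twice as fast in the ASC group; within-subsystem
coupling is age-constant.  Signals are multivariate-normal draws from
this matrix plus a BOLD baseline (50, which sets the DVARS scale to a
realistic 2–3 %), an additive per-site offset, and white noise whose
per-subject scale varies lognormally (σ = 0.15) so tSNR and DVARS differ
across subjects.  Motion parameters are random walks with lognormally
varying amplitude and optional spike steps; CSF/WM confounds are AR(1)
series.

**Effect-size calibration.**  The per-year slope β_int maps onto a
standardized GLM coefficient through the Fisher transform and the sum
over 38 between-subsystem edges.  `calibrate_interaction` inverts this
map: the observed correlation is attenuated by κ = 1/(1 + noise_sd²),
the sensitivity of between-module strength to a per-year slope is
38κ/(1 − (κc₀)²) · sd(age), and the outcome SD combines the analytic
effect-variance terms with a residual SD estimated by simulating ~80
mid-age subjects through the actual connectivity pipeline.  A planted
standardized β of −0.3 is recovered with median β̂ within ~0.05 of the
target at n = 400, T = 200.

**Site effects and image quality.**  The 30-metric IQM table is
generated from four latent quality factors (random loadings fixed by
the seed) plus white noise; site effects shift the latent factor means.
Two consequences are intended: the table is exactly rank 4 in the
noiseless limit even with site effects present, and regressing out the
four estimated factors removes site information robustly.  The leakage
validation experiment contaminates edge features through each subject's
estimated factor scores (site → quality → features mediation).  An
earlier design with independent rank-2 site offsets in metric space was
rejected because a 4-component solution captured the site dimensions
only for favourable seeds, and regression on noisy factor scores only
attenuated (errors-in-variables) rather than removed site-mean offsets.
On real data, site effects that are *not* mediated by measured quality
would be under-corrected by this scheme — exactly the residual leakage
the SVM check is there to quantify.

**What the synthetic validation does not show.**  The generator has no
hemodynamic response, no autocorrelated BOLD noise spectrum, no spatial
smoothness, no scanner-specific multiplicative effects, and
time-series site effects are additive mean shifts (which correlation
estimates ignore by construction).  Passing the planted-effect and
calibration checks therefore demonstrates correctness of the estimator
chain under the stated generative model, not robustness to the full
physics of multi-site fMRI.

## Problem sizes and numerical conventions

Validation studies are sized for a single CPU: 500 null datasets
(n = 100, n_boot = 200) for type-I calibration; 100 replicate cohorts
(n = 400, T = 200, n_boot = 200) for power and recovery; 300 subjects,
3 sites for the leakage ordering.  Other conventions: percentile and
CI computation use linear interpolation; Fisher clip 1e-7; PD floor
1e-8; rank-deficient designs fall back to pseudo-inverse with a logged
warning; all randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, and identical configuration reproduces
byte-identical output tables.

## Known limitations

* The signed-modularity convention for negative Fisher-z weights is a
  documented choice between two published variants, not a claim about
  any particular prior implementation.
* The DVARS exclusion uses the subject **mean** (a maximum-based rule is
  a one-line config change); which summary the motivating literature
  used is ambiguous.
* Voxel-level spatial smoothing is not implemented; 8 mm sphere
  averaging dominates a 6 mm kernel for ROI-level analyses, but
  voxel-wise results would differ.
* The pipeline is cross-sectional; no mixed-effects or site-stratified
  models are provided.
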