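# dmn-subsys

Analysis of default-mode-network (DMN) subsystem connectivity in
resting-state fMRI, built around the question of how the network's
modular organisation differs between autistic (ASC) and comparison
(CMP) individuals across childhood and adolescence.

The DMN is represented by 11 spherical ROIs (8 mm radius, fixed MNI
coordinates) in three a-priori subsystems — the medial temporal lobe
(MTL) subsystem (5 nodes), the dorsal medial prefrontal (dMPFC)
subsystem (4 nodes) and the PCC–aMPFC core (2 nodes).  The package
provides, as a library and a CLI:

* **synthetic cohorts** with planted effects: per-subject multivariate
  time series whose block-structured correlation matrix has
  between-subsystem coupling that declines with age and declines faster
  in one group, plus fMRIPrep-style confounds, paintable 4D test
  volumes, and a 30-metric image-quality table with a 4-factor
  structure (`dmn_subsys.synthetic_data`);
* **connectivity**: sphere-averaged ROI extraction, 32-regressor
  nuisance regression (+ CompCor), detrending, 0.008–0.1 Hz zero-phase
  band-pass, and Fisher-z correlation matrices
  (`dmn_subsys.connectivity`);
* **network statistics**: the weighted modularity index
  Q = (1/2m) Σᵢⱼ [wᵢⱼ − kᵢkⱼ/2m] δ(cᵢ,cⱼ) over the fixed partition,
  with two documented conventions for signed matrices, and
  within/between-subsystem summed connection strengths
  (`dmn_subsys.network_metrics`);
* **quality control**: framewise displacement and standardized DVARS,
  the exclusion rules (mean FD > 0.5 mm, mean DVARS > 5 %, FIQ outside
  [83, 130]), pooled-95th-percentile movement outliers, PCA reduction
  of image-quality metrics to four factors, and a linear-SVM check for
  acquisition-site leakage in connectivity features
  (`dmn_subsys.quality_control`);
* **inference**: a bootstrap-permutation GLM — standardized OLS
  coefficients (age, ±0.5-coded group, their interaction, nuisance
  covariates), the median of 1000 bootstrap resamples reported with its
  5–95 % interval, and p-values from a scrambled-association null —
  with BH-FDR across the 55 edges and Bonferroni across the four
  strength outcomes (`dmn_subsys.inference`);
* **pipeline**: `simulate → connectivity → metrics → qc → analyze →
  report` as one reproducible, YAML-configured run
  (`dmn_subsys.pipeline`, CLI `dmn-subsys`).

See `docs/methods.md` for the model details, conventions and known
limitations.

## Worked example

Simulate a cohort of 120 children and adolescents (60 per group, ages
6–18, T = 200 frames at TR = 2 s) with the default planted effect —
between-subsystem coupling declining ~0.008/year faster in the ASC
group — and test the module-level age × group interaction:

```python
from dmn_subsys import SimulationConfig, subject_connectivity, summarize_network
from dmn_subsys.rois import RoiSet
from dmn_subsys.synthetic_data import generate_phenotypes, generate_timeseries
from dmn_subsys.network_metrics import summaries_table
from dmn_subsys.inference import GlmSpec, module_level_analysis

roiset = RoiSet.default()
config = SimulationConfig(n_per_group=60, T=200, seed=7)

pheno = generate_phenotypes(config)
summaries = []
for _, row in pheno.iterrows():
    ts = generate_timeseries(row, roiset, config)          # T×11 signals + confounds
    cm = subject_connectivity(ts)                          # denoise → Fisher-z matrix
    summaries.append(summarize_network(ts.subject_id, cm.z,
                                       roiset.partition(), cm.labels))
summaries = summaries_table(summaries)

spec = GlmSpec(nuisance=("fiq",), n_boot=200, seed=0)
stats = module_level_analysis(summaries, pheno, None, spec)
cols = ["outcome", "coef", "beta_median", "ci_lo", "ci_hi", "p_raw", "p_corrected"]
print(stats[stats["coef"] == "age_x_group"][cols].round(3).to_string(index=False))
```

```
     outcome        coef  beta_median  ci_lo  ci_hi  p_raw  p_corrected
     between age_x_group       -0.514 -0.775 -0.320  0.010         0.04
  within_MTL age_x_group        0.217 -0.113  0.540  0.254         1.00
within_dMPFC age_x_group       -0.043 -0.353  0.336  0.806         1.00
 within_Core age_x_group       -0.168 -0.432  0.124  0.418         1.00
           Q age_x_group        0.567  0.360  0.740  0.010         0.01
```

Reading the output: the interaction is detected where it was planted —
between-subsystem strength falls faster with age in the ASC group
(standardized β = −0.51, Bonferroni-corrected p = 0.04 across the four
strength outcomes), and consequently modularity Q rises faster with age
in that group (β = +0.57, uncorrected p = 0.01, its own family).  The
within-subsystem strengths, where no effect was planted, stay null.
`beta_median` and the interval are the median and 5th/95th percentiles
of 200 bootstrap resamples; `p_raw` compares that median against
coefficients from resamples with scrambled outcome–predictor
association, so its smallest attainable value is 1/201 ≈ 0.005.

The same analysis as a shell pipeline:

```bash
dmn-subsys simulate --out run --seed 7 --n-per-group 60 --t 200
dmn-subsys connectivity --out run
dmn-subsys metrics --out run
dmn-subsys qc --out run
dmn-subsys analyze --out run --n-boot 200
dmn-subsys report --out run        # adjacency panels, effect matrices, scatter plots
```

or in one step from a YAML file: `dmn-subsys run --config run.yaml`.

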