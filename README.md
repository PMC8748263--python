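# csa-aging

Longitudinal aging curves of **global cortical spontaneous activity (CSA)**
from resting-state fMRI, as a tested, fully simulated analysis pipeline.

Cross-sectional fMRI studies confound age-related *differences* between
people with aging-related *changes* within people. Estimating true aging
curves needs repeated measures per subject and a model that separates
within-subject change from between-subject (cohort) variation. This package
implements that analysis end to end for three surface-based rsfMRI metrics —

* **ALFF** — amplitude of low-frequency fluctuations: the mean one-sided
  amplitude spectrum `(2/T)·|DFT|` over a band's frequency bins,
* **ReHo** — regional homogeneity: Kendall's coefficient of concordance *W*
  of a vertex's time series with its 4-step mesh neighborhood (~61 vertices
  on a regular 2 mm mesh), `W ∈ [0, 1]`,
* **VMHC** — homotopic connectivity: Fisher-z-transformed Pearson
  correlation between mirrored left/right surface vertices,

each computed in three slow frequency bands (slow-5: 0.02–0.03 Hz, slow-4:
0.03–0.08 Hz, slow-3: 0.08–0.22 Hz), summarized globally (mean and SD over
the group surface mask, averaged over a visit's two scans), and modeled as

```
y_ij = β0 + f(a_ij) + γ1·sex_i + γ2·cohort_i + γ3·edu_i + b_0i + ε_ij
```

where `f` is a penalized cubic B-spline smooth of age `a_ij` (5 knots,
second-order difference penalty), `b_0i ~ N(0, σ_b²)` a subject random
intercept, and the smoothing parameter and variance components are
estimated by REML. Each fit reports the smooth's effective degrees of
freedom (edf ≈ 1 means an essentially linear aging curve), an approximate
smooth p-value, covariate Wald tests, and a prediction curve with
pointwise 95% CI.

Real cohort data is access-controlled, so the package ships a first-class
**synthetic-data generator**: longitudinal cohorts (24 older adults, ages
58–77 at baseline, five annual visits, two 150-volume TR = 2 s scans per
visit) on a mirrored triangular surface mesh, with independently switchable
ground-truth aging effects on band amplitude (ALFF pathway), local coupling
(ReHo pathway) and homotopic coupling (VMHC pathway). Every injected effect
is recorded in a ledger, so the whole analysis is validated by parameter
recovery. Who this is for: rsfMRI methods researchers who want a tested
reference implementation of multi-band global CSA metrics and
penalized-spline aging-curve models, and a harness for power/calibration
studies of longitudinal designs.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic data
with the full injected aging pattern (+2 %/year band amplitude in all three
bands; homotopic- and local-coupling drift in slow-4 only):

```bash
python analysis/01_simulate_cohort.py     # 240 scans + ground-truth ledger
python analysis/02_compute_csa_metrics.py # global CSA table (2,160 rows)
python analysis/03_fit_aging_curves.py    # 18 GAMMs + reports + figures
python analysis/04_validate_recovery.py   # recovery scoreboard
```

`03_fit_aging_curves.py` prints the global-mean report (one model per
metric × band; rows are the smooth's p-value and edf and the covariate
p-values):

```
metric         ALFF                    ReHo                    VMHC
band         slow-3  slow-4  slow-5  slow-3  slow-4  slow-5  slow-3  slow-4  slow-5
s(age).p     0.0000  0.0000  0.0000  0.3796  0.0001  0.1843  0.9029  0.0000  0.3191
s(age).edf   1.2699  4.0778  1.0000  1.0000  1.0000  1.0000  1.0000  1.0000  1.1350
Cohort.p     0.2492  0.2532  0.2085  0.4469  0.0102  0.4652  0.9611  0.4220  0.3507
Education.p  0.4216  0.4275  0.4355  0.5687  0.6875  0.3612  0.1810  0.7537  0.3750
Sex.p        0.2961  0.2979  0.3148  0.2135  0.3378  0.8391  0.2604  0.6184  0.5374
```

Reading it: the aging smooth is significant for ALFF in all three bands and
for ReHo/VMHC in slow-4 only — exactly the injected truth. `s(age).edf ≈ 1`
marks near-linear aging curves; larger values (e.g. 4.08 for slow-4 ALFF
here) mark nonlinear ones. The scoreboard in `04_validate_recovery.py`
quantifies this over replicates:

```
[PASS] type-I error of s(age) under null: 0.040 (bounds [0.01, 0.1], n=200)
[PASS] power of s(age) under linear aging: 1.000 (bounds [0.9, 1.0], n=50)
[PASS] end-to-end aging-pattern recovery (ALFF all bands; ReHo/VMHC slow-4): 0.920 (bounds [0.8, 1.0], n=25)
```

Library use mirrors the drivers: `build_hex_mesh` / `generate_dataset` /
`preprocess_scan` / `compute_csa_table` / `fit_gamm` / `predict_curve`, or
one call to `csa_aging.run_pipeline(PipelineConfig(...))`.

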