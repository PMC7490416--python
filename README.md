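# hemopred

Can central (aortic) hemodynamics and cardiac contractility be estimated
from measurements any clinic can make? `hemopred` studies that question
in silico. It simulates a virtual population of cardiovascular subjects
with a reduced-order heart/arterial-tree model, "measures" each subject
noninvasively — brachial systolic and diastolic pressure (brSBP, brDBP),
heart rate (HR), carotid-femoral pulse wave velocity (cfPWV), ejection
fraction (EF) — and asks nested cross-validated regressions (Random
Forest, SVR, Ridge, Gradient Boosting) to recover three invasive targets:

* **aSBP** — aortic systolic blood pressure (mmHg),
* **CO** — cardiac output (L/min),
* **E_es** — left-ventricular end-systolic elastance (mmHg/mL), the slope
  of the end-systolic pressure-volume relation and a load-independent
  contractility index.

The heart is a time-varying elastance chamber, `P_lv = E(t)(V_lv − V_d)`
with `E(t)` rising from `E_ed` to `E_es` over `t_max = 340 ms`; the
arteries form a tapered RLC transmission-line tree with three-element
Windkessel terminations, calibrated per subject so total compliance and
peripheral resistance match the sampled values exactly. cfPWV is measured
from the simulated waves by the clinical foot-to-foot (intersecting
tangents) method. Every feature and target is corrupted with a bounded
±6% relative measurement error before regression. See
[docs/methods.md](docs/methods.md) for the full model description.

The audience: researchers in cardiovascular modelling or physiological
machine learning who want a fully reproducible, tested virtual-population
pipeline — from ODE integration to nested-CV reporting — in plain Python.

## Worked example

```python
from hemopred.config import StudyConfig
from hemopred.population import SamplingConfig
from hemopred.study import generate_study_dataset, run_study

config = StudyConfig(sampling=SamplingConfig(n=300, seed=7), batch_size=150)
report = generate_study_dataset(config)          # ~1 min on one CPU
print(report.dataset.table[["brSBP_mmHg", "aSBP_mmHg", "cfPWV_mps"]].mean())

runs, summary, hyper, importances = run_study(
    report.dataset, config, families=("svr", "ridge"))
print(summary[["model", "target", "features", "r", "rmse"]].to_string(index=False))
```

which prints (n = 300, seed 7; your numbers will match exactly):

```
brSBP_mmHg    126.622454
aSBP_mmHg     119.994608
cfPWV_mps       8.380191
dtype: float64

       model target                features        r     rmse
         svr   aSBP    brSBP+brDBP+HR+cfPWV 0.957381 6.768343
       ridge   aSBP    brSBP+brDBP+HR+cfPWV 0.982237 4.862530
ensemble_all   aSBP    brSBP+brDBP+HR+cfPWV 0.980350 5.170729
         svr     CO    brSBP+brDBP+HR+cfPWV 0.838354 0.703756
       ridge     CO    brSBP+brDBP+HR+cfPWV 0.857953 0.664761
ensemble_all     CO    brSBP+brDBP+HR+cfPWV 0.862852 0.654113
         svr   E_es    brSBP+brDBP+HR+cfPWV 0.287249 0.352457
       ridge   E_es    brSBP+brDBP+HR+cfPWV 0.316382 0.346527
ensemble_all   E_es    brSBP+brDBP+HR+cfPWV 0.321200 0.345972
         svr   E_es brSBP+brDBP+HR+cfPWV+EF 0.614650 0.288209
       ridge   E_es brSBP+brDBP+HR+cfPWV+EF 0.652050 0.275167
ensemble_all   E_es brSBP+brDBP+HR+cfPWV+EF 0.646682 0.277385
```

(brachial SBP, mean 126.6 mmHg, sits above the aortic 120.0 mmHg —
peripheral amplification — and cfPWV averages 8.4 m/s.)

The pattern the study is about is already visible at this scale: aortic
pressure is recovered almost perfectly from cuff-type inputs, cardiac
output partially, and contractility not at all — until EF joins the
feature set, which roughly doubles its correlation.

## The analysis, step by step

Numbered drivers under `analysis/` reproduce the full study and write
their tables under `results/`:

| script | what it does |
|---|---|
| `00_calibrate_template.py` | re-runs the scripted wave-speed calibration and audits the population against the study table |
| `01_generate_population.py` | samples, simulates and measures the virtual population; writes `dataset.csv` + drop log |
| `02_nested_cv_study.py` | the nested-CV battery over models and scenarios; metrics, hyperparameter frequencies, importances |
| `03_training_size_sweep.py` | RMSE as the training split shrinks 95%→15% |
| `04_linear_statistics.py` | OLS coefficient t-tests and the correlation matrix |
| `05_external_validation.py` | train-on-synthetic / test-on-external workflow (synthetic stand-in cohort by default) |

The same workflows are available as a CLI:
`hemopred generate | train-eval | sweep | external-test | report`.

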