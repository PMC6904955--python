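# prostate-qmri

Longitudinal quantitative MRI analysis of weekly prostate radiotherapy,
rebuilt as a tested pipeline over a synthetic phantom cohort with known
ground truth.

## The problem

During ultra-hypofractionated prostate radiotherapy (five weekly fractions),
quantitative MRI — T2 maps from a multi-echo spin-echo series and ADC maps
from diffusion-weighted imaging — can track tissue change week by week.  The
analysis question is whether median T2/ADC values in three regions of
interest (central gland CG, peripheral zone PZ, tumor) change significantly
over treatment, how the trajectories differ between patients with and
without concurrent hormonal therapy, and which individual patients show
changes that exceed test-retest repeatability and persist to the end of
treatment.

The core quantities:

- **ADC** from the mono-exponential model `S(b) = S0·exp(−b·ADC)`, fitted by
  log-linear least squares over b ∈ [200, 800] s/mm² (never b = 0).
- **T2** from `S(TE) = S0·exp(−TE/T2)` over 12 echoes (TE = 32…208 ms),
  fitted by iteratively reweighted log-linear least squares.
- **Normalized trajectories** `x_w = median_w / median_0` per patient ×
  region × map, after rigid mutual-information registration of every weekly
  exam to the pretreatment anatomy, resampling to a 1 mm isotropic grid, and
  erosion of each region by a 2 mm margin.
- **Nine Wilcoxon signed-rank tests** (exact, tie-aware) of pretreatment vs
  week-5 medians at the Bonferroni level 0.05/9 (p < 0.0056).
- **Persistence calls** against repeatability confidence intervals of 11 %
  (T2) and 47 % (ADC): a change counts only if it stays outside the interval
  with the same sign through week 5.

Because the underlying patient data are not deposited, the package ships a
seeded synthetic cohort generator (digital pelvis phantom, Rician noise,
known weekly effect sizes, random inter-exam misalignment, missing weeks)
so that every stage is verifiable against ground truth.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from prostate_qmri import SimConfig, PipelineConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(n_patients=20, snr=30.0, seed=7))
run = run_pipeline(config, out_dir="scratch/demo")

for t in run.result.tests:
    flag = "*" if t["significant"] else " "
    print(f"{flag} {t['map_type']:>3} {t['roi']:>5} {t['stratum']:>4}: "
          f"{t['week5_percent_change']:+6.1f} %  p={t['p_value']:.4g}  "
          f"(n={t['n_patients']})")
```

Output (seed 7):

```
*  T2    CG   HT:  -11.2 %  p=0.001953  (n=10)
*  T2    PZ   HT:  -17.5 %  p=0.001953  (n=10)
*  T2 tumor   HT:   +4.2 %  p=0.001953  (n=10)
* ADC    CG   HT:   -7.4 %  p=0.001953  (n=10)
* ADC    PZ   HT:  -17.6 %  p=0.001953  (n=10)
* ADC tumor   HT:   +7.7 %  p=0.001953  (n=10)
* ADC    CG noHT:   -3.5 %  p=0.003906  (n=10)
* ADC    PZ noHT:   -5.8 %  p=0.001953  (n=10)
* ADC tumor noHT:  +19.8 %  p=0.001953  (n=10)
```

Each line is one cell of the nine-test battery: the population median
week-5 change of the normalized trajectory, the exact Wilcoxon signed-rank
p-value for pretreatment vs week-5 medians, and a `*` when it clears the
Bonferroni threshold p < 0.0056.  The recovered changes sit within about a
point of the effect sizes injected by the simulator (CG −12 %/−8 %, PZ
−17 %/−18 % under hormonal therapy; tumor +20 % ADC without).  Note that
with the generator's deliberately tight patient-to-patient spread every
injected effect — even the small ones — is sign-consistent across patients
and therefore significant; in clinical cohorts the biological spread is far
larger, which is why only the big effects survive testing there.  A
flat-effect cohort (`week5_factors` all 1.0) shows no significant tests,
which is the type-I behaviour the test suite verifies over 100 replicates.

The same flow is available step by step as numbered drivers:

```bash
python analysis/01_simulate_cohort.py        # NIfTI cohort + manifest
python analysis/02_fit_register_extract.py   # maps, registration, trajectories
python analysis/03_cohort_statistics.py      # exclusions, tests, persistence
python analysis/04_render_report.py          # figures + summary tables
```

or through the CLI (`prostate-qmri simulate|fit-adc|fit-t2|register|
propagate|analyze|report|run-all`).

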