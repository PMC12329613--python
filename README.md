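# ssdelp

Size-specific dose estimate (SSDE) dose indices and effective-dose
conversion-coefficient calibration for abdominopelvic CT.

## The problem

Clinics routinely estimate a patient's effective dose *E* (mSv) from a CT
exam by multiplying the console's dose-length product, DLP = CTDIvol × scan
length (mGy·cm), by a fixed conversion coefficient, conventionally
*k* = 0.015 mSv·mGy⁻¹·cm⁻¹ for the abdominopelvic region. But CTDIvol is a
phantom-referenced machine output: for patients smaller or larger than the
32 cm reference phantom the DLP-based estimate is biased, and the bias grows
with body size.

The size-specific dose estimate corrects for this. From each axial image the
water-equivalent diameter

&nbsp;&nbsp;&nbsp;&nbsp;*D*<sub>w</sub> = 2·√([CT̄<sub>ROI</sub>/1000 + 1]·*A*<sub>ROI</sub>/π)

gives the diameter of the water cylinder with the patient's integrated
attenuation, and the size-dependent factor *f*(*D*<sub>w</sub>) =
*a*·exp(−*b*·*D*<sub>w</sub>) (32 cm-phantom coefficients
*a* = 3.704369, *b* = 0.03671937) converts the slice dose:
SSDE(*z*) = *f*(*D*<sub>w</sub>(*z*))·CTDIvol(*z*). The **SSDE-length
product**, SSDE-LP = mean SSDE × scan length, is the size-corrected analogue
of DLP.

This package implements the full calibration pipeline around that index:

1. **dose_metrics** — per-slice *D*<sub>w</sub>, *f*, SSDE and per-exam
   scan length / DLP / mean SSDE / SSDE-LP from pixel data (plus a minimal
   DICOM slice reader);
2. **cohort** — exam records, exclusion filtering (arm-in-field, metal
   implants, non-positive reference dose), stratification and CSV I/O;
3. **calibration** — sex-stratified conversion coefficients *k*<sub>DLP</sub>
   and *k*<sub>SSDE-LP</sub> as regression slopes of reference effective dose
   on each index (intercept or through-origin mode), with R² diagnostics and
   the fixed conventional *k* = 0.015 alongside;
4. **validation** — held-out verification: predicted − reference effective
   dose per factor and stratum, summarized as mean ± SD and ranked;
5. **synth_cohort** — a virtual-patient generator (elliptical water
   phantoms, exponential tube-current modulation, a surrogate reference dose
   linear in SSDE-LP) so the whole pipeline runs end to end with no clinical
   data;
6. **cli** — `ssdelp simulate / compute / fit / validate / report`.

It is aimed at medical physicists who want to calibrate facility-specific
conversion coefficients against their dose-management software and verify
them on a held-out year of exams.

## Worked example

Simulate a two-year study (377 calibration exams, 293 held-out validation
exams), fit the coefficients, and verify them:

```bash
$ ssdelp simulate --seed 42 --out-dir run
stratum   n  age_mean    age_sd note
   male 224 60.857143 17.610564
 female 153 58.222222 20.270935
   both 377 59.787798 18.754363
...

$ ssdelp fit --calibration run/calibration.csv --out run/factors.yaml
factor                            male                female                  both    target
k_conventional                   0.015                 0.015                 0.015       DLP
k_dlp                 0.013 (R2=0.983)      0.016 (R2=0.986)      0.013 (R2=0.969)       DLP
k_ssde_lp             0.012 (R2=0.993)      0.014 (R2=0.995)      0.012 (R2=0.984)   SSDE-LP

$ ssdelp validate --validation run/validation.csv --factors run/factors.yaml --out run/summary.tsv
factor                      male (mSv)          female (mSv)            both (mSv)
conventional                -0.1 ± 1.6            -1.4 ± 0.8            -0.7 ± 1.4
k_dlp                       -1.4 ± 0.9            -1.0 ± 0.7            -1.6 ± 1.1
k_ssde_lp                   -0.1 ± 0.6            -0.0 ± 0.4            -0.4 ± 0.8
INFO ssdelp: ranking (male, best first): k_ssde_lp < conventional < k_dlp
```

Reading the output: the fitted SSDE-LP coefficients (0.012 male, 0.014
female) recover the generator's true values with R² ≈ 0.993–0.995 — higher
than the DLP fits, because the reference dose tracks the size-corrected
index. On the held-out cohort the discrepancy grid (predicted − reference,
so underestimation is negative) shows the conventional factor
underestimating in every stratum and the SSDE-LP factor with both the
smallest central discrepancy and the smallest SD — stable accuracy across
body sizes, which is the point of the size-corrected index.

Every command writes a `*.manifest.json` (config snapshot, seed, input and
output digests); the pipeline is byte-identical across reruns of one seed.

The library surface mirrors the CLI, e.g.:

```python
from ssdelp import (GeneratorConfig, generate_cohorts, filter_cohort,
                    fit_all, compute_discrepancies, summarize_discrepancies)
cohorts = generate_cohorts(GeneratorConfig(seed=42))
cal, _ = filter_cohort(cohorts["calibration"])
factors = fit_all(cal)                         # 2 indices x 3 strata + 0.015
```

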