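# tacdose

Lesion and kidney dosimetry for ¹⁷⁷Lu radioligand therapy (e.g.
¹⁷⁷Lu-PSMA-I&T) from serial quantitative SPECT/CT measurements: time–activity
curve (TAC) fitting with population-shared parameters, time-integrated
activity, mass-corrected absorbed dose, biologically effective dose, and a
systematic comparison of reduced imaging schedules against a four-time-point
reference. A phantom-analysis module quantifies partial-volume effects of
CT-based versus isocontour sphere segmentation, and a synthetic-data module
generates cohorts and phantom images with the study's statistical structure
so that every stage is testable without patient data.

The package is for medical physicists and methodologists who want to study
how the number and timing of SPECT/CT acquisitions propagates into dose
estimates.

## Model

Each volume of interest (VOI — a lesion or kidney) has activity samples
A(tᵢ) at times tᵢ post-injection. Four washout models are supported, all
containing the fixed physical decay λ_phys = 4.34·10⁻³ h⁻¹ of ¹⁷⁷Lu:

    f_mono(t)   = A₀ e^{−(λ_bio+λ_phys) t}
    f_bi1(t)    = A₀ γ e^{−(λ_bio+λ_phys) t} + A₀ (1−γ) e^{−λ_phys t}
    f_bi2(t)    = A₀ e^{−(λ_bio+λ_phys) t} + A₁ e^{−λ_phys t}

The bi-exponential models keep two free parameters per VOI by treating one
parameter (γ, λ_bio or A₁) as population-shared; the shared value is
estimated with a leave-one-patient-out jackknife over joint fits. The dose
chain follows the MIRD self-dose formalism:

    TIA = ∫₀^∞ f(t) dt,   D = TIA · S(m),   S(m) = S_ref · m_ref / m,
    BED = D · RE,         RE = 1 + D · G / (α/β),

with the VOI mass m from the CT volume and an HU → density calibration
(ρ = 7.94·10⁻⁵·HU + 0.964 g/ml), and G the Lea–Catcheside dose-protraction
factor (λ_eff/(µ+λ_eff) for mono-exponential washout; the standard
four-term expression for bi-exponential washout). Reduced sampling schedules
(subsets of days 1, 2, 3, 7) are scored by the relative BED deviation
RD = 100·(BED − BED_ref)/BED_ref, its mean absolute value (MD ± SD) and
Bland–Altman statistics.

## Worked example

```python
import tacdose as td

# synthetic five-patient cohort at the study's acquisition times
cohort, truth = td.generate_cohort(td.CohortSpec(seed=1))
lesion = next(s for s in cohort if s.voi_type == "lesion")

model = td.TimeActivityModel(lesion, td.ModelId.MONO)
result = model.fit()
print(result.summary())

dose = td.voi_dose(lesion, result, td.TUMOR)
print(f"TIA {dose.tia_MBq_h:.1f} MBq h, D {dose.D_Gy:.2f} Gy, "
      f"G {dose.G:.4f}, BED {dose.BED_Gy:.2f} Gy")
```

prints

```
Time-activity curve fit
======================================================
Model:       mono
Samples:     4    dof: 2    converged: True
SSE:         0.0220635 MBq^2
TIA:         553.547 MBq h
T_eff:       55.15 h
------------------------------------------------------
param             estimate       std err        CV %
a0                 6.95668        0.1801        2.59
lambda_bio      0.00822745     0.0006078        7.39
======================================================
TIA 553.5 MBq h, D 2.76 Gy, G 0.0333, BED 2.84 Gy
```

The summary table gives the fitted activity at t = 0 (A₀, MBq) and the
biological clearance rate (h⁻¹) with their standard errors and coefficients
of variation; T_eff is the effective half-life. The dose line shows the
chain TIA → absorbed dose → Lea–Catcheside factor → BED for this ~17 g
lesion: 553.5 MBq·h of integrated activity deposit 2.76 Gy, and the slow
delivery (G ≈ 0.03, most sublethal damage repaired between decays) raises
the biologically effective dose only slightly above the absorbed dose.

Comparing a reduced schedule to the four-point reference:

```python
lesions = [s for s in cohort if s.voi_type == "lesion"]
report = td.deviation_report(lesions, td.SamplingSchedule((1, 3, 7)), td.ModelId.MONO)
print(f"MD {report.md_percent:.1f} ± {report.md_sd:.1f} %, "
      f"{100 * report.frac_within_10pct:.0f}% of lesions within ±10%")
# -> MD 1.8 ± 1.4 %, 100% of lesions within ±10%
```

The same pipeline is scriptable from the shell:

```
tacdose simulate --seed 1 --out cohort.csv
tacdose sampling-study --input cohort.csv --schedules 1,3,7 --schedules 1,2,3 --out summary.json
tacdose dose --input cohort.csv --out doses.csv
tacdose phantom --seed 1 --fwhm-mm 10 --out rc.csv
```

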