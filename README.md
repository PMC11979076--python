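# thyrokin

Population-based model selection (PBMS) with non-linear mixed-effects (NLME)
modelling for ¹³¹I thyroid retention kinetics.

## The problem

Pre-therapy dosimetry for radioiodine treatment of benign thyroid disease
needs each patient's **time-integrated activity** (TIA): the integral over
time of the fraction of administered activity retained in the thyroid,

```
TIA = ∫₀^∞ a(t) dt        [h, per unit administered activity]
```

The TIA is obtained by fitting a kinetic model to a handful of retention
measurements per patient (nominally 2, 6, 24, 48 and 96 or 120 h after
administration). Which function to fit is not innocuous: different choices
shift individual TIAs — and hence the prescribed therapeutic activity — by
tens of percent. `thyrokin` implements a reproducible, statistically
principled way to make that choice for a whole patient population at once:

1. **Candidate bank.** Nine sums of exponentials `a_px(t)` with 3–6 adjustable
   parameters, each term decaying with its biological rate plus the physical
   decay constant λ_phys = ln 2 / (8.022 d) of ¹³¹I. The bank includes the
   bi-exponential uptake/clearance function of the EANM standard operational
   procedure (`a3b`) and its extension with a residual blood-pool amplitude
   (`a4c`).
2. **NLME fit.** Each candidate is fitted to all patients jointly:
   `P_i = TVP · exp(η_i)` with `η_i ~ N(0, diag(ω²))` and proportional
   residual error `y = f·(1+ε)`, `ε ~ N(0, σ²)` (additive, combined and
   exponential variants available). Estimation maximizes the
   Laplace-approximate marginal likelihood with many randomized starts.
3. **Goodness-of-fit gate.** A fit survives only if it converged with usable
   uncertainties, relative standard errors < 0.3 (fixed effects) and < 0.5
   (random effects), maximum |off-diagonal correlation| < 0.8, and no
   systematic residual trend at any nominal sampling time.
4. **AICc / Akaike weights.** Surviving candidates are ranked by
   `AICc = −2 ln L̂ + 2K + 2K(K+1)/(N−K−1)` and weighted by
   `w = exp(−Δ/2) / Σ_F exp(−Δ/2)`; the highest-weight function is selected.
5. **TIAs and validation.** Per-patient TIAs come from empirical-Bayes
   parameters in closed form; VPC, NPDE and SIR quantify model adequacy and
   parameter uncertainty; an individual-fit comparator (per-patient `a3b`
   least squares, K = 3 × patients) reproduces the standard-procedure
   bookkeeping.

Because the underlying patient data are not public, the package ships a
synthetic-cohort generator that reproduces the study design (73 patients,
N = 364 observations) from the published population estimates, so the whole
pipeline is testable end to end.

## Worked example

```python
from thyrokin import (RetentionNLME, generate_population, run_pbms)

data = generate_population(seed=7)        # 73 patients, 364 observations
report = run_pbms(data, n_starts=100, seed=7)
print(report.to_frame().to_string(index=False))
print("selected:", report.selected_model_id)

best = report.fits[report.selected_model_id]
print(best.summary())
print("typical TIA [h]:", round(best.tia_typical(), 1))
```

Output (abridged; the full run takes ~10 minutes):

```
function  K  max_fixed_rse  max_random_rse  max_corr           of         aicc  akaike_weight_pct                 gate
     a3a  7       0.001156        0.019259  0.848594 -1031.574189 -1017.259583                NaN          correlation
     a3b  7       0.078015        0.178046  0.512682 -1052.678868 -1038.364261       6.047625e-53                 pass
     a4a  9       0.003899        0.012256  0.729525 -1074.073005 -1055.564530       3.285305e-49                 pass
     a4b  9       6.173266        5.139775  0.379558 -1030.477453 -1011.968978                NaN fixed_rse,random_rse
     a4c  9       0.155200        0.274212  0.507172 -1306.557765 -1288.049290       1.000000e+02                 pass
     a5a 11            NaN             NaN       NaN -1070.232982 -1047.482982                NaN          convergence
     a5b 11            NaN             NaN       NaN -1134.882330 -1112.132330                NaN          convergence
     a6a 13            NaN             NaN       NaN -1065.770935 -1038.730935                NaN          convergence
     a6b 13            NaN             NaN       NaN -1249.689554 -1222.649554                NaN          convergence
selected: a4c
```

and for the selected fit:

```
Retention NLME results — model a4c (proportional error)
patients: 73   observations: 364   K: 9
-2 log L (Laplace): -1306.558   starts: 100 (best: #95)
----------------------------------------------------------
parameter           estimate     RSE
tvp_a1               0.06222   0.088
tvp_lambda1          0.06133   0.106
tvp_lambda2          0.06595   0.058
tvp_lambda3         0.001049   0.155
omega2_a1             0.3568   0.224
omega2_lambda1        0.7745   0.175
omega2_lambda2        0.1493   0.233
omega2_lambda3        0.5905   0.274
sigma2              0.002137   0.133
max |off-diagonal correlation|: 0.507
typical TIA [h]: 101.3
```

The generating function — the blood-pool-extended bi-exponential `a4c` — is
selected with an Akaike weight of ≈100%: once precision criteria are
enforced, none of the other eight candidates retains measurable support (the
models that fit acceptably, `a3b` and `a4a`, trail by >200 AICc units; the
rest fail the gate on correlation, precision or a usable covariance). The
typical-subject TIA (≈100 h per unit administered activity) is the quantity
that feeds the therapeutic activity calculation, and per-patient TIAs come
from `best.patient_tia(pid)`.

A command-line interface mirrors the library:

```sh
thyrokin simulate --out cohort.csv --seed 7
thyrokin select --data cohort.csv --n-starts 100 --seed 7 --out report.json
thyrokin fit --data cohort.csv --model a4c --n-starts 100 --out fit.json
thyrokin validate --data cohort.csv --fit fit.json
thyrokin run --out results/           # full pipeline with manifest
```

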