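# thighasym

Quantifying left–right soft-tissue asymmetry of the mid-thigh from CT
radiodensity histograms, and relating it to age and functional mobility in
elderly cohorts.

## The problem

A single mid-thigh CT cross-section summarises a leg's soft-tissue
composition as a histogram of Hounsfield-unit (HU) values on [−200, 200].
That histogram is trimodal: adipose tissue occupies [−200, −10] HU, loose
connective tissue [−9, 40] HU, and lean muscle [41, 200] HU. Sarcopenia
research uses the shape of these modes as markers of muscle quantity and
quality, and the *difference between the two legs* as a marker of
asymmetric decline, which is associated with slower gait and higher fall
risk in older adults.

`thighasym` is for biostatisticians and musculoskeletal researchers who
need that analysis as a reproducible library rather than a spreadsheet:
fit the trimodal model per leg, compute per-subject asymmetry indicators,
and run the cohort-level trend and stratification workflow. Because the
clinical source cohorts of this kind are access-restricted, the package
ships a synthetic cohort generator with a ground-truth ledger so every
stage is testable end to end.

## The model

Each leg's histogram is treated as a quasi-probability density: a sum of
three amplitude-scaled, optionally skewed Gaussian modes,

```
f(x) = Σᵢ  Nᵢ/(σᵢ√2π) · exp(−(x−μᵢ)²/(2σᵢ²)) · erfc(αᵢ(x−μᵢ)/(σᵢ√2)),
```

with i ∈ {fat, connective, muscle}, the connective mode held symmetric
(α = 0). With this normalisation each mode integrates to exactly Nᵢ, so N
measures tissue quantity (histogram mass) while μ, σ, α describe tissue
quality. That gives 11 parameters per leg, estimated by bounded
trust-region nonlinear least squares on the 401 per-bin residuals, each μ
confined to its tissue window.

Per subject, the 11 asymmetry indicators are ΔNTRA_i = |left_i − right_i|.
The cohort workflow then: (1) min-max normalises each indicator across the
cohort, (2) averages within integer years of age, (3) fits a cubic
polynomial to each age-averaged series, (4) selects the indicator with the
highest R² per tissue, and (5) re-computes the age trends within BMI
(<18.5 / 18.5–25 / 25–30 / ≥30 kg/m²), normal-gait (1.0 m/s), fast-gait
(1.3 m/s) and timed-up-and-go (10/13/29 s) classes, alongside paired
left-vs-right t-tests per parameter.

## Worked example

```sh
python examples/cohort_workflow.py
```

simulates an 80-subject cohort, fits all 160 histograms and runs the full
workflow, printing (abridged):

```
selected indicator per tissue (highest cubic-trend R^2):
  connective   dsigma_conn    R^2 = 0.597
  fat          dN_fat         R^2 = 0.531
  muscle       dsigma_mus     R^2 = 0.657
```

The generator imposes asymmetry that grows with age in muscle width,
connective-tissue width and fat amplitude; the R²-based selection recovers
exactly those three indicators from the fitted (not true) parameters.
`examples/fit_single_histogram.py` shows a single 100 000-pixel fit
(amplitudes recovered within ~1%), and `examples/group_separation.py`
prints the mobility-class separation fractions — ~100% of ages separated
for the fast-gait split that the generator links to asymmetry, ~50–70%
(no systematic separation) for the unlinked normal-gait and TUG splits.

The same workflow is scriptable from a shell:

```sh
thighasym all -n 50 --seed 7 --out runs/demo --group gait_fast --plots
```

which writes every artifact (histograms, fits, indicators, trends,
grouped trends, t-tests, report) as CSV/JSON into `runs/demo/`; re-running
with the saved `generator_config.json` reproduces them bit-identically.

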