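# Methods

## Radiodensity model

A mid-thigh HU histogram over [−200, 200] HU is modelled as the sum of
three modes, one per tissue, each of the form

    φ(x; N, μ, σ, α) = N/(σ√2π) · exp(−(x−μ)²/2σ²) · erfc(α(x−μ)/(σ√2)).

Since erfc(αz/√2) = 2Φ(−αz), φ equals N times a skew-normal density with
shape −α, so ∫φ dx = N identically for every α: the amplitude is the
mode's mass, independent of its shape. `mode_mass` therefore returns N
analytically; the test suite confirms the identity by quadrature. The
connective mode's skewness is structurally fixed at zero, leaving 11 free
parameters per leg in the canonical order
(N, μ, σ, α)_fat, (N, μ, σ)_conn, (N, μ, σ, α)_mus.

Tissue windows are fixed integer-HU intervals — fat [−200, −10],
connective [−9, 40], muscle [41, 200] — that partition [−200, 200].
Histograms use unit-width bins centred on the 401 integers (integer HU is
the native CT quantisation; bin k covers [k−0.5, k+0.5), values outside
the range are discarded and counted).

## Fitting

The objective is the plain sum of squared per-bin residuals between the
observed counts and the trimodal curve at the 401 bin centres, minimised
with a bounded trust-region least-squares solver under box constraints:
each μ inside its tissue window, σ ∈ [0.5, 120] HU, α ∈ [−10, 10],
N ∈ [0, 10 × total mass], α_conn ≡ 0. A density-normalised objective
(counts divided by total mass) is available and yields the same
(μ, σ, α) with N rescaled. Initialisation is deterministic: per window,
N₀ = window mass, μ₀ = mass centroid, σ₀ = mass SD floored at 2 HU,
α₀ = 0. Convergence tolerances are ftol 1e−10 / xtol 1e−12 with at most
500 iteration-equivalents; the returned SSE never exceeds the objective at
the initialisation (the trust-region path is monotone, and the
initialisation is returned if the solver ever reports worse).

Degenerate inputs: an empty histogram or all-non-finite counts raise; a
histogram with fewer than four occupied bins cannot identify the model and
is returned with `converged=False`; an empty tissue window is legitimate
(obese or lean extremes) and simply drives that mode's N toward zero.

On noiseless model curves the fit recovers all 11 parameters to ~1e−10
relative. Under Poisson sampling noise at mass 1e5 the median errors are
≈0.3 HU in μ, ≈2% in σ and <1% in N; the broad, mildly skewed fat mode
shows the usual skew-normal μ/α trade-off, which inflates its individual
errors without biasing the mass.

## Asymmetry workflow

Indicators are ΔNTRA_i = |left_i − right_i| for the 11 canonical
parameters (absolute values, so the vector is invariant to leg order).
The cohort stages:

1. **Min-max normalisation** per indicator across the full analysis
   cohort: (v − min)/(max − min). A constant indicator is degenerate; its
   normalised values are defined as 0 and a warning is raised (this keeps
   an all-symmetric cohort runnable). Group analyses reuse the cohort-wide
   extrema rather than re-normalising within groups, since normalisation
   precedes grouping in the workflow; a per-group re-normalisation would
   change only the vertical scale of each group's curve.
2. **Age averaging**: arithmetic mean per integer year of age actually
   present (ages with no subjects are absent, not zero-filled).
3. **Cubic trend**: unweighted OLS cubic on (age, mean) pairs, R² =
   1 − SSE/SST, requiring ≥ 4 distinct ages; SST = 0 defines R² = 0 with
   a warning.
4. **Selection**: per tissue, the indicator with maximal R²; ties break
   by canonical parameter order and are flagged, as is an all-zero tissue.
5. **Grouping**: age series and cubic fits per class of BMI, normal gait,
   fast gait or TUG. Subjects missing a grouping variable are excluded
   from that grouping only; groups with < 4 distinct ages are marked
   unfittable rather than raising.

Paired left-vs-right t-tests use d = left − right, t = mean(d)/(sd(d)/√n)
with sample SDs (n−1) and two-sided Student-t p-values on n−1 df. All-zero
differences are reported as an undefined statistic (flag, NaN) rather than
an exception. p-values are raw; no multiple-testing correction.

Class thresholds are hard-coded clinical cut-offs: BMI 18.5/25/30 kg/m²,
normal gait 1.0 m/s, fast gait 1.3 m/s, TUG 10/13/29 s. The published
class definitions use strict inequalities on both sides, leaving boundary
values unassigned; this package assigns boundaries to the upper class
(lower-inclusive intervals), so BMI 25.0 → class 3, v_fast 1.3 → normal,
TUG 29.0 → very slow.

## Synthetic cohort generator

The generator emulates the statistical structure of an elderly CT cohort
(the real cohorts of this kind are access-restricted) and doubles as the
ground-truth oracle for recovery tests. Defaults, chosen once as
plausible for a mid-thigh slice and an aged population:

* ages uniform on 71–98 years; ~62% female; n configurable.
* left-leg parameters = template + Gaussian subject jitter. Template:
  fat N = 0.33·M, μ = −60, σ = 25, α = 0.3; connective N = 0.22·M,
  μ = 15, σ = 12; muscle N = 0.45·M, μ = 55, σ = 13, α = 3.1, with
  M = 1e5 the per-leg sampling mass (≈ soft-tissue pixel count of a
  mid-thigh slice, order of magnitude). Jitter SDs: 6% on amplitudes,
  4–6 HU on locations, 2–3 HU on widths, 0.15–0.4 on skewness, with
  rejection-resampling to keep every μ inside its window (failure after
  1000 attempts raises).
* right leg = left ± a half-normal draw per parameter whose expected
  magnitude follows a cubic in (age − 70). The trends rise for muscle
  width (1.0 → ≈5.8 HU across the age range), connective width
  (0.8 → ≈4.1 HU) and fat amplitude (150 → ≈1030 pixels at M = 1e5) and
  stay age-flat for the remaining parameters — asymmetry grows with
  advancing age, concentrated in those three indicators.
* histograms: each leg's mass is drawn from its trimodal density via the
  δ-representation of the skew normal, truncated to [−200, 200] by
  rejection (rejections are counted), and binned; the expected histogram
  equals the true model curve. Generation can skip histograms
  (`make_histograms=False`) for parameter-level studies.
* outcomes: BMI ~ N(26.5, 4²) truncated above 12 kg/m²; gait speeds
  linear in age with Gaussian noise; TUG lognormal with median 11.3 s at
  71 rising ~1%/yr. A composite asymmetry burden (mean of the three key
  indicators, each scaled by its oldest-age expected magnitude, so the
  burden approaches 1 at age 98) enters the outcome models through
  configurable links; by default only fast gait speed is linked
  (−0.4 m/s per unit burden) while normal gait and TUG are unlinked,
  reproducing the qualitative pattern that fast-gait classes separate on
  asymmetry and TUG classes do not. Missingness is applied at 3.4%
  (v_norm), 12.7% (v_fast) and 3.3% (TUG), mirroring typical per-test
  attrition. Everything is deterministic under the configured seed.

What the generator does **not** emulate: partial-volume and beam-hardening
artefacts, bone/skin segmentation errors, non-uniform age pyramids,
sex-specific tissue distributions, and correlated multi-outcome noise.
Passing tests therefore demonstrate that the pipeline recovers structure
of this idealised form, not that real cohorts contain such structure.

## Problem sizes in the tests

The suite exercises the estimator at the scales where its statistical
claims are stated: 50 Poisson-noise histograms at mass 1e5 for recovery
medians, 20 replicates of 1000-subject cohorts (parameter-level, no
histogram refitting) for the trend-selection rate, 5 such replicates for
group separability, and a 10-subject fully-fitted mirrored cohort for the
end-to-end zero case. The grouped-separability criterion is evaluated on
the composite of the three selected indicators' fitted curves; "no
systematic separation" for the unlinked groupings is read as a pooled
slow-above-normal fraction staying below 0.8 across replicates, against
≥ 0.9 for the linked fast-gait split.

## Known limitations

* The skew-normal μ/α coupling makes individual fat-mode location/skewness
  estimates noisy at realistic masses; amplitude (tissue quantity) is
  robust. Asymmetry indicators inherit this per-parameter noise.
* The fit is a local optimiser; the deterministic moment initialisation is
  reliable for window-separated modes but pathological histograms (e.g.
  all mass on one bin) are flagged rather than solved.
* Min-max normalisation is sensitive to single extreme subjects; the
  extrema used are saved with every run for auditability.
* The cubic trend is a descriptive smoother, not a causal age model; R²
  comparisons between indicators share the same age grid by construction.
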