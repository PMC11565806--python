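# Methods

`fnirsinc` models and measures how participant-level factors — hair color,
curl pattern, strand coarseness, shaft thickness and density, skin
pigmentation (Melanin Index), head size, sex and age — degrade
continuous-wave fNIRS signal quality, and provides the statistical machinery
to quantify those effects. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic cohort does
and does not emulate.

## Signal-quality metrics

For a channel with raw intensity `I_w(t)` at wavelengths 760 and 850 nm:

* **Uncorrected Signal Mean (USM)** = time mean of `I_w`, averaged across
  the two wavelengths. Proportional to detected optical power; used by the
  NEP analysis and the capping comparison.
* **Corrected Signal Mean (CSM)**: per wavelength, the time mean is divided
  by the LED source-power percentage and multiplied by 100; the two
  corrected means are averaged and then log10-transformed. Source-power
  correction undoes the instrument's automatic source modulation (which
  otherwise hides attenuation differences between heads); the log
  approximately normalizes the distribution and makes factor effects
  additive. The order "average, then log" is a documented switch
  (`log_before_average`) because both readings of the definition are
  defensible; the default is stated so results are reproducible.
* **Scalp Coupling Index (SCI)**: both wavelength traces are band-passed to
  the cardiac band 0.5–2.5 Hz with a 3rd-order Butterworth filter applied
  forward-backward (zero phase, which preserves the zero-lag structure),
  normalized by their standard deviation, and correlated at lag zero.
  Well-coupled optodes see the same cardiac pulsation at both wavelengths,
  so SCI ≈ 1. A Fisher z-transform (`atanh`, input clipped to
  `|r| ≤ 1 − 1e-12`) stabilizes the variance for statistics.
* **SNR** = mean/SD of the raw intensity, averaged over wavelengths.
  Channels with SNR **strictly below 5** are excluded from task analyses;
  a zero-variance (noiseless) trace maps to +inf and is retained, since the
  absence of noise is not a defect.

## Combined hair-skin metric

Four factors — average shaft thickness (42–88 µm), hair type (0–4), hair
color (0–4) and skin pigmentation (4.7–90) — are each min-max normalized to
[0, 1] over these observed ranges and averaged with equal weights. Values
outside a range are clipped after normalization (with a warning): the
ranges are a study population's extremes, not physical bounds. Thickness
uses the mean of the side and back trichoscopy values; the two regions are
equally informative and no aggregation rule is canonical, so the symmetric
choice is used. Group assignment partitions [0, 1] into
[0.15, 0.30), [0.30, 0.45), [0.45, 0.60), [0.60, 0.75), [0.75, 1.0] (groups
1–5, right-half-open except the last); values below 0.15 fold into group 1
so the map is total.

## Statistics

* **Binning**: four equal-width bins over [min, max], right-half-open
  except the last. Binning serves visualization and the first-vs-last-bin
  tests only; correlations and regressions always use continuous values.
* **Mann-Whitney U** (two-sided) between the first and last bins: exact
  p-value for tie-free groups of ≤ 20, otherwise the normal approximation
  with tie correction (scipy).
* **Multiplicity**: Benjamini-Hochberg step-up across each analysis family;
  significance is declared at adjusted p ≤ 0.01.
* **Robust fits**: iteratively reweighted least squares with Tukey bisquare
  weights, tuning constant 4.685 (≈ 95% Gaussian efficiency — the common
  toolbox default), convergence tolerance 1e-8 on coefficients, at most 50
  iterations (non-convergence returns the last iterate, flagged). Perfect
  or near-perfect fits fall back to OLS because the robust scale estimate
  degenerates. Backed by statsmodels RLM.
* **Fold change**: the robust fit on the log10-scale response is evaluated
  at the 1st and 99th percentiles (linear interpolation between order
  statistics) of the factor, unlogged, and reported as U/L when U ≥ L and
  −L/U otherwise, so the magnitude is always ≥ 1 and the sign gives the
  direction.
* **Multicollinearity screen**: predictor pairs with |Pearson r| > 0.5 are
  resolved by dropping the lower-priority member; pairs are processed in
  descending |r| and pairs involving already-dropped predictors are skipped,
  which makes chains deterministic. The default priority prefers the more
  objective measurement (e.g. Melanin Index over the visually assessed
  Fitzpatrick group). VIFs (1/(1 − R²) of each predictor on the rest) are
  reported with bands < 5 low, 5–10 moderate, > 10 high.
* **Robust multiple regression**: same IRLS fit; SEs from the robust
  covariance; t = estimate/SE with two-sided p from a t distribution on
  n − p − 1 degrees of freedom. Cohen's **f²** per predictor is
  (R²_full − R²_−j)/(1 − R²_full) with R² computed from weighted sums of
  squares at the converged robust weights (a robust fit has no unique R²;
  this pairing is the documented choice), floored at 0; bands 0.02 / 0.15 /
  0.35 for small / medium / large.
* **Unit of analysis**: channel-wise rows within an ROI by default
  (responses are channel measurements), with a per-participant-mean switch
  because pooling channels inflates n; the tests exercise the default.

## NEP inclusivity analysis

The measurement device pairs a raw-unit noise floor (6.8e-6) with a known
detector sensitivity (NEP 52 fW/√Hz, detector area 9.6 mm²), giving a
linear raw ↔ optical-power equivalence: `power = raw × NEP/noise_floor`.
The √Hz bandwidth normalization is absorbed into this measured pair. A
channel passes if its mean power is at least the pruning threshold
`NEP × 10^(margin/10)` — dB is ten times the log10 of a *power* ratio, so
the default 20 dB margin is a factor of 100 (1 pW → 100 pW). Boundary
channels pass ("at least 20 dB"). The sensitivity sweep substitutes virtual
NEP values into the threshold only; the raw-to-power conversion always uses
the measurement device's constants (substituting the virtual NEP into both
would cancel out of the criterion). Pass percentages are reported per
combined-metric group; curves are non-increasing in NEP by construction.

## Task GLM

Raw intensities are converted to optical density `OD = −ln(I/mean(I))`,
SNR < 5 channels are removed first, the OD is low-pass filtered (6th-order
Butterworth at 0.5 Hz, forward-backward — zero phase, effective attenuation
order doubled, unit DC gain), and inverted through the 2×2 modified
Beer-Lambert system at 760/850 nm **without pathlength correction**:
concentrations are scaled only by the source-detector separation (in cm)
and therefore carry the unknown differential-pathlength factor. The
extinction coefficients are the standard Gratzer/Prahl compilation used
across fNIRS toolboxes: ε(760) = (586.0, 1548.52), ε(850) =
(1058.0, 691.32) cm⁻¹ M⁻¹ for (HbO₂, HbR).

The response kernel is the modified gamma
`h(t) = e·u²·exp(−u²)`, `u = (t − τ)/σ` for `t ≥ τ` (0 before), which has
unit peak at `t = τ + σ`: 3.1 s for HbO₂ (τ=0.1, σ=3) and 4.8 s for HbR
(τ=1.8, σ=3), on the −2…12 s window. The third parameter ("duration" = 5 s)
is the length of the stimulus boxcar the kernel is convolved with; the
convolved regressor is normalized to unit peak so betas carry amplitude
units. Condition regressors receive the same 0.5 Hz low-pass as the data,
keeping the OLS estimator unbiased under the generative model. For each
long channel, the short-separation channel with the highest Pearson
correlation to it is added as a superficial-physiology nuisance regressor
(ties break on sorted channel label); intercept and linear drift complete
the design. The estimated HRF is baseline-corrected by subtracting its mean
over −2…0 s, and the t-statistic of the HbO₂ condition beta is the primary
per-channel outcome. Left- and right-hand conditions are fitted jointly.

## Synthetic cohort and forward model

The generator emulates the structure the analyses assume, not photon
transport:

* **Participants.** Continuous factors are truncated normals with the
  population means/SDs built into the module (`TRICHOSCOPY_POPULATION`,
  `WHOLE_HEAD_POPULATION`); shaft thickness truncates to the observed
  42–88 µm, pigmentation to 4.7–90 (note: truncating the N(25.3, 18.1)
  parent at 4.7 shifts the realized mean to ≈ 29.6 — tests check against
  the closed-form truncated mean), other factors to mean ± 3 SD floored at
  0. Percent triples are renormalized to sum to 100. Categorical priors for
  hair color/type/texture were solved once so the unconditional means/SDs
  match the population table (e.g. color prior (.02, .06, .12, .30, .50)
  gives mean 3.2, SD 1.0). Pigmentation and hair color share a Gaussian
  copula (latent correlation 0.5 by default); the Fitzpatrick group is a
  deterministic regrouping of the pigment value (edges 20 and 45), which
  deliberately creates the > 0.5 correlation the screening step must
  resolve. Hair type/texture are independent of color given hair presence —
  a simplification; real coarseness co-varies with color.
* **Attenuation.** Per region, log10 attenuation is linear in the
  normalized pigment/color/thickness/type factors, which makes CSM linear
  in the factors — the functional form the regression analysis assumes.
  The hairless forehead responds to pigment only. Default weights
  (forehead 0.85 pigment; side 1.6/1.2/0.6/0.5; back 1.2/1.6/1.2/0.4 for
  pigment/color/thickness/type, log10 units per normalized factor) are
  anchored to the observed per-region effect *directions* and rough
  magnitudes; no quantitative attenuation-per-factor constants exist to
  calibrate against, so magnitude agreement is not claimed. A per-channel
  lognormal placement effect (SD 0.25 log10 units) persists across a
  capping pair (same cap, same head) but differs between participants'
  sessions.
* **Cardiac & coupling.** A shared sinusoid at 1.1 Hz plus one harmonic
  (1% of baseline), inside the SCI band, with per-channel coupling
  `1 − Σ w_f · factor_f` clipped to [0, 1] (weights on color/thickness/
  type), so hair degrades SCI without changing mean intensity. Smooth
  sub-0.25 Hz "systemic" noise is shared within a hemisphere so
  short-separation regression has something to remove.
* **Evoked responses.** Injected in OD space through the same forward
  Beer-Lambert matrix the analysis inverts, on side long channels
  contralateral to the squeezing hand, with true amplitudes set in the
  config (defaults 1e-6 HbO₂, −0.3e-6 HbR) — so GLM recovery is measured
  against a known truth.
* **Noise & power.** White Gaussian noise at the device-equivalent raw
  floor 6.8e-6 per sample. Source power is "fixed" (100%) by default; the
  "auto-scaled" policy emulates the instrument raising LED power for
  attenuated channels (capped at 100%), which flattens USM while the
  power-corrected CSM still reveals the attenuation.
* **Capping pairs.** The fast-capping run adds hair-scaled extra
  attenuation (0.10 log10 per normalized hair-factor sum) and a coupling
  penalty (0.20), on side/back only; the proper-capping run does not. The
  forehead is unaffected by construction.

Not emulated: photon transport and 3-D head optics, motion artifacts, hair
styles (braids, locs, etc.), detector-type asymmetries between hemispheres,
and any mechanistic sex effect (hooks exist but default off). Passing tests
therefore demonstrate that the *analysis chain* is correct and calibrated
under the assumed generative structure, not that the forward model
reproduces any particular device's measurements.

## Problem sizes and numerical choices

Cohort-level test runs use short resting segments (≈ 12 s) when only
mean-intensity metrics are consumed, 3-minute segments where the SCI null
distribution matters, and full-length task runs (15 trials/condition,
5 s stimuli, 5–15 s ISI) for GLM recovery; these sizes were chosen so the
whole battery runs comfortably on one CPU while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances. All randomness flows
through explicit integer seeds; identical seed and config give bit-identical
outputs. Degenerate inputs are flagged, not silently dropped: non-positive
means (CSM), flat traces (SCI/SNR), rank-deficient designs and empty
metric groups all surface as NaN/inf sentinels or typed errors.

## Known limitations

* The attenuation and coupling weights set effect *directions* reliably;
  absolute fold changes and f² magnitudes depend on them and should not be
  read as device predictions.
* OLS GLM inference ignores residual autocorrelation from unmodeled
  physiology; t-statistics on real recordings would need prewhitening
  (out of scope here).
* The SNIRF writer/reader covers CW amplitude data only; channel
  annotations ride in `metaDataTags` JSON, which foreign readers ignore.
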