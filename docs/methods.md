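# Methods

## Scope and data model

The package analyses broadband dielectric spectra of amorphous
drug–polymer dispersions along the two workflows such studies use:
non-isothermal characterization (spectra on a heating ramp → relaxation
map → glass transition, crystallization onset, stability factor) and
isothermal/isochronal stability comparison (fixed-frequency ε′ traces →
crystallization kinetics → residual composition). All temperatures are in
kelvin, frequencies in Hz, relaxation times in seconds, with ω = 2πf;
conversions happen only at I/O boundaries. Files are long-format CSV with
unit-suffixed headers (`temperature_K`, `time_s`, `frequency_Hz`,
`eps_real`, `eps_imag`), chosen because no standard interchange format
exists for dielectric data and explicit units prevent silent kelvin/°C or
Hz/rad·s⁻¹ mix-ups. Rows are grouped into spectra by temperature with a
0.01 K tolerance (configurable) — an order of magnitude tighter than a
good cryostat's stability, so distinct set-points are never merged while
controller drift within one sweep is.

## Havriliak–Negami fitting

Each spectrum is modelled as ε*(ω) = ε∞ + Δε/[1 + (iωτ_HN)^a]^b +
σ_dc/(ε0·iω), sign convention ε* = ε′ − iε″. One relaxation process is
fitted; secondary (β) relaxations and electrode polarization are out of
scope. Loss spectra are baseline-corrected nowhere: the reader makes no
silent corrections.

Design choices, all of which were genuinely open:

* **Objective.** Default `loss_only` minimizes residuals on log ε″. The
  loss spans several decades across a sweep; linear residuals would fit
  only the peak, log residuals weight every decade equally. A `complex`
  mode minimizes joint relative residuals on ε′ and ε″ for when the real
  part is trusted.
* **ε∞ in loss-only mode.** ε∞ does not enter ε″, so it is not a fit
  parameter there; it is recovered afterwards from the high-frequency tail
  of ε′ (mean of the last three points minus the residual relaxation
  contribution), or held at its initial value when ε′ is absent.
* **Bounds.** 0 < a ≤ 1, 0 < b ≤ 1, Δε > 0, σ_dc ≥ 0, ε∞ ≥ 1 — physical
  admissibility for a passive dielectric.
* **Conductivity exponent** is fixed at 1 (pure dc conduction); no
  fractional-power term.
* **Parameterization.** τ_HN and σ_dc are fitted as log₁₀ values: both are
  scale parameters spanning many decades, and a linear σ_dc bounded in
  [0, 1] S/m stalls the trust-region solver when its magnitude is ~10⁻¹²
  of the bound width. σ ≤ 10⁻¹⁸ S/m is reported as exactly zero. The
  solver is least-squares (TRF) with ftol = xtol = gtol = 10⁻¹⁴.
* **Initialization.** From the interior loss maximum: τ_HN = 1/(2πf_peak)
  (Debye assumption), Δε = 2 × peak height, a = b = 0.8, σ_dc from half
  the lowest-frequency loss. The peak search smooths log ε″ with a 5-point
  moving average so 1%-level noise cannot plant spurious maxima, and
  rejects edge maxima (the conductivity upturn). A spectrum with no
  interior maximum raises an initialization error unless a start is
  supplied; a fitted relaxation whose peak contributes < 5% of the
  observed maximum loss is flagged `non-identifiable`.

**Peak-time convention.** The α-relaxation time is the inverse angular
frequency of the loss maximum, τ_α = τ_HN·[sin(πa/(2+2b))]^(−1/a)·
[sin(πab/(2+2b))]^(1/a). The exponent signs are validated against dense
numeric maximization of ε″(ω) over the full (a, b) grid (agreement to
0.1%, exact Cole–Davidson limit ω_max·τ = tan(π/(2b+2)) at a = 1). The
same expression circulates in the literature with the exponents swapped;
that variant is the reciprocal and places the peak on the wrong side of
τ_HN, so the numerically validated form is used.

## VFT analysis

τ_α(T) = τ∞·exp(B/(T − T0)) is fitted by least squares on log₁₀ τ with
unit weights (τ spans many decades; linear-time residuals would see only
the slowest points — the residual scale is a recorded choice). Fitting
requires ≥ 4 points spanning ≥ 2 decades in τ: three parameters plus a
degree of freedom, and a narrower span cannot separate B from T0. T0 is
bounded to (1 K, T_min); a fit ending on a bound (e.g. Arrhenius-like
data) is flagged `at-bound`, not rejected. The parameter covariance of
(log₁₀ τ∞, B, T0) is kept from the final Jacobian.

Tg = T(τ_α = 100 s) and isochronal temperatures T(τ_α = 1.5 ms) are the
closed-form inversion T0 + B/ln(τ/τ∞); both reference times are exposed as
parameters. Extrapolation below the fitted range is deliberate — Tg lies
below it by construction — and the extrapolation distance in kelvin is
available for reporting. The Tg uncertainty is first-order propagation of
the parameter covariance through the inversion.

## Gordon–Taylor modelling

Tg(w₂) = (W₁Tg₁ + K·W₂Tg₂)/(W₁ + K·W₂), component 1 the drug, component 2
the polymer, endpoints exact by construction. K may be taken as
ΔCp₂/ΔCp₁ from the pure-component heat-capacity steps, or fitted to
interior compositions by least squares in kelvin (unweighted), with the
pure-component Tgs held fixed — they are measured data, not parameters. A
single interior point is solved exactly. The inversion
w₂ = (Tg − Tg₁)/[(Tg − Tg₁) + K(Tg₂ − Tg)] is the exact algebraic inverse;
its sensitivity dw₂/dTg = K(Tg₂ − Tg₁)/denom² is always reported, because
closely spaced endpoint Tgs (a few kelvin) amplify Tg noise into large
composition uncertainty. No Fox, Couchman–Karasz or Kwei extensions.

## Crystallization detection and kinetics

* **Wide-band onset.** The fitted Δε(T) sequence is screened against a
  Langevin baseline Δε = A/T fitted over a growing pre-onset window;
  onset is the first temperature falling ≥ 10% (configurable) below the
  extrapolated baseline. The window stops growing at the first violation,
  so post-onset points never contaminate the baseline. The 10% default
  quantifies "a noticeable drop"; a threshold sweep (5–15%) moves the
  detected onset by at most one grid step on a sharp collapse.
* **Single-frequency onset.** A 1 kHz ε′(T) heating scan runs ε∞ → step up
  at the glass transition → slow decay → collapse. The detector estimates
  ε∞ from the initial glass plateau, searches only beyond the ε′ maximum
  (so the step-up cannot trigger), extrapolates a local linear baseline
  over a sliding window, and normalizes the shortfall by the remaining
  relaxation step (baseline − ε∞) — making the criterion "fraction of
  dielectric strength lost", commensurate with the wide-band detector.
* **No onset is a result**, not an error: stable samples simply report
  none.
* **Kinetics.** ε′_N(t) = (ε′(0) − ε′(t))/(ε′(0) − ε′(∞)); ε′(0) defaults
  to the mean of the first three points, ε′(∞) must be supplied when
  crystallization is incomplete (otherwise the final-plateau mean is
  used). Induction time = first crossing of ε′_N = 0.05; cessation = start
  of the terminal stretch where |dε′_N/dt| < 10⁻³ h⁻¹ on a trace smoothed
  over the plateau window (a pointwise gradient would let sample noise
  mask a real plateau; at noise above ~0.5% the slope tolerance needs
  coarsening); final_norm below 0.9 flags incomplete crystallization.
* **Residual composition.** Pipeline: α′ relaxation map of the
  post-crystallization cooling series → VFT → Tg → Gordon–Taylor
  inversion, with the Tg covariance propagated to a composition error bar.
  An out-of-range Tg raises with the distance reported, never clamps. A
  recovered drug fraction ≈ 0 is warned about: the α′ process is then
  indistinguishable from the neat polymer's segmental relaxation.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: HN +
conductivity spectra; τ_HN(T) on a VFT law; Δε(T) = A/T (Langevin), scaled
above the programmed onset by the surviving amorphous fraction; sigmoidal
ε′(t) during isothermal crystallization. The crystallized fraction uses a
stretched-exponential (Avrami-type) kernel X = x_max·(1 − e^(−k·Δx^n)) —
a generator choice recorded in every manifest; the detectors are
deliberately kernel-agnostic. x_max < 1 models incomplete crystallization
(a saturated amorphous phase survives). Noise is multiplicative Gaussian,
default 1% relative, applied last and independently to ε′ and ε″, because
loss values span decades and additive noise would swamp the wings. A
single integer seed drives per-spectrum substreams
(`SeedSequence(seed).spawn`), so regeneration is bit-exact, and every
dataset ships a JSON manifest (seed, grids, per-condition parameters)
sufficient to recompute it.

Two conventions matter when building end-to-end scenarios:

* `vft_for_tg` anchors a VFT law so that a chosen reference time is
  reached exactly at a target Tg; with a `shape` argument the anchor is
  placed on the loss-*peak* time rather than τ_HN, since the two differ by
  a fixed shape factor (≈ 0.575 for a = 0.8, b = 0.6) and Tg downstream is
  defined on the peak time.
* `generate_saturated_series` builds the post-crystallization α′ scenario
  from a mixing model and a true dissolved drug fraction, with the
  temperature grid spanning the measurable decades (τ_α between 10⁻⁴ and
  1 s by default, 15 temperatures).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: secondary relaxations overlapping the α peak,
electrode polarization at low frequency, temperature-dependent shape
exponents, non-Avrami or multi-stage crystallization, spatially
heterogeneous (surface vs bulk) crystallization, and any DSC observable.

## Problem sizes and defaults

Synthetic studies use frequency grids of 10–30 points/decade over
10⁻¹–10⁶ Hz (the span of a standard dielectric analyzer), temperature
ramps in 2 K steps, 15-point relaxation maps, 100-seed Monte-Carlo
repeats for recovery statistics, and 1% relative spectral noise — the
package's standard working conditions for validation. The end-to-end
solubility scenarios use dissolved drug fractions of 0.17, 0.10 and 0.06,
spanning the plasticized and antiplasticized mixing models; recovery
within ±0.02 weight fraction at 1% noise is the acceptance bar, limited by
the dw₂/dTg sensitivity when the endpoint Tgs sit only ~18 K apart.

## Known limitations

* One HN process per spectrum; overlapping β processes bias a, b.
* The loss-only ε∞ estimate assumes the sweep's high-frequency end is well
  past the loss peak.
* Cessation-time detection at the default slope tolerance assumes a
  low-noise normalized trace (≲ 0.5% of the relaxation step).
* The Gordon–Taylor inversion inherits the rule's assumptions (ideal
  volume additivity, no strong specific interactions); systems with Tg
  deviations from the rule will map Tg to composition with bias that the
  reported sensitivity does not capture.
* VFT covariance-based Tg uncertainties are first-order and understate
  errors for strongly correlated parameters on narrow maps.
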