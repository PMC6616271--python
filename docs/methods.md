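# Methods

## The measurement problem

Midday stem water potential (Ψ_stem, MPa, negative) is the most informative
single index of water status in anisohydric stone fruit, but it is a manual,
destructive spot measurement. Two continuous, organ-level proxies exist: the
fruit diameter FD from an LVDT dendrometer (mm) and the attenuated leaf-patch
pressure p_p from a leaf patch clamp pressure probe (kPa; inversely related
to leaf cell turgor). Neither organ alone is reliable — fruit growth is
stage-dependent and leaf turgor decouples from whole-tree status — so the
package quantifies their *joint* diel behaviour and calibrates it against
Ψ_stem.

## Signal model and processing choices

Both signals live on a 15-min grid. Processing order is smooth → standardise
(or smooth → rate-transform); the order is configurable but smoothing first
is the default, since the rate transform amplifies high-frequency noise.

* **Smoothing.** A centred least-squares polynomial convolution filter
  (Savitzky–Golay), window 15 samples (3 h 45 min), degree 3, per contiguous
  gap-free segment, with polynomial edge handling (`mode="interp"`). The
  window/degree pair preserves cubics exactly — hence sub-diel curvature —
  while attenuating sensor noise; both are recorded in the series history and
  configurable. Segments shorter than the window pass through with a warning
  flag rather than being extrapolated.
* **QC.** The median absolute 15-min step of the series sets the scale; a
  step larger than 10× that scale flags either a spike (immediately
  reversed; the middle point is flagged) or a displacement (persistent
  offset; the landing point is flagged — the shifted run itself is kept, as
  level shifts cancel in log-differences once the boundary interval is
  dropped). A series loses at most 5% of its points (configurable); beyond
  that it is rejected outright rather than silently thinned.
* **Standardisation.** z = (x − mean)/sd with the *sample* (n−1) standard
  deviation, over the full deployment window by default (per-day windows are
  an option). z-scores make sensors on different fruit/leaves comparable and
  averageable; they are idempotent under re-standardisation.
* **Rates.** RGR and RPCR are first log-differences per 15-min interval
  (multiply by 4 for per-hour). They are invariant under multiplicative
  rescaling of the source signal, equal the exact exponential growth rate for
  FD = A·e^{rt}, and are *not* standardised — the log-difference already
  removes sensor-specific scale.

## Windows and features

Diurnal is 07:00–19:45 (52 slots), nocturnal 20:00–06:45 of the next morning
(44 slots, anchored to the evening date); the diel window of a date is their
union (07:00 → 06:45, 96 slots), so the two sub-windows tile it exactly and
sums decompose. Per window: RSD = sd/|mean| (sample sd), max, min, sum,
mean. A window reports null features below 80% slot completeness
(configurable) — tolerant of the ≤5% QC exclusions without biasing RSD — and
RSD alone is null-flagged when |mean| < 1e-12 in the segment's units (a
ratio against an essentially zero mean is meaningless, not infinite).

RSD is dimensionless, allowing the fruit-to-leaf ratio RSD_RGR/RSD_RPCR to
combine organs with different native units. Note the instability this
inherits: when nocturnal growth stalls entirely (severe deficit), the
nocturnal mean RGR approaches zero and the per-day ratio becomes heavy-
tailed; the calibration therefore works on tree-week means.

## Hysteresis loops

The diel trajectory of RPCR (y) against RGR (x) at 15-min steps, closed
last-to-first, is quantified by the shoelace signed area; positive =
anticlockwise. The loop anchor is midnight-to-midnight by default
(07:00-anchored is an option). Self-intersecting trajectories receive the
algebraic shoelace value, documented as such. Fewer than three distinct
points → degenerate, area 0. Anticlockwise rotation arises when the leaf
signal leads the fruit signal, i.e. turgor loss precedes the fruit's
shrinkage response; loop area grows with deficit because both diel
amplitudes do.

## Model forms

* **Multilinear** Ψ_stem = b0 + b1·Ψ_leaf + b2·g_s + b3·VPD, ordinary least
  squares (statsmodels), with a rank check that names collinear columns.
  Leaf relative water content is intentionally not a predictor (it carries
  little independent signal on a daily scale).
* **Lorentzian peak** MAX_RGR = a/{1 + [(Ψ − c)/w]²}: nocturnal maximum
  fruit growth peaks at a mild deficit c (rehydration-driven expansion) and
  decays toward zero under severe deficit. Nonlinear least squares
  (Levenberg–Marquardt); initial values a = max(y), c = x at max(y),
  w = half the x range; the width is reported as its positive root since it
  enters squared.
* **Linear** MIN_RPCR = b0 + b1·Ψ_stem: the strongest instantaneous leaf
  rehydration rate scales directly with deficit.
* **Expo-linear** ratio = k0 + k1·e^{k2·Ψ} + k3·Ψ with k1 > 0 enforced by
  fitting log k1 (confidence intervals for k1 are exact transforms of the
  log-space intervals). Initialisation: OLS on the milder half of the Ψ
  range gives (k0, k3); a log-linear fit of the positive residuals on the
  severe half gives (log k1, k2). Convergence: 1e-10 on the sum of squares,
  1e-12 step tolerance. Linearised (Jacobian) covariances throughout, with
  t-based intervals on n − p degrees of freedom; Monte-Carlo checks in the
  test suite confirm 95% intervals cover truth at 93–97% across the three
  forms at realistic noise.

## Threshold and inversion

The water-deficit threshold is the Ψ_stem where the exponential component
k1·e^{k2·Ψ} equals a set fraction (default 1%) of |k0 + k3·Ψ| — the most
negative such crossing, found by a coarse scan plus Brent's method to
1e-6 MPa. The fraction is exposed as a parameter; the threshold is
continuous and strictly decreasing in it. A purely linear fit (k1 = 0)
yields a null threshold. Inversion of the fitted expo-linear curve maps an
observed nocturnal RSD ratio back to Ψ_stem over the calibration range
(default −3.6 to −0.8 MPa, where the curve is monotonic); out-of-range
ratios clamp to the nearer endpoint with a flag.

The threshold is an *extrapolated* quantity: it sits where the exponential
term is ~1% of the signal, roughly 1 MPa above the region where the data
constrain that term, so its sampling uncertainty is dominated by the decay
rate k2. For a single synthetic season (32 tree-week means at the default
noise) the delta-method standard deviation of the detected threshold is
≈0.24 MPa — estimates from one season should be read with that in mind, and
multi-season pooling is the intended use for tight thresholds.

## The synthetic generator

The generator's defaults describe one four-stage deficit-irrigation season
on a late-ripening nectarine orchard (southern hemisphere, 36.4° S, 113 m):

* **Stages** I/II/IIIa/IIIb spanning DAFB 27–62/63–112/113–141/142–172
  (36/50/29/31 days), with one 7-day sensor deployment per stage (starting
  DAFB 48/86/127/155) and one spot-curve day each.
* **Treatments** control/DI-40/DI-20/DI-0 with midday Ψ_stem targets falling
  from −0.8 to −1.5 MPa (control) and −1.2 to −3.5 MPa (DI-0) across the
  season; the two severest treatments converge late, when unwatered trees
  cannot fall much further. Tree-week Ψ_stem scatters around the target with
  sd 0.25 MPa, matching typical between-tree spread.
* **Fruit diameter**: a double-sigmoid seasonal trend (two logistic terms,
  stage-II plateau; asymptote ≈59 mm for controls, scaled down ~10% for
  DI-0) minus a diurnal shrinkage bell (amplitude 0.15 mm, growing 60%/MPa
  below a −1.0 MPa onset), with within-week growth stalled in proportion to
  deficit (flat at −3.5 MPa); AR(1) noise (ρ = 0.8, sd 0.01 mm) — sensor
  noise is strongly autocorrelated, and white noise would make smoothing
  unrealistically effective.
* **Leaf patch pressure**: baseline ≈120 kPa plus a noon turgor-loss bell
  (25 kPa, same deficit gain), *led* by 90 min relative to the fruit signal
  (the configured fruit–leaf lag; positive lag = leaf leads = anticlockwise
  loops); AR(1) noise sd 0.4 kPa.
* **Weather** at 10 min: sinusoidal seasonal/diel temperature, humidity
  inversely tracking it, clear-sky radiation with cloudy episodes, light
  wind, sporadic evening rain, optional multi-day logger gap. Daily means
  land in 0–4 kPa VPD and 1–10 mm ET0.
* **Spot physiology**: Ψ_stem diel curve from pre-dawn to a solar-noon
  minimum at the treatment target; Ψ_leaf = Ψ_stem − (0.05 + 0.25·VPD) plus
  leaf-to-leaf scatter (sd 0.08 MPa); g_s solved from the multilinear
  relation so the table satisfies it exactly, then Gaussian residual sd 0.24
  on observed Ψ_stem; RWC a bounded linear map of Ψ_leaf into 55–100%.
* **Calibration pairs**: per-day nocturnal RSD ratios drawn from a
  configured true expo-linear form (defaulting to the bundled reference
  parameters) plus day-to-day scatter sd 0.03 — the scale actually measured
  on the generator's own control-tree sensor output.

Everything derives from one integer seed via `SeedSequence` children keyed
by component (CRC-32 of the component name), so identical configurations are
byte-identical and per-series streams are order-independent.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about field data: mechanistic xylem/phloem/transpiration
flows (the deficit → amplitude link is a minimal linear mechanism);
weather-coupled sensor signals (sensor weeks use a fixed diel shape, not the
generated weather); a quantitative sensor-to-ratio calibration (the
calibration table is drawn from the expo-linear form directly, because
sensor-derived RSD ratios are intrinsically heavy-tailed under stalled
growth); soil water balance; sensor drift and attachment artefacts beyond
simple spikes/offsets.

## Degenerate inputs and numeric conventions

Non-positive FD or p_p values are QC-flagged (log undefined) and become rate
gaps; duplicate timestamps are errors, off-grid stamps snap within ±90 s;
flat series refuse standardisation; zero-variance series refuse correlation;
rank-deficient designs refuse OLS naming the offending columns. All
stochastic code paths take explicit seeds; reruns of the pipeline are
bit-for-bit reproducible.

## Problem sizes used by the test and acceptance harnesses

Noiseless round-trips use 40–60 point grids on Ψ ∈ [−3.6, −0.8] MPa;
Monte-Carlo coverage uses 200 replicates per model form (n = 80 for the
multilinear at residual sd 0.24, n = 40 at sd 0.01 for the peak, n = 60 at
sd 0.03 for the expo-linear); the end-to-end check runs the full default
season — 128 sensor weeks, ~86k sensor points — through the entire pipeline.
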