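# Methods

This note records the models behind `filotrack`, the parameter choices that
matter, what the synthetic data does and does not emulate, and the numerical
conventions a user should know before trusting (or extending) a result.

## Kinetic ground-truth model

A molecule is a continuous-time Markov chain over the states
`CYTO3D → MEM2D → {FILO_DIRECTED, FILO_STALLED, FILO_DIFFUSIVE} → TIP`,
integrated on a sub-step of one tenth of a frame interval (5 ms at 20
frames/s). Rates are converted to per-sub-step probabilities as
`1 − exp(−rate·dt)`; any rate implying a per-sub-step switching probability
above one is refused rather than silently aliased.

* **Cytosol.** Isotropic Brownian motion with per-axis step variance
  2·D_cyto·dt, reflected at the coverslip (z = 0) and at
  `cytosol_height_um`. Membrane binding at rate *f* applies only while the
  molecule is within one sub-step diffusion length √(2·D_cyto·dt) of the
  membrane plane. This capture-zone construction makes *f* an effective
  first-order rate: in a thin basal sheet (the geometry TIRF actually
  observes) the realized cytosolic dwell is 1/f, while in a tall cytosol the
  effective rebinding rate is diluted by the fraction of time spent outside
  the capture zone. The dwell-time tests therefore use a 0.2 µm sheet.
* **Membrane.** 2D diffusion at D_mem; detachment at rate *g*; entry into a
  filopodium only within `root_radius_um` of its root, at a configurable
  entry rate (5 s⁻¹ default — fast enough that root visits usually convert,
  slow enough to stay well-behaved on the sub-step).
* **Filopodium.** 1D dynamics in arc length along a polyline axis: directed
  episodes advance at v_directed (1.4 µm·s⁻¹), diffusive episodes use
  D_filo, stalled episodes hold position. The three states exchange at
  symmetric 1 s⁻¹ rates by default; only the directed speed and the
  resulting population fractions are constrained by measurement, so the
  switch rates are configuration, not claims. Transverse positions are drawn
  per sub-step from a Gaussian whose FWHM equals the shaft diameter
  (116.5 nm default), reflecting fast transverse equilibration.
* **Tip.** Reaching the end of the axis confines the molecule within one PSF
  width of the tip (soft trap with residual jitter), not a hard absorber.
  Whether tip-bound molecules re-enter the shaft is not established; an
  optional escape rate (default 0) leaves both behaviors available.
* **Bleaching.** A single exponential time per molecule; emission stops in
  one frame step.

## Camera model

Expected photons per molecule per frame:
`N(z) = photons_per_frame_at_z0 · exp(−z / evanescent_depth)` with the
evanescent depth defaulting to 100 nm. Photons are spread over pixels by an
error-function-integrated 2D Gaussian (σ = 150 nm, 100 nm pixels); motion
blur uses five sub-frame positions per exposure. Counts are
`offset + gain·Poisson(photons + background) + N(0, read_noise)`. The EMCCD
excess-noise factor is deliberately omitted; gain plus read noise reproduces
the tested SNR regime, and all precision statements below are calibrated
against this model, not against a full EM register simulation.

The default photon budget (180 photons/frame at z = 0, 15 background
photons/pixel) is chosen so a single in-focus fluorophore is localized with
≈30 nm precision — the regime in which the study's tracking operated. The
ACF-mapping simulations instead use a low flat background (2 photons/pixel),
because in the live-cell data the fluctuating background *is* the moving
molecules; a large static Poisson pedestal would only add white noise that
carries no mobility information.

## Detection and linking

Candidates are local maxima of the PSF-matched-filtered image. The threshold
is the larger of `snr_threshold` (default 4) matched-filter noise SDs and a
family-wise guard: the Gaussian quantile at which a whole frame of pure
noise yields on the order of 10⁻⁶ expected false maxima, set that far below
the nominal 10⁻³/frame target because the tail of smoothed shot noise is
measurably heavier than Gaussian. Candidates are refined by a 2D Gaussian
fit to a 7×7 window and rejected if the width leaves [0.5, 2]×σ_PSF, the
centre moves more than 2 px, or the amplitude is insignificant; saturated
windows are excluded; duplicates within one PSF FWHM are merged keeping the
brighter. Background is the frame median; noise is 1.4826×MAD.

Linking accepts track–spot pairs in order of increasing distance under a
0.5 µm/frame gate (≈4× the RMS step of D = 0.2 µm²·s⁻¹ motion at 20
frames/s), ties broken by lower spot index; each spot is used once, and a
partition assertion runs on every call. `max_gap` defaults to 0
(disappearance within one frame ends a track); gap closing is available and
the MSD computation is gap-aware when it is used.

## MSD analysis

Per-track, time-averaged MSD over all same-track pairs, lags up to a quarter
of the track's frame span; the curve includes MSD(0) = 0 by construction.
D_lat is slope/4 of an unweighted least-squares line through the origin over
the first `n_initial_points` curve points (default 4, i.e. three non-zero
lags — early enough to precede the confinement bend at the corral scales
seen in membrane data, late enough for a stable slope). The localization
noise floor (4σ²_loc, ≈0.0036 µm² at 30 nm) is *not* subtracted by default,
matching how initial-gradient D_lat values are usually quoted; pass
`noise_sigma_um` to remove it. Shape classification fits the anomalous
exponent α of MSD = 4D·dtᵅ in log–log space over at most the first ten
lags, weighted by √(pair count) — beyond ~10 % of the track the
time-averaged MSD is noise-dominated and only degrades the exponent.
Boundaries: α < 0.8 concave-down, α > 1.2 concave-up, else linear; these
thresholds are this package's convention. Objects with
D_lat < 0.02 µm²·s⁻¹ are excluded as stationary (the boundary value is
retained).

## Autocorrelation mobility mapping

Each pixel's mean-subtracted intensity series gives a normalized temporal
ACF (lags to a quarter of the record). For mapping, the zero-lag value —
which carries the white shot/read-noise spike — is replaced by the signal
variance linearly extrapolated from lags 1–2 before normalization (standard
image-correlation practice); pixels whose extrapolated signal variance is
below 12 % of the total variance are unresolved (never visited). τ is the
first 1/e crossing, linearly interpolated; an ACF that never crosses is
saturated at the maximum lag (immobile emitters decay only through
bleaching). A single-exponential fit is available as an alternative
estimator; the crossing rule is the default because the evanescent-field
convolution makes the ACF distinctly non-exponential. τ grids are averaged
over sliding 8×8 windows ignoring unresolved pixels; windows under 25 %
resolved are dropped.

τ→D conversion is empirical: movies of uniformly seeded in-plane diffusers
at 0.15 visible molecules/µm² (the single-molecule expression regime;
density is stored in the calibration because τ is density-sensitive) are run
through the identical pipeline across a D grid of 0.02–2 µm²·s⁻¹, the mean
τ per D is made monotone by decreasing isotonic regression, and the table is
inverted by interpolation. A movie is reduced to the *median* window τ, and
maps are summarised by median mapped D — the window-τ distribution is
right-skewed by windows a molecule lingered in, and the same statistic must
be used on both sides of the calibration. Bleaching at the configured rate
is included in calibration movies so its τ bias cancels. Mapped values at or
above 2 µm²·s⁻¹ are reported as saturated, never as numbers; the
pseudo-color overlay runs red (0) to magenta (≥2).

Round-trip accuracy (median mapped D within ±25 % at 0.05, 0.2 and
1.0 µm²·s⁻¹) is verified on independently seeded movies; the benchmark uses
a 96×96 px field, 400-frame records at 50 frames/s, a 7-point calibration
grid with 4 replicate movies per point, and the median over 3 test movies
per D — sizes chosen to hold the estimator noise comfortably inside that
band on a single CPU.

## Filopodial kinetics

Filopodia are splines through control points; straightening samples a
5-pixel perpendicular stripe at pixel pitch with bilinear interpolation, and
kymographs stack the stripe-averaged profiles with the tip row on top.
Streak velocity is a total-least-squares line through per-column
intensity-weighted centroids taken within a PSF-sized window around each
column's peak (a whole-column centroid is dragged toward mid-shaft by
residual background). Segments are rejected when the peak SNR is below 2 or
when the centroids scatter off the fitted line by more than 10 % of the
position span — noise maxima exceed any fixed threshold somewhere in a
large segment, but they do not line up.

Instantaneous velocities are least-squares slopes of arc length vs time in a
sliding 10-frame window (500 ms at 50-ms frames) — a regression slope, not
an endpoint difference, for robustness to localization noise; samples
projecting farther than shaft radius + 2σ_PSF off the axis are dropped, and
reversing the path's tip end negates all velocities exactly. Velocity
histograms (0.1 µm·s⁻¹ bins, counts) are fitted with a sum of two Gaussians
from five deterministic restarts (directed-component mean seeded at upper
sample quantiles), best SSE kept; the component nearer zero is labelled 1.
The directed percentage comes from the fitted component weights (A·σ
products), also expressed as a count n_V2 = round(weight·n). A second
component is kept only when it improves on a single Gaussian by an F-test at
p < 0.01 and carries at least 1 % of the weight; otherwise the fit falls
back to one component with the directed mean undefined — the behavior free
fluorophore controls show. On the heavily overlapping mixture used in the
benchmarks this fallback fires in roughly 1 in 50 replicates, which is
reported rather than suppressed. Construct comparisons use a one-tailed
Welch t-test with n reduced to the moving fraction (n_total·pctV2); Welch
rather than pooled variance is the conservative choice, and comparisons with
effective n < 3 are refused.

## Super-resolution rendering

Localizations accumulate additively on a 16× canvas (pitch exactly
100/16 = 6.25 nm, displayed "~6.3 nm" by half-up rounding) as Gaussians with
amplitude c_A·I and σ = c_σ/√I, clamped to [one canvas pixel, 100 nm] —
brighter spots are localized better and drawn sharper. The constants are
anchored to the data: a median-intensity spot renders at σ = 30 nm (the
nominal single-fluorophore precision) with unit amplitude. Total mass per
spot is amplitude·2πσ², and accumulation is order-independent.

Transverse profiles sample perpendicular to the straightened axis and
average along a segment; FWHM comes from a Gaussian fit weighted shot-noise
style (σ_i ∝ √signal) — unweighted least squares lets the many empty tail
bins inflate the width by several nanometres on unlucky draws. Profiles with
two peaks separated by more than half the overall half-max width are flagged
bimodal and measured per peak. For the diffraction-limited channel the
measurement chain itself widens the profile: camera-pixel integration adds
a²/12 and the bilinear 16× expansion of the averaged image adds a²/6 of
variance (a = 100 nm); `psf_sigma_for_measured_width` accounts for both when
choosing a PSF that should *measure* at a target width.

## Search model

Closed forms: f = c·k_on (nM converted to molar), t_mem = 1/g, t_cyto = 1/f,
explored membrane area A = D_mem/g, cytosolic excursion length
ℓ = √(D_cyto/f), run survival 100·exp(−d/λ) for exponential run lengths
(the standard assumption for processive motors). The area and length
prefactors (1 by default; 2 and 4 selectable) are a documented choice: the
forms above reproduce the published worked value of ~2 µm² and make ℓ equal
to the membrane patch scale √A at the measured parameters. The Monte-Carlo
check simulates the alternating episodes directly; the D·t estimator of
per-visit area has expectation D_mem/g, the convex-hull estimator
π·D_mem/g, and the squared cytosolic excursion 6·D_cyto/f — all verified to
3 SE.

## What the synthetic data does not capture

The simulator emulates sparse single-fluorophore imaging with the study's
optics and kinetics. It does not model: EMCCD excess noise (precision
claims would degrade by ~√2 with it), fluorophore blinking, filopodial
growth/retraction or bending during acquisition, cargo binding, anomalous
membrane sub-diffusion beyond simple confinement, cell-shaped membrane
masks beyond a rectangular footprint, or stage drift. Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every artifact of real recordings. Track-level recovery in
dense rendered movies is recall-limited by motion blur at 50-ms exposures —
which is precisely why the fast cytosolic pool is analysed by pixel
autocorrelation rather than tracking.

## Problem sizes

Benchmarks run on one CPU in about a minute total: 200 tracks × 100 frames
for D_lat; 20 rendered runs of 50 frames for kymograph velocimetry; 50
mixture replicates of n = 425; 10⁴ localizations for the confinement width;
and the mobility-map round trip described above.
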