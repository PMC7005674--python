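# Methods

This note documents the models, estimators and numerical choices behind
`smtirfkit`, what the synthetic-data generator does and does not emulate, and
the limits of what the test suite can establish about real data.

## Binding model and dwell-time kinetics

A surface-immobilized site alternates between unbound and bound states.
Search (dark) times are exponential with rate `on_rate` (mean τ_on); each
binding event draws a mixture mode `i` with probability `A_i` and a bound
dwell Exp(τ_off,i). Components with τ_off > 1 s are classified *specific* —
the boundary is the conventional one for distinguishing site-specific
engagement from nonspecific sampling (sub-second) and is configurable.

Dwell statistics are summarized by the empirical survival function
S(t) = P(T ≥ t) evaluated at each observed duration (unbinned). Fitting uses
bounded nonlinear least squares (`scipy.optimize.least_squares`) on
S(t) = Σ A_i exp(−t/τ_i) with 20 log-spaced initializations of the time
constants spread over the observed range; multi-exponential objectives are
multimodal and the multi-start is what makes the noise-free oracle recovery
exact (≈1e-12 relative). Amplitudes are fitted free (≥ 0) and normalized to
sum to 1 afterwards — the survival curve's S(0) = 1 anchors the scale, and
this matches how amplitude percentages are conventionally reported. Time
constants are bounded to [half the shortest observed dwell, 10× the longest];
a fit touching a bound is flagged.

**Model selection.** The number of components (1–3) is chosen by BIC computed
from the *dwell-sample log-likelihood* under the fitted mixture density
f(t) = Σ (A_i/τ_i) exp(−t/τ_i), not from the survival-curve residual sum of
squares: survival points are order statistics of the same sample, so an
RSS-based criterion double-counts observations and systematically prefers
over-parametrized fits. A `force_n` override reproduces fixed per-substrate
choices (2 components for free DNA, 3 for nucleosomes and chromatin fibers).

**On-rates.** Dark-time survival is fitted mono-exponentially; we define
k_on,app ≡ 1/τ_on (fitting y = A·exp(−t/τ_on); writing the rate constant
itself in the exponent would be dimensionally inconsistent). Because the
detected event stream mixes specific and nonspecific interactions, the
specific on-rate is the apparent rate scaled by the amplitude share of
specific components: k_on,specific = k_on,app · ΣA_specific / ΣA_all.

**Censoring.** First/last intervals of each trace are truncated by the
observation window and excluded from survival curves; the censored fraction
is reported so that heavily truncated datasets (>10% censored) can be flagged
rather than silently biased.

**Photobleaching.** Immobilized-dye controls at ≥ 2 excitation powers give an
apparent off-rate that is pure bleaching; regressing it on power through the
origin yields the bleach sensitivity. The optional dwell correction
1/τ_true = 1/τ_obs − b·duty is **off by default**: residence times are
reported uncorrected, with the control quantifying the bias.

## Image processing

- **Background**: rolling-ball subtraction (radius 50 px default). For radii
  ≥ 16 px the image is shrunk by local averaging, the ball rolled on the
  reduced image and the background upscaled bilinearly — the downsampling
  strategy the standard ImageJ implementation uses, which keeps per-frame
  subtraction tractable on multi-thousand-frame movies (~6 ms vs ~0.3 s per
  128² frame) while preserving spot integrals to well within 5%.
- **Detection**: 8-neighborhood local maxima above mean + 5σ (configurable),
  each refined by a symmetric 2D Gaussian least-squares fit; degenerate fits
  (flat patch, non-positive amplitude, implausible width) are dropped. Spots
  wider than 1.5× a single-dye reference width are excluded as aggregates;
  the cutoff is configurable because the reference is an instrument property.
- **Drift**: whole-frame cross-correlation against frame 0 with 1/50-px
  upsampled peak interpolation. Plain (not phase-whitened) correlation is
  used: phase normalization whitens the spectrum and is noticeably noisier on
  sparse spot images with Poisson noise.
- **Registration**: least-squares affine (6 dof) on ≥ 3 non-collinear
  fiducial pairs; with ~10 well-spread beads the linear part is determined to
  ~1e-3 while the translation terms carry the full localization noise.
  Projective terms are unnecessary at this residual level.
- **Colocalization**: binder detections are assigned to the nearest locator
  within 2 px (the printed radius); exact ties resolve to the lowest locator
  index for determinism. Coordinates are 0-based pixel-center floats.

## Trace analysis

Traces are **sums** over a 2-px disk (sums preserve photon count; means would
only rescale). Denoising uses a forward–backward nonlinear filter: forward
predictors (means of the preceding k samples) and backward predictors (means
of the following k) are combined with weights ∝ (windowed squared prediction
error)^(−p), p = 10. Windows are (2, 4, 8) frames with a 2-frame error
window: the 2-frame predictor is required for 3–6-frame events — with a
minimum window of 4, every predictor straddles an edge inside a 4-frame event
and the filter suppresses it entirely. The backward predictor's weight is
judged on *future* errors (mirror of the forward case); this is what makes
noiseless steps pass through exactly. The cost of the short window is a
plateau-noise reduction of ~2.2× rather than ~3× at noise SD = half the step
height; at realistic trace SNR the segmentation is threshold-limited, not
smoothing-limited.

**Event segmentation.** Threshold default: background mean + 4 background SD,
with a 1 SD hysteresis band. The background class is identified by Otsu's
two-class split (robust even when a molecule is bound most of the movie,
where lower-quantile background estimates fail). Event amplitude is the
plateau level (interior median for runs ≥ 3 frames; edge frames are dimmed by
partial overlap with the integration window). Runs whose amplitude exceeds
1.7× the median single-event amplitude are counted as overlapping
multi-molecule events and excluded from dwell statistics. Dwells are
n_frames × (t_on + t_off): stroboscopic gaps count toward the dwell, which is
what lets second-scale frames measure minute-scale residence times.

## Stroboscopic illumination and bleaching

The camera integrates for t_on and sleeps for t_off each frame; a binding
event is visible in a frame iff it overlaps the t_on window, with partial
overlap dimming the spot proportionally. The bleaching clock advances only
during t_on — duty-cycling is precisely the measure that slows bleaching
during long dwells — so a dye with bleach rate b at duty cycle d has apparent
dwell 1/(1/τ + b·d), which the generator reproduces and the control-analysis
recovers. The dye's bleach rate at measurement power is not a published
constant; it is a free generator parameter (default 0).

## smFRET

**Trace generation.** Conformational states are a continuous-time Markov
chain; state `s` with efficiency E_s and photon budget I_s emits
F_D = I_s(1−E_s) in the donor channel and F_A = γ·I_s·E_s + β·F_D in the
acceptor channel (sensitized emission scaled by the detection-efficiency
ratio γ, plus bleed-through β). Acceptor bleach reroutes all energy to the
donor (F_D = I_s, F_A = β·F_D); donor bleach zeroes both. Bleach times are
exponential in illuminated time.

**Calibration.** β is the post-acceptor-bleach F_A/F_D ratio. γ is the ratio
of the *bleed-through-corrected* acceptor drop to the donor rise across the
bleach, Δ(F_A − β̂F_D)/ΔF_D: with the standard bleed-through model the raw
ΔF_A/ΔF_D equals γ−β, not γ, so correcting with the per-trace β̂ first is
required for the round trip through the efficiency formula
E = (F_A − βF_D)/((F_A − βF_D) + γF_D) to be exact (and it is exact on
noiseless traces, to 1e-9). Per-trace estimates are aggregated by median.

**Bleach-step detection** is recursive two-piece-constant change-point
fitting (depth 4), a step being significant at 4× the robust point noise
(median absolute successive difference / √2), floored at 0.1% of the dynamic
range so noiseless traces do not split on rounding-level shifts. Steps within
one minimum segment (5 frames) merge, keeping the largest — partial-overlap
frames at a bleach otherwise spawn satellite steps. A dye bleach marks *both*
channels (donor bleach removes its bleed-through from the acceptor channel;
acceptor bleach raises the donor), so coincident cross-channel steps are
paired into one per-dye event; unexplained steps (recoveries = blinking,
double drops) mark the trace anomalous and fail selection criterion (i).

**Selection criteria** (each recorded per trace): (i) a single bleach event
per dye, no anomalies; (ii) total emission F_D + F_A/γ above 2000 counts and
"constant", operationalized as coefficient of variation < 20% pre-bleach (no
printed tolerance exists); (iii) ≥ 2 s baseline after donor bleach; (iv)
≥ 5 s of donor emission; (v) acceptor presence — an acceptor bleach while the
donor is alive, or a direct-excitation flag supplied with the trace.
Pre-filters reject clustered spots and traces exceeding 8000 (donor) / 5000
(acceptor) counts, which indicate aggregates.

**Histograms and populations.** Pre-bleach valid E samples are histogrammed
at 0.02 bins over [−0.2, 1.2] (noise excursions are kept, not clamped);
each trace's histogram is normalized to unit mass so traces contribute
equally regardless of length, then averaged. The mean histogram is fitted
with three Gaussians (lmfit; centers kept ordered via positive offsets,
initialized at 0.05/0.30/0.50 with σ = 0.05 — the canonical anatomy of the
defective / open / compact populations; widths independent per dataset).
Areas are analytic (A·σ·√(2π)); population percentages are area shares,
classed LF (c < 0.2), MF (0.2 ≤ c ≤ 0.4), HF (c > 0.4). Under compaction
conditions an LF share ≥ 50% fails the preparation QC gate (strict
inequality, as printed).

## Dynamics classification

C_{D−A}(t) is the mean-subtracted donor–acceptor cross-covariance normalized
by √(Var F_D · Var F_A), so C(0) is the Pearson correlation. Normalizing by
the zero-lag cross term itself would force C(0) = +1 for every trace and
destroy the sign that the negative-amplitude criterion depends on; the
variance normalization is the only reading consistent with that criterion.
Lags are capped at min(5 s, trace/4).

The curve (lags > 0; the lag-0 point carries the full uncorrelated shot-noise
variance) is fitted with C(t) = a₁e^(−t/θ₁) + a₂e^(−t/θ₂); amplitude is the
t→0 extrapolation a₁+a₂, relaxation the amplitude-weighted mean θ (the
weighted mean, rather than the slow θ alone, degrades gracefully when the fit
splits one true component in two; configurable). Time constants are bounded
below by one frame period — sub-frame components are unresolvable and the
bound caps the extrapolation factor at e — and components carrying < 10% of
the total |amplitude| are excluded from the relaxation average (they are
degenerate fit chasers with θ at the bounds and otherwise inflate the
relaxation severalfold). A trace is *dynamic* iff it lasts > 10 s, spends
> 20% of its time at E > 0.2, and the fit gives amplitude < −0.1 with
relaxation > 100 ms.

**Statistical power.** The per-lag noise of Ĉ is ≈ 1/√n for n frames, and
the t→0 extrapolation inflates the amplitude estimate by up to e. At the
full movie length used for chromatin smFRET (1991 frames ≈ 200 s) the static
amplitude scatter is ≈ 0.06, comfortably below the −0.1 threshold (measured
specificity ≈ 97%, sensitivity 100% at 300 ms exchange). For traces of only
10–30 s the scatter reaches 0.1–0.2 and the printed threshold cannot deliver
high specificity for *any* estimator honoring the amplitude definition — the
classifier is meant for long traces, and the benchmarks here use the full
movie length.

## Synthetic-data generator: what it does and does not emulate

Emulated: immobilized diffraction-limited spots at 160 nm/px; exponential
mixture dwell processes; duty-cycled illumination with shutter-gated
bleaching; Gaussian PSFs with Poisson shot noise and Gaussian read noise
(default 10 counts, EMCCD-like); anti-correlated two-channel FRET traces with
single-step bleaching; per-molecule independent random streams from one seed
(bit-identical regeneration).

Not emulated: molecular diffusion, evanescent-field depth, polarization,
dye blinking beyond step events, EMCCD gain register statistics, non-affine
chromatic distortion, background structure beyond a constant level. Passing
tests therefore certify the *estimators* — that the pipeline recovers known
kinetic and conformational parameters from data with the assumed statistical
structure — not robustness to every instrumental artifact of real movies.

Default study regimes: the free-DNA site with A = (0.35, 0.65),
τ_off = (12.4, 452) s under 100/600 ms stroboscopic timing, and a
mononucleosome-like regime A = (0.40, 0.35, 0.25), τ_off = (0.3, 3, 12) s,
τ_on = 10 s under 100/0.3 ms timing — a sub-second nonspecific mode plus
specific modes an order of magnitude shorter-lived than on free DNA.
Calibration truth defaults: γ = 0.423, β = 0.073.

## Problem sizes and tolerances

The validation suite runs: 50 × 5000-dwell Monte-Carlo refits of the
two-component regime (τ within 15%, A within 0.05 in ≥ 95% of runs); one
full 50-molecule, 2000-frame, 128² movie through the entire pipeline
(specific τ and k_on,specific within 20% — the dominant residual is the
physical detection limit for sub-frame nonspecific events, which biases
k_on,app low by ~10% before the amplitude correction); β/γ medians within 5%
over 20 noisy traces (exact on noiseless ones); Gaussian decomposition of
known three-component histograms (centers within 0.01, shares within 3
points); and 30 + 30 labeled dynamic/static traces at 1991 frames
(sensitivity and specificity ≥ 90%). These sizes keep the suite within a few
minutes on one CPU while leaving comfortable statistical margins.

## Known limitations

- Dwells shorter than the camera integration window are detected only via
  partial-frame brightness and are under-counted; dark gaps shorter than one
  frame merge adjacent events. Both are physical resolution limits.
- Survival-curve least squares is not interval-censored maximum likelihood;
  censored events are excluded rather than modeled.
- The multi-molecule exclusion (amplitude > 1.7× the median event) assumes
  most events on a trace are single molecules.
- β/γ calibration needs acceptor-before-donor bleaching; traces where the
  donor dies first contribute nothing.
- The three-Gaussian fit assumes exactly three populations; histograms that
  are genuinely uni- or bimodal return a collapsed or near-zero component
  (flagged) rather than a reduced model.
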