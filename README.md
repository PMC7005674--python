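# smtirfkit

Analysis toolkit for two-channel single-molecule TIRF experiments on
transcription-factor/chromatin binding: extraction of binding kinetics from
colocalization movies, and chromatin-conformation analysis from smFRET traces.
A seeded synthetic-data generator with full ground truth makes every stage of
the pipeline testable end to end.

## What it computes

**Colocalization kinetics.** A far-red "locator" channel marks immobilized DNA,
nucleosomes or chromatin fibers; a second channel reports transient binding of a
labeled factor (e.g. the yeast pioneer factor Rap1). The pipeline performs
rolling-ball background subtraction, local-maxima spot detection with 2D
Gaussian PSF refinement, phase-correlation drift correction, and extraction of
per-molecule intensity traces within a 2-pixel radius of each locator position.
Traces are denoised with a forward–backward nonlinear (Chung–Kennedy style)
filter and segmented into bright/dark dwells by thresholding. Pooled bright
dwells `t_bright` form a survival curve fitted with an exponential mixture

    S(t) = Σᵢ Aᵢ exp(−t / τ_off,i),    Σᵢ Aᵢ = 1,

whose components are classified *specific* (τ > 1 s) or *nonspecific*. Dark
times give the apparent on-rate `k_on,app = 1/τ_on` (mono-exponential fit),
corrected to the specific on-rate by the amplitude share of specific events:

    k_on,specific = k_on,app · (Σ_specific Aᵢ) / (Σ_all Aᵢ).

**smFRET conformation analysis.** Donor/acceptor traces are calibrated from
acceptor-bleaching steps (bleed-through β from the post-bleach ratio, detection
efficiency γ from the corrected intensity jumps), converted to FRET efficiency

    E = (F_A − βF_D) / ((F_A − βF_D) + γF_D),

filtered by five selection criteria (single bleaching event, constant total
emission > 2000 counts, ≥ 2 s post-bleach baseline, ≥ 5 s donor emission,
acceptor present), histogrammed at 0.02 bins with per-trace normalization, and
decomposed into three Gaussian sub-populations — low (c < 0.2), medium
(0.2 ≤ c ≤ 0.4) and high FRET (c > 0.4) — with analytic areas A·σ·√(2π).
Preparations with ≥ 50% LF under compaction conditions fail QC. Conformational
dynamics are detected by donor–acceptor cross-correlation: a trace is *dynamic*
when the bi-exponential fit of C_{D−A}(t) has amplitude < −0.1 and relaxation
time > 100 ms.

**Synthetic data.** `smtirfkit.simkit` generates continuous-time binding
timelines (exponential-mixture dwells, duty-cycled stroboscopic illumination,
photobleaching that accrues only while the shutter is open), anti-correlated
FRET traces with single-step bleaching, and rendered two-channel TIFF movies
with Gaussian PSFs, Poisson shot noise and read noise — all bit-reproducible
from one seed, with ground-truth sidecars.

## Worked example

```python
import numpy as np
from smtirfkit.simkit import (MONONUCLEOSOME_BINDING, IlluminationScheme,
                              OpticsModel, PhotophysicsModel,
                              random_positions, render_movie,
                              simulate_binding_timeline)
from smtirfkit.pipeline import analyze_binding_movie

binding = MONONUCLEOSOME_BINDING          # A=(0.40,0.35,0.25), τ=(0.3,3,12) s
illum = IlluminationScheme(t_on_ms=100, t_off_ms=0.3, n_frames=2000)
optics = OpticsModel(image_size=(128, 128), background_level=100, read_noise_sd=10)

streams = np.random.SeedSequence(1).spawn(51)
timelines = [simulate_binding_timeline(binding, PhotophysicsModel(), illum,
                                       seed=np.random.default_rng(s))
             for s in streams[:50]]
positions = random_positions(50, optics.image_size, margin=8, min_separation=8,
                             rng=np.random.default_rng(streams[50]))
movie = render_movie(timelines, optics, illum, positions=positions,
                     seed=np.random.default_rng(streams[50]))

result = analyze_binding_movie(movie, n_components=3)
for c in result.bright_fit.components:
    print(f"A={c.amplitude:.2f}  tau_off={c.tau:5.2f} s  ({c.kind})")
print(f"k_on,app      = {result.on_rate.k_on_app:.3f} /s")
print(f"k_on,specific = {result.on_rate.k_on_specific:.3f} /s")
```

Output (seed 1):

```
A=0.31  tau_off= 0.27 s  (nonspecific)
A=0.51  tau_off= 2.80 s  (specific)
A=0.19  tau_off=17.70 s  (specific)
k_on,app      = 0.091 /s
k_on,specific = 0.063 /s
```

The generator's truth is A = (0.40, 0.35, 0.25), τ = (0.3, 3, 12) s with
`k_on,app` = 0.1/s and `k_on,specific` = 0.06/s: the amplitude-weighted
specific residence time (6.8 s vs 6.75 s true) and the specific on-rate are
recovered within a few percent; the nonspecific amplitude is slightly
underestimated because sub-frame events fall below the detection limit —
exactly the bias the amplitude correction of `k_on` compensates.

A `smtirfkit` CLI wraps the same stages (`simulate`, `detect`, `traces`,
`kinetics`, `fret`, `dynamics`); see `smtirfkit --help`.

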