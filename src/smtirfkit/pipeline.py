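"""End-to-end orchestration: movie -> spots -> traces -> dwell kinetics.

Glue around the stage modules for the common case of a two-channel
colocalization movie: background-subtract, detect locator positions, correct
drift, extract and filter binder traces at the locator positions, segment
events, pool dwell times and fit the exponential mixture and on-rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import imaging, kinetics, tracekit
from .simkit import IlluminationScheme, MovieStack

__all__ = ["BindingAnalysisResult", "analyze_binding_movie"]


@dataclass
class BindingAnalysisResult:
    positions: np.ndarray
    event_lists: dict[int, tracekit.EventList]
    bright_fit: kinetics.ExpMixtureFit
    on_rate: kinetics.OnRateEstimate
    n_bright_events: int
    n_dark_events: int
    censored_fraction: float


def analyze_binding_movie(
    movie: MovieStack | tuple[np.ndarray, np.ndarray],
    illum: IlluminationScheme | None = None,
    n_components: int | None = None,
    threshold_sigma: float = 5.0,
    ball_radius: float = 50.0,
    radius_px: float = 2.0,
    correct_drift: bool = True,
    subtract_binder_background: bool = True,
    specific_threshold_s: float = kinetics.SPECIFIC_TAU_THRESHOLD_S,
) -> BindingAnalysisResult:
    """Run the full colocalization-kinetics pipeline on a two-channel movie.

    Locator positions are detected on the background-subtracted mean of the
    far-red channel (immobilized molecules are present in every frame, so
    averaging boosts their SNR); stage drift is estimated from the locator
    channel and applied to the binder channel; binder traces are extracted
    within ``radius_px`` of each locator position, nonlinearly filtered and
    thresholded into events; pooled bright dwells are fitted with an
    exponential mixture (BIC-selected unless ``n_components`` forces a
    choice) and pooled dark dwells with a mono-exponential for the on-rate.
    """
    if isinstance(movie, MovieStack):
        locator, binder = movie.locator, movie.binder
        illum = illum or movie.illum
    else:
        locator, binder = movie
    if illum is None:
        raise ValueError("an IlluminationScheme is required")

    if correct_drift:
        drift = imaging.estimate_drift(locator, upsample_factor=20)
        locator = imaging.apply_drift(locator, drift)
        binder = imaging.apply_drift(binder, drift)

    mean_locator = imaging.subtract_background(locator.mean(axis=0), ball_radius)
    spots = imaging.detect_spots(mean_locator, threshold_sigma=threshold_sigma)
    positions = np.array([[s.y, s.x] for s in spots])
    if len(positions) == 0:
        raise ValueError("no locator spots detected")

    if subtract_binder_background:
        binder = imaging.subtract_background_stack(binder, ball_radius)

    event_lists: dict[int, tracekit.EventList] = {}
    for i, pos in enumerate(positions):
        tr = tracekit.extract_trace(binder, tuple(pos), illum, radius_px=radius_px, molecule_id=i)
        if tr.edge_flagged:
            continue
        tracekit.nonlinear_filter(tr)
        event_lists[i] = tracekit.threshold_events(tr)

    bright = np.concatenate(
        [el.bright_durations() for el in event_lists.values()] or [np.array([])]
    )
    bright_censored = np.zeros(len(bright), dtype=bool)  # censored already excluded
    dark = np.concatenate([el.dark_durations() for el in event_lists.values()] or [np.array([])])
    n_all_bright = sum(
        len(el.bright_durations(include_censored=True, include_excluded=True))
        for el in event_lists.values()
    )
    cens_frac = 1.0 - len(bright) / n_all_bright if n_all_bright else 0.0

    curve = kinetics.build_survival(bright, bright_censored)
    if n_components is None:
        n_sel, fits = kinetics.select_model(curve, specific_threshold_s=specific_threshold_s)
        fit = fits[n_sel]
    else:
        fit = kinetics.fit_exponentials(curve, n_components, specific_threshold_s=specific_threshold_s)
    dark_curve = kinetics.build_survival(dark)
    on = kinetics.fit_on_rate(dark_curve)
    on.k_on_specific = kinetics.correct_on_rate(on.k_on_app, fit)
    on.amplitude_fractions = {c.kind: c.amplitude for c in fit.components}
    return BindingAnalysisResult(
        positions=positions,
        event_lists=event_lists,
        bright_fit=fit,
        on_rate=on,
        n_bright_events=len(bright),
        n_dark_events=len(dark),
        censored_fraction=cens_frac,
    )
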