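"""Donor-acceptor cross-correlation and dynamic-trace classification.

Conformational exchange between FRET states produces anti-correlated donor
and acceptor fluctuations; the normalized cross-correlation

    C_{D-A}(t) = <dF_D(0) dF_A(t)> / sqrt(Var(F_D) Var(F_A))

is negative at short lags for dynamic traces and decays with the exchange
relaxation time.  C(0) is the Pearson correlation of the two channels, so a
strongly negative amplitude is meaningful; normalizing instead by the zero-lag
cross term would fix C(0) at +1 and destroy the sign, hence the variance
normalization used here.  Traces are classified dynamic when a bi-exponential
fit gives amplitude < -0.1 and relaxation time > 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CrossCorrelationCurve",
    "DynamicsClassification",
    "cross_correlate",
    "classify_dynamic",
    "fraction_dynamic",
    "AMPLITUDE_THRESHOLD",
    "RELAXATION_THRESHOLD_S",
]

#: Classification thresholds: amplitude below -0.1, relaxation above 100 ms.
AMPLITUDE_THRESHOLD = -0.1
RELAXATION_THRESHOLD_S = 0.1


@dataclass
class CrossCorrelationCurve:
    lags: np.ndarray  # s, starting at 0
    values: np.ndarray
    n_frames: int
    frame_period: float

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must match")


@dataclass
class DynamicsClassification:
    amplitude: float
    relaxation_s: float
    included: bool
    is_dynamic: bool
    indeterminate: bool = False
    theta_fast_s: float = np.nan
    theta_slow_s: float = np.nan


def cross_correlate(
    f_d: np.ndarray,
    f_a: np.ndarray,
    frame_period: float,
    max_lag_s: float = 5.0,
) -> CrossCorrelationCurve:
    """Mean-subtracted donor-acceptor cross-correlation.

    Only pre-bleach segments should be passed in.  Lags are capped at a
    quarter of the trace (the estimator variance blows up beyond that).
    """
    f_d = np.asarray(f_d, dtype=float)
    f_a = np.asarray(f_a, dtype=float)
    n = len(f_d)
    if len(f_a) != n:
        raise ValueError("channels must have equal length")
    var_d, var_a = f_d.var(), f_a.var()
    if var_d == 0 or var_a == 0:
        raise ValueError("zero variance in a channel")
    dd = f_d - f_d.mean()
    da = f_a - f_a.mean()
    max_lag = min(int(round(max_lag_s / frame_period)), n // 4)
    norm = np.sqrt(var_d * var_a)
    lags = np.arange(max_lag + 1)
    vals = np.array([np.mean(dd[: n - k] * da[k:]) for k in lags]) / norm
    return CrossCorrelationCurve(
        lags=lags * frame_period, values=vals, n_frames=n, frame_period=frame_period
    )


def _biexp_fit(lags: np.ndarray, values: np.ndarray, frame_period: float, max_lag_s: float):
    """Fit C(t) = a1 exp(-t/th1) + a2 exp(-t/th2) on lags > 0."""

    def residual(p):
        a1, a2, lth1, lth2 = p
        th1, th2 = np.exp(lth1), np.exp(lth2)
        return a1 * np.exp(-lags / th1) + a2 * np.exp(-lags / th2) - values

    c1 = values[0]
    # components faster than one frame are unresolvable; bounding theta at the
    # frame period also caps the t->0 extrapolation factor at e
    lo = np.log(frame_period)
    hi = np.log(10 * max_lag_s)
    best = None
    for lth1, lth2 in ((np.log(2 * frame_period), np.log(max_lag_s / 2)),
                       (np.log(5 * frame_period), np.log(max_lag_s)),
                       (np.log(frame_period), np.log(10 * frame_period))):
        p0 = [c1 / 2, c1 / 2, lth1, lth2]
        try:
            sol = least_squares(
                residual, p0, bounds=([-2, -2, lo, lo], [2, 2, hi, hi]), method="trf"
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return None
    a1, a2, lth1, lth2 = best[1].x
    return a1, a2, float(np.exp(lth1)), float(np.exp(lth2))


def classify_dynamic(
    curve: CrossCorrelationCurve,
    duration_s: float,
    fraction_above_e02: float,
    amp_threshold: float = AMPLITUDE_THRESHOLD,
    tau_threshold_s: float = RELAXATION_THRESHOLD_S,
) -> DynamicsClassification:
    """Classify one trace from its cross-correlation curve.

    Inclusion gate: the (pre-bleach) trace must last more than 10 s and spend
    more than 20% of its duration at E_FRET > 0.2.  The curve is fitted with a
    bi-exponential on lags > 0 (the lag-0 point is shot-noise dominated); the
    amplitude is the t->0 extrapolation a1+a2 and the relaxation time the
    amplitude-weighted mean of the two time constants.  Dynamic means
    amplitude < -0.1 and relaxation > 100 ms.
    """
    included = duration_s > 10.0 and fraction_above_e02 > 0.2
    if not included:
        return DynamicsClassification(np.nan, np.nan, included=False, is_dynamic=False)
    lags = curve.lags[1:]
    vals = curve.values[1:]
    if len(lags) < 4:
        return DynamicsClassification(np.nan, np.nan, included=True, is_dynamic=False, indeterminate=True)
    fit = _biexp_fit(lags, vals, curve.frame_period, float(curve.lags[-1]))
    if fit is None:
        return DynamicsClassification(np.nan, np.nan, included=True, is_dynamic=False, indeterminate=True)
    a1, a2, th1, th2 = fit
    amplitude = a1 + a2
    # amplitude-weighted mean relaxation; components carrying <10% of the
    # total amplitude are degenerate fit chasers (typically a near-zero weight
    # on a time constant at the bounds) and are excluded from the weighting
    wsum = abs(a1) + abs(a2)
    comps = [(a, th) for a, th in ((a1, th1), (a2, th2)) if abs(a) >= 0.1 * wsum]
    wkeep = sum(abs(a) for a, _ in comps)
    relaxation = sum(abs(a) * th for a, th in comps) / wkeep if wkeep > 0 else np.nan
    is_dynamic = bool(amplitude < amp_threshold and relaxation > tau_threshold_s)
    return DynamicsClassification(
        amplitude=float(amplitude),
        relaxation_s=float(relaxation),
        included=True,
        is_dynamic=is_dynamic,
        theta_fast_s=min(th1, th2),
        theta_slow_s=max(th1, th2),
    )


def fraction_dynamic(
    classifications: list[DynamicsClassification],
    movie_ids: list | None = None,
) -> tuple[float, dict]:
    """Percentage of dynamic traces among included ones, pooled and per movie."""
    included = [c for c in classifications if c.included]
    if not included:
        raise ValueError("no included traces")
    pooled = 100.0 * sum(c.is_dynamic for c in included) / len(included)
    per_movie: dict = {}
    if movie_ids is not None:
        if len(movie_ids) != len(classifications):
            raise ValueError("movie_ids must match classifications")
        for mid, c in zip(movie_ids, classifications):
            if not c.included:
                continue
            n_dyn, n_tot = per_movie.get(mid, (0, 0))
            per_movie[mid] = (n_dyn + int(c.is_dynamic), n_tot + 1)
        per_movie = {m: 100.0 * d / t for m, (d, t) in per_movie.items()}
    return pooled, per_movie
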