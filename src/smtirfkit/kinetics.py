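"""Dwell-time kinetics: survival curves, exponential-mixture fits, on-rates.

Bound-dwell (``t_bright``) distributions are summarized as survival curves
S(t) = fraction of events with duration >= t and fitted with 1-, 2- or
3-exponential mixtures by bounded nonlinear least squares with log-spaced
multi-start.  Components with time constants above a configurable boundary
(1 s by default) are classified "specific"; shorter ones reflect nonspecific
sampling.  Apparent on-rates come from mono-exponential fits to the dark-time
survival (k_on,app = 1/tau_on) and are corrected to specific on-rates by the
amplitude fraction of specific events:

    k_on,specific = k_on,app * (sum of specific A_i) / (sum of all A_i)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SurvivalCurve",
    "ExpComponent",
    "ExpMixtureFit",
    "OnRateEstimate",
    "build_survival",
    "fit_exponentials",
    "select_model",
    "fit_on_rate",
    "correct_on_rate",
    "bleach_rate_from_control",
    "correct_dwell_for_bleaching",
    "SPECIFIC_TAU_THRESHOLD_S",
]

#: Residence-time boundary between nonspecific and specific components.
SPECIFIC_TAU_THRESHOLD_S = 1.0


@dataclass
class SurvivalCurve:
    """Empirical survival of dwell durations: S(t) = P(T >= t)."""

    durations: np.ndarray  # sorted, s
    survival: np.ndarray  # same length, in (0, 1]
    n_events: int
    censored_fraction: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass
class ExpComponent:
    amplitude: float  # normalized, sums to 1 across components
    tau: float  # s
    kind: str  # "specific" | "nonspecific"


@dataclass
class ExpMixtureFit:
    components: list[ExpComponent]
    n_components: int
    rss: float
    bic: float
    covariance: np.ndarray | None = None
    at_bounds: bool = False
    specific_threshold_s: float = SPECIFIC_TAU_THRESHOLD_S

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([c.tau for c in self.components])

    def specific_fraction(self) -> float:
        return float(sum(c.amplitude for c in self.components if c.kind == "specific"))


@dataclass
class OnRateEstimate:
    tau_on: float  # s
    k_on_app: float  # 1/s
    k_on_specific: float | None = None
    amplitude_fractions: dict = field(default_factory=dict)


def build_survival(
    durations: np.ndarray,
    censored: np.ndarray | None = None,
    min_events: int = 10,
) -> SurvivalCurve:
    """Survival curve from observed dwell durations.

    Censored (window-truncated) events are excluded; if more than 10% of the
    input was censored the curve still excludes them but records the fraction
    so downstream reporting can flag the truncation bias.
    """
    durations = np.asarray(durations, dtype=float)
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        cens_frac = float(censored.mean()) if len(censored) else 0.0
        durations = durations[~censored]
    else:
        cens_frac = 0.0
    n = len(durations)
    if n < min_events:
        raise ValueError(f"need at least {min_events} uncensored events, got {n}")
    d = np.sort(durations)
    # S at each observed duration: fraction of events >= that duration
    s = 1.0 - np.arange(n) / n
    return SurvivalCurve(durations=d, survival=s, n_events=n, censored_fraction=cens_frac)


# ---------------------------------------------------------------------------
# Exponential-mixture fitting
# ---------------------------------------------------------------------------


def _mixture(t: np.ndarray, amps: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)


def fit_exponentials(
    curve: SurvivalCurve,
    n_components: int,
    specific_threshold_s: float = SPECIFIC_TAU_THRESHOLD_S,
    n_starts: int = 20,
    tau_bounds: tuple[float, float] | None = None,
) -> ExpMixtureFit:
    """Fit S(t) = sum_i A_i exp(-t/tau_i) to an unbinned survival curve.

    Bounded least squares with ``n_starts`` log-spaced initializations of the
    time constants (multi-start guards against the local minima that plague
    multi-exponential fits).  Amplitudes are fitted free (>= 0) and normalized
    to sum to 1 in the reported components; components are sorted by tau and
    classified specific/nonspecific by the threshold.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    t = curve.durations
    y = curve.survival
    t_min = max(t.min(), 1e-6)
    t_max = t.max()
    if tau_bounds is None:
        tau_bounds = (t_min / 2, 10.0 * t_max)
    lo_tau, hi_tau = tau_bounds

    k = n_components

    def residual(p):
        amps, taus = p[:k], p[k:]
        return _mixture(t, amps, taus) - y

    lower = np.concatenate([np.zeros(k), np.full(k, lo_tau)])
    upper = np.concatenate([np.full(k, 1.5), np.full(k, hi_tau)])

    # log-spaced initial tau grids spread over the observed range
    grid = np.geomspace(max(t_min, lo_tau * 1.01), min(t_max, hi_tau * 0.99), n_starts)
    best = None
    for s, start_tau in enumerate(grid):
        if k == 1:
            taus0 = np.array([start_tau])
        else:
            span = np.geomspace(1.0, max(t_max / start_tau, 4.0), k)
            taus0 = np.clip(start_tau * span, lo_tau * 1.01, hi_tau * 0.99)
        amps0 = np.full(k, 1.0 / k)
        p0 = np.concatenate([amps0, taus0])
        try:
            sol = least_squares(residual, p0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
        if rss < 1e-18:
            break
    if best is None:
        raise RuntimeError(
            f"exponential fit failed to converge for n={k} after {n_starts} starts"
        )
    rss, sol = best
    amps, taus = sol.x[:k], sol.x[k:]
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    total = amps.sum()
    if total <= 0:
        raise RuntimeError("degenerate fit: all amplitudes zero")
    norm_amps = amps / total

    at_bounds = bool(np.any(np.isclose(taus, lo_tau, rtol=1e-3)) or np.any(np.isclose(taus, hi_tau, rtol=1e-3)))

    n_obs = len(t)
    n_par = 2 * k - 1  # amplitudes constrained to sum to 1
    # BIC from the dwell-sample log-likelihood under the fitted mixture
    # density f(t) = sum_i (A_i / tau_i) exp(-t / tau_i); the survival points
    # are order statistics of the same sample, so an RSS-based criterion would
    # double-count them and systematically over-fit.
    dens = np.sum((norm_amps / taus)[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)
    loglik = float(np.sum(np.log(np.maximum(dens, 1e-300))))
    bic = -2.0 * loglik + n_par * np.log(n_obs)

    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (rss / max(n_obs - n_par, 1))
    except np.linalg.LinAlgError:
        pass

    comps = [
        ExpComponent(
            amplitude=float(a),
            tau=float(tau),
            kind="specific" if tau > specific_threshold_s else "nonspecific",
        )
        for a, tau in zip(norm_amps, taus)
    ]
    return ExpMixtureFit(
        components=comps,
        n_components=k,
        rss=rss,
        bic=float(bic),
        covariance=cov,
        at_bounds=at_bounds,
        specific_threshold_s=specific_threshold_s,
    )


def select_model(
    curve: SurvivalCurve,
    force_n: int | None = None,
    max_components: int = 3,
    **fit_kwargs,
) -> tuple[int, dict[int, ExpMixtureFit]]:
    """Choose the number of exponential components by BIC (or honor an override).

    Returns the selected n and the fits for every candidate n, so callers can
    reproduce fixed per-substrate choices (2 for free DNA, 3 for nucleosomes
    and chromatin fibers) via ``force_n``.
    """
    fits: dict[int, ExpMixtureFit] = {}
    for n in range(1, max_components + 1):
        try:
            fits[n] = fit_exponentials(curve, n, **fit_kwargs)
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("no exponential fit converged for any n")
    if force_n is not None:
        if force_n not in fits:
            fits[force_n] = fit_exponentials(curve, force_n, **fit_kwargs)
        return force_n, fits
    best = min(fits, key=lambda n: fits[n].bic)
    return best, fits


# ---------------------------------------------------------------------------
# On-rates
# ---------------------------------------------------------------------------


def fit_on_rate(dark_curve: SurvivalCurve, **fit_kwargs) -> OnRateEstimate:
    """Mono-exponential fit to the dark-time survival; k_on,app = 1/tau_on."""
    fit = fit_exponentials(dark_curve, 1, **fit_kwargs)
    tau_on = fit.components[0].tau
    return OnRateEstimate(tau_on=tau_on, k_on_app=1.0 / tau_on)


def correct_on_rate(k_on_app: float, fit: ExpMixtureFit) -> float:
    """Correct the apparent on-rate for nonspecific binding events.

    Multiplies by the amplitude fraction of specific components, removing the
    contribution of short nonspecific interactions to the measured event rate.
    """
    if not fit.components:
        raise ValueError("mixture fit has no components")
    total = float(fit.amplitudes.sum())
    specific = sum(c.amplitude for c in fit.components if c.kind == "specific")
    return float(k_on_app * specific / total)


# ---------------------------------------------------------------------------
# Photobleaching control
# ---------------------------------------------------------------------------


def bleach_rate_from_control(
    dwell_sets: dict[float, np.ndarray],
    duty_cycle: float = 1.0,
) -> float:
    """Bleach sensitivity (1/s per power unit) from immobilized-dye controls.

    ``dwell_sets`` maps excitation power to observed bright durations of
    surface-immobilized dyes (no unbinding, so the apparent off-rate is pure
    photobleaching).  Apparent rates are regressed on power through the
    origin; the slope divided by the duty cycle is the bleach rate per unit
    power of illuminated time.
    """
    if len(dwell_sets) < 2:
        raise ValueError("need at least two excitation power levels")
    powers = []
    rates = []
    for power, durations in sorted(dwell_sets.items()):
        if hasattr(durations, "bright_durations"):  # EventList
            durations = durations.bright_durations(include_censored=False)
        durations = np.asarray(durations, dtype=float)
        if len(durations) == 0:
            raise ValueError(f"no dwells at power {power}")
        rates.append(1.0 / durations.mean())
        powers.append(power)
    powers = np.array(powers)
    rates = np.array(rates)
    slope = float(np.sum(rates * powers) / np.sum(powers**2))
    return slope / duty_cycle


def correct_dwell_for_bleaching(
    tau_obs: float,
    bleach_rate: float,
    duty_cycle: float,
    enabled: bool = False,
) -> float:
    """Optional photobleaching correction 1/tau_true = 1/tau_obs - b*duty.

    Off by default: reported residence times are conventionally left
    uncorrected for dye photobleaching, with the control quantifying the bias.
    """
    if not enabled or bleach_rate == 0:
        return tau_obs
    inv = 1.0 / tau_obs - bleach_rate * duty_cycle
    if inv <= 0:
        raise ValueError("bleach correction exceeds observed rate")
    return 1.0 / inv
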