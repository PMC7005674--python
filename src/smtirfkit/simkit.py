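"""Seeded synthetic-data generator for smTIRF colocalization and smFRET experiments.

Produces ground-truth binding timelines (alternating bound/unbound intervals
drawn from an exponential-mixture dwell process), donor/acceptor smFRET traces
with anti-correlated state transitions and single-step photobleaching, and
rendered two-channel movie stacks with Gaussian PSFs, Poisson shot noise and
Gaussian read noise.  The generator emulates the statistical structure a
colocalization/FRET analysis assumes: immobilized diffraction-limited spots, a
far-red "locator" channel present in every frame, a transient "binder" (or
donor) channel, duty-cycled stroboscopic illumination, and photobleaching that
accumulates only while the camera shutter is open.

Everything is driven by a single integer seed which is expanded into
independent per-molecule streams via :class:`numpy.random.SeedSequence`, so a
configuration regenerates bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "BindingModel",
    "IlluminationScheme",
    "PhotophysicsModel",
    "OpticsModel",
    "FretStateModel",
    "TraceNoise",
    "Interval",
    "Timeline",
    "SimulatedFretTrace",
    "MovieStack",
    "simulate_binding_timeline",
    "simulate_fret_trace",
    "render_movie",
    "random_positions",
    "S2_DNA_BINDING",
    "MONONUCLEOSOME_BINDING",
    "DNA_ILLUMINATION",
    "NUCLEOSOME_ILLUMINATION",
]

# ---------------------------------------------------------------------------
# Domain models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingModel:
    """Kinetic model of a binder at an immobilized site.

    Parameters
    ----------
    on_rate : float
        Association events per second per site, i.e. ``1/tau_on``.
    off_components : sequence of (weight, tau_off_s)
        Exponential mixture of bound-dwell components.  Weights must sum
        to 1; components with ``tau_off > 1 s`` are conventionally the
        "specific" binding modes, shorter ones nonspecific sampling.
    site_count : int
        Number of independent sites per locator position.
    """

    on_rate: float
    off_components: tuple[tuple[float, float], ...]
    site_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "off_components", tuple((float(a), float(t)) for a, t in self.off_components))
        if self.on_rate < 0:
            raise ValueError("on_rate must be >= 0")
        if not self.off_components:
            raise ValueError("at least one off component required")
        total = sum(a for a, _ in self.off_components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"off-component weights must sum to 1 (got {total})")
        if any(t <= 0 for _, t in self.off_components):
            raise ValueError("all tau_off must be > 0")
        if any(a < 0 for a, _ in self.off_components):
            raise ValueError("weights must be >= 0")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([a for a, _ in self.off_components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.off_components])

    def survival(self, t: np.ndarray | float) -> np.ndarray:
        """Analytic bound-dwell survival S(t) = sum_i A_i exp(-t/tau_i)."""
        t = np.asarray(t, dtype=float)
        return np.sum(self.weights[:, None] * np.exp(-t[None, :] / self.taus[:, None]), axis=0) if t.ndim else float(
            np.sum(self.weights * np.exp(-t / self.taus))
        )


@dataclass(frozen=True)
class IlluminationScheme:
    """Stroboscopic camera timing: integration ``t_on`` and dead time ``t_off``.

    Duty-cycled (stroboscopic) illumination slows photobleaching during long
    dwells: the dye is excited only during the ``t_on`` window of each frame
    period ``t_on + t_off``.
    """

    t_on_ms: float
    t_off_ms: float
    n_frames: int
    excitation_power: float = 1.0

    def __post_init__(self) -> None:
        if self.t_on_ms <= 0:
            raise ValueError("t_on must be > 0")
        if self.t_off_ms < 0:
            raise ValueError("t_off must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def frame_period_s(self) -> float:
        return (self.t_on_ms + self.t_off_ms) / 1000.0

    @property
    def t_on_s(self) -> float:
        return self.t_on_ms / 1000.0

    @property
    def duty_cycle(self) -> float:
        return self.t_on_ms / (self.t_on_ms + self.t_off_ms)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def frame_times(self) -> np.ndarray:
        """Frame start times in seconds (length n_frames)."""
        return np.arange(self.n_frames) * self.frame_period_s


@dataclass(frozen=True)
class PhotophysicsModel:
    """Dye photophysics.  ``bleach_rate`` is per second of *illuminated* time
    and scales linearly with excitation power."""

    bleach_rate: float = 0.0
    blink_allowed: bool = False

    def __post_init__(self) -> None:
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model for movie rendering."""

    image_size: tuple[int, int] = (128, 128)
    psf_sigma: float = 1.3
    pixel_size_nm: float = 160.0
    channel_transform: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
    )
    background_level: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    drift_per_frame: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def transform_matrix(self) -> np.ndarray:
        return np.asarray(self.channel_transform, dtype=float)


@dataclass(frozen=True)
class FretStateModel:
    """Markov model of FRET conformational states.

    ``states`` is a list of ``(E_level, total_emission)`` pairs: the FRET
    efficiency of the conformation and the total photon budget per frame
    (donor + sensitized acceptor, before detection corrections).
    ``transition_rates[i, j]`` is the i->j exchange rate in 1/s.
    """

    states: tuple[tuple[float, float], ...]
    transition_rates: tuple[tuple[float, ...], ...] = ()
    gamma_true: float = 0.423
    beta_true: float = 0.073
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple((float(e), float(i)) for e, i in self.states))
        if not self.states:
            raise ValueError("at least one FRET state required")
        for e, _ in self.states:
            if not 0.0 <= e <= 1.0:
                raise ValueError("E levels must lie in [0, 1]")
        if self.gamma_true <= 0:
            raise ValueError("gamma must be > 0")
        if self.beta_true < 0:
            raise ValueError("beta must be >= 0")
        n = len(self.states)
        if self.transition_rates:
            q = np.asarray(self.transition_rates, dtype=float)
            if q.shape != (n, n):
                raise ValueError("transition_rates must be n_states x n_states")
            if (q[~np.eye(n, dtype=bool)] < 0).any():
                raise ValueError("rates must be >= 0")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rates must be >= 0")

    @property
    def rate_matrix(self) -> np.ndarray:
        n = len(self.states)
        if not self.transition_rates:
            return np.zeros((n, n))
        return np.asarray(self.transition_rates, dtype=float)

    def emissions(self) -> tuple[np.ndarray, np.ndarray]:
        """Ideal detected (F_D, F_A) per state.

        Donor photons are ``I*(1-E)``; the acceptor channel detects the
        sensitized emission scaled by the detection-efficiency ratio gamma
        plus donor bleed-through beta:  F_A = gamma*I*E + beta*F_D.
        """
        e = np.array([s[0] for s in self.states])
        i = np.array([s[1] for s in self.states])
        f_d = i * (1.0 - e)
        f_a = self.gamma_true * i * e + self.beta_true * f_d
        return f_d, f_a


@dataclass(frozen=True)
class TraceNoise:
    """Additive noise for simulated intensity traces."""

    background: float = 0.0
    read_noise_sd: float = 0.0
    shot_noise: bool = False


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

STATE_UNBOUND = "unbound"
STATE_BOUND = "bound"
STATE_BLEACHED = "bleached"


@dataclass(frozen=True)
class Interval:
    state: str
    start: float
    end: float
    mode: int = -1  # index into off_components for bound intervals

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Timeline:
    """Ground-truth state history of one molecule: contiguous, non-overlapping
    intervals covering [0, duration]."""

    intervals: list[Interval]
    duration: float

    def __post_init__(self) -> None:
        t = 0.0
        for iv in self.intervals:
            if abs(iv.start - t) > 1e-9 or iv.end < iv.start:
                raise ValueError("intervals must be contiguous and non-overlapping")
            t = iv.end
        if abs(t - self.duration) > 1e-9:
            raise ValueError("intervals must cover [0, duration]")

    def bright_durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals if iv.state == STATE_BOUND])

    def dark_durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals if iv.state == STATE_UNBOUND])

    def bright_modes(self) -> np.ndarray:
        return np.array([iv.mode for iv in self.intervals if iv.state == STATE_BOUND], dtype=int)

    def brightness_per_frame(self, illum: IlluminationScheme) -> np.ndarray:
        """Fraction of each frame's t_on window spent bound (0..1).

        A binding event is visible in a frame if it overlaps any part of the
        frame's integration window; partial overlap dims the spot
        proportionally, matching camera integration.
        """
        period = illum.frame_period_s
        t_on = illum.t_on_s
        frac = np.zeros(illum.n_frames)
        for iv in self.intervals:
            if iv.state != STATE_BOUND:
                continue
            k0 = max(0, int(np.floor(iv.start / period)))
            k1 = min(illum.n_frames - 1, int(np.ceil(iv.end / period)))
            for k in range(k0, k1 + 1):
                w0, w1 = k * period, k * period + t_on
                overlap = min(iv.end, w1) - max(iv.start, w0)
                if overlap > 0:
                    frac[k] += overlap / t_on
        return np.clip(frac, 0.0, 1.0)


def _illuminated_time(a: float, b: float, illum: IlluminationScheme) -> float:
    """Total camera-open (t_on) time within wall-clock interval [a, b]."""
    if b <= a:
        return 0.0
    period, t_on = illum.frame_period_s, illum.t_on_s

    def cum(t: float) -> float:
        k, r = divmod(t, period)
        return k * t_on + min(r, t_on)

    return cum(b) - cum(a)


def _wall_time_for_illumination(a: float, budget: float, illum: IlluminationScheme) -> float:
    """Wall-clock time t >= a at which illuminated time since ``a`` reaches
    ``budget`` (inverse of :func:`_illuminated_time`)."""
    period, t_on = illum.frame_period_s, illum.t_on_s
    k, r = divmod(a, period)
    # illuminated time remaining in the current period after phase r
    head = max(0.0, t_on - min(r, t_on))
    if budget <= head:
        return a + budget if r < t_on else (k + 1) * period + budget
    budget -= head
    k += 1  # now at start of period k
    full, rem = divmod(budget, t_on)
    return (k + full) * period + rem


def simulate_binding_timeline(
    model: BindingModel,
    photo: PhotophysicsModel,
    illum: IlluminationScheme,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
) -> Timeline:
    """Sample a continuous-time bound/unbound timeline for one site.

    Dark (search) durations are Exp(1/on_rate); each binding event draws a
    mixture mode ``i`` with probability ``A_i`` and a duration Exp(tau_off_i).
    If ``photo.bleach_rate > 0`` the dye carries an exponentially distributed
    illuminated-time budget; the bleaching clock advances only during camera
    t_on windows (the point of stroboscopic imaging), and a bleach truncates
    the bright interval (subsequent events use fresh dyes from solution).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = illum.duration_s
    if duration <= 0:
        raise ValueError("duration must be > 0")

    intervals: list[Interval] = []
    t = 0.0
    if model.on_rate == 0:
        return Timeline([Interval(STATE_UNBOUND, 0.0, duration)], duration)
    weights, taus = model.weights, model.taus
    while t < duration:
        dark = rng.exponential(1.0 / model.on_rate)
        t_bind = t + dark
        if t_bind >= duration:
            intervals.append(Interval(STATE_UNBOUND, t, duration))
            break
        intervals.append(Interval(STATE_UNBOUND, t, t_bind))
        mode = int(rng.choice(len(weights), p=weights))
        dwell = rng.exponential(taus[mode])
        t_release = t_bind + dwell
        if photo.bleach_rate > 0:
            budget = rng.exponential(1.0 / photo.bleach_rate)
            t_bleach = _wall_time_for_illumination(t_bind, budget, illum)
            t_release = min(t_release, t_bleach)
        t_release = min(t_release, duration)
        if t_release > t_bind:
            intervals.append(Interval(STATE_BOUND, t_bind, t_release, mode=mode))
        t = t_release
    if not intervals or intervals[-1].end < duration:
        last = intervals[-1].end if intervals else 0.0
        intervals.append(Interval(STATE_UNBOUND, last, duration))
    return Timeline(intervals, duration)


# ---------------------------------------------------------------------------
# FRET traces
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFretTrace:
    """Raw donor/acceptor trace plus generator ground truth."""

    times: np.ndarray
    f_d: np.ndarray
    f_a: np.ndarray
    true_e: np.ndarray  # occupancy-weighted E per frame (nan after bleach)
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    model: FretStateModel
    background: float = 0.0


def _sample_state_path(model: FretStateModel, duration: float, rng: np.random.Generator):
    """Continuous-time Markov chain path: list of (state_index, start, end)."""
    n = len(model.states)
    q = model.rate_matrix
    out_rates = q.sum(axis=1) - np.diag(q)
    state = int(rng.integers(n)) if n > 1 else 0
    # start from the stationary-ish uniform choice; fine for synthetic traces
    path = []
    t = 0.0
    while t < duration:
        r = out_rates[state]
        hold = rng.exponential(1.0 / r) if r > 0 else duration - t
        end = min(t + hold, duration)
        path.append((state, t, end))
        t = end
        if t >= duration or r == 0:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(n, p=probs))
    if path and path[-1][2] < duration:
        path.append((path[-1][0], path[-1][2], duration))
    return path


def simulate_fret_trace(
    model: FretStateModel,
    illum: IlluminationScheme,
    noise: TraceNoise | None = None,
    seed: int | np.random.Generator = 0,
) -> SimulatedFretTrace:
    """Generate anti-correlated donor/acceptor traces with single-step bleaching.

    Per-frame signals are occupancy-weighted averages over each frame's t_on
    window, so applying the corrected FRET-efficiency formula with the true
    beta/gamma returns the occupied state's E level exactly on noiseless,
    single-occupancy frames.  Bleach times are exponential in illuminated
    time; after acceptor bleach all excitation energy exits through the donor
    (plus bleed-through), after donor bleach both channels fall to background.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or TraceNoise()
    duration = illum.duration_s
    path = _sample_state_path(model, duration, rng)
    f_d_states, f_a_states = model.emissions()
    totals = np.array([i for _, i in model.states])
    e_levels = np.array([e for e, _ in model.states])

    t_a = (
        _wall_time_for_illumination(0.0, rng.exponential(1.0 / model.acceptor_bleach_rate), illum)
        if model.acceptor_bleach_rate > 0
        else np.inf
    )
    t_d = (
        _wall_time_for_illumination(0.0, rng.exponential(1.0 / model.donor_bleach_rate), illum)
        if model.donor_bleach_rate > 0
        else np.inf
    )

    period, t_on = illum.frame_period_s, illum.t_on_s
    n = illum.n_frames
    f_d = np.zeros(n)
    f_a = np.zeros(n)
    true_e = np.full(n, np.nan)

    def segment_emission(state: int, a: float, b: float, k: int) -> None:
        """Accumulate emission of `state` occupied on wall interval [a,b] into frame k."""
        w0, w1 = k * period, k * period + t_on
        lo, hi = max(a, w0), min(b, w1)
        if hi <= lo:
            return
        # split by bleach times
        edges = sorted({lo, hi, *(x for x in (t_a, t_d) if lo < x < hi)})
        for s0, s1 in zip(edges[:-1], edges[1:]):
            frac = (s1 - s0) / t_on
            mid = 0.5 * (s0 + s1)
            if mid >= min(t_d, t_a) and mid >= t_d:
                continue  # donor bleached: both channels dark
            if mid >= t_a:  # acceptor bleached, donor alive: no FRET
                d = totals[state]
                f_d[k] += frac * d
                f_a[k] += frac * model.beta_true * d
            else:
                f_d[k] += frac * f_d_states[state]
                f_a[k] += frac * f_a_states[state]
            if mid < min(t_a, t_d):
                # occupancy-weighted true E accumulates only pre-bleach
                if np.isnan(true_e[k]):
                    true_e[k] = 0.0
                true_e[k] += frac * e_levels[state]

    for state, a, b in path:
        k0 = max(0, int(np.floor(a / period)))
        k1 = min(n - 1, int(np.ceil(b / period)))
        for k in range(k0, k1 + 1):
            segment_emission(state, a, b, k)

    # normalize true E by bound fraction of each frame actually pre-bleach
    if noise.shot_noise:
        f_d = rng.poisson(f_d + noise.background).astype(float)
        f_a = rng.poisson(f_a + noise.background).astype(float)
    else:
        f_d = f_d + noise.background
        f_a = f_a + noise.background
    if noise.read_noise_sd > 0:
        f_d = f_d + rng.normal(0, noise.read_noise_sd, n)
        f_a = f_a + rng.normal(0, noise.read_noise_sd, n)

    def frame_of(t: float) -> int | None:
        if not np.isfinite(t) or t >= duration:
            return None
        return int(t / period)

    return SimulatedFretTrace(
        times=illum.frame_times(),
        f_d=f_d,
        f_a=f_a,
        true_e=true_e,
        donor_bleach_frame=frame_of(t_d),
        acceptor_bleach_frame=frame_of(t_a),
        model=model,
        background=noise.background,
    )


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


@dataclass
class MovieStack:
    """Two-channel synthetic movie with ground-truth sidecar."""

    locator: np.ndarray  # (T, H, W)
    binder: np.ndarray  # (T, H, W)
    optics: OpticsModel
    illum: IlluminationScheme
    sidecar: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "locator.tif", self.locator.astype(np.float32))
        tifffile.imwrite(out / "binder.tif", self.binder.astype(np.float32))
        sidecar = dict(self.sidecar)
        events = sidecar.pop("events", None)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=_jsonable)
        if events is not None:
            pd.DataFrame(events).to_csv(out / "events.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(type(obj))


def random_positions(
    n: int,
    image_size: tuple[int, int],
    margin: float = 8.0,
    min_separation: float = 6.0,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Uniform random (row, col) spot positions with a minimum separation."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    h, w = image_size
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not place positions with requested separation")
        p = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
        if all(np.hypot(*(p - q)) >= min_separation for q in pts):
            pts.append(p)
    return np.array(pts)


def _render_spot(frame: np.ndarray, y: float, x: float, photons: float, sigma: float) -> None:
    """Add a 2D Gaussian PSF of integrated intensity `photons` in place."""
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y1 <= y0 or x1 <= x0:
        return
    yy = np.arange(y0, y1)[:, None]
    xx = np.arange(x0, x1)[None, :]
    g = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    frame[y0:y1, x0:x1] += photons * g / (2 * np.pi * sigma**2)


def render_movie(
    timelines: list[Timeline],
    optics: OpticsModel,
    illum: IlluminationScheme,
    positions: np.ndarray | None = None,
    binder_emission: float = 3000.0,
    locator_emission: float = 2000.0,
    seed: int | np.random.Generator = 0,
) -> MovieStack:
    """Render a two-channel movie from ground-truth binding timelines.

    The far-red locator channel shows every molecule in every frame (plus
    drift); the binder channel shows a spot only while its timeline is bound,
    dimmed by partial-frame overlap.  Emissions are photon counts integrated
    over the PSF per frame.  A ground-truth sidecar (positions, per-molecule
    event table) is attached for round-trip validation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = optics.image_size
    n_mol = len(timelines)
    if positions is None:
        positions = random_positions(n_mol, optics.image_size, rng=rng)
    positions = np.asarray(positions, dtype=float)
    if len(positions) != n_mol:
        raise ValueError("one position per timeline required")
    if n_mol and (
        (positions < 0).any() or (positions[:, 0] >= h).any() or (positions[:, 1] >= w).any()
    ):
        raise ValueError("positions must lie inside image bounds")

    overlap_warning = False
    for i in range(n_mol):
        for j in range(i + 1, n_mol):
            if np.hypot(*(positions[i] - positions[j])) < 4 * optics.psf_sigma:
                overlap_warning = True

    bright = np.array([tl.brightness_per_frame(illum) for tl in timelines]) if n_mol else np.zeros((0, illum.n_frames))
    drift = np.asarray(optics.drift_per_frame, dtype=float)

    locator = np.zeros((illum.n_frames, h, w))
    binder = np.zeros((illum.n_frames, h, w))
    for k in range(illum.n_frames):
        off = drift * k
        locator[k] += optics.background_level
        binder[k] += optics.background_level
        for m in range(n_mol):
            y, x = positions[m] + off
            _render_spot(locator[k], y, x, locator_emission, optics.psf_sigma)
            if bright[m, k] > 0:
                _render_spot(binder[k], y, x, binder_emission * bright[m, k], optics.psf_sigma)
    if optics.shot_noise:
        locator = rng.poisson(locator).astype(float)
        binder = rng.poisson(binder).astype(float)
    if optics.read_noise_sd > 0:
        locator = locator + rng.normal(0, optics.read_noise_sd, locator.shape)
        binder = binder + rng.normal(0, optics.read_noise_sd, binder.shape)

    events = []
    for m, tl in enumerate(timelines):
        for iv in tl.intervals:
            if iv.state == STATE_BOUND:
                events.append(
                    {"molecule": m, "start_s": iv.start, "duration_s": iv.duration, "mode": iv.mode}
                )
    sidecar = {
        "positions": positions,
        "binder_emission": binder_emission,
        "locator_emission": locator_emission,
        "drift_per_frame": list(drift),
        "overlap_warning": overlap_warning,
        "frame_period_s": illum.frame_period_s,
        "events": events,
    }
    if overlap_warning:
        warnings.warn("some spots closer than 4*psf_sigma; flagged in sidecar", stacklevel=2)
    return MovieStack(locator=locator, binder=binder, optics=optics, illum=illum, sidecar=sidecar)


# ---------------------------------------------------------------------------
# Reference regimes (study conditions)
# ---------------------------------------------------------------------------

#: Two-exponential dwell mixture of the medium-affinity free-DNA site:
#: 35% short (12.4 s) and 65% long (452 s) residence components.
S2_DNA_BINDING = BindingModel(on_rate=0.01, off_components=((0.35, 12.4), (0.65, 452.0)))

#: Three-component mononucleosome-like regime: a sub-second nonspecific mode
#: plus two specific modes with >10-fold shorter residence than free DNA.
MONONUCLEOSOME_BINDING = BindingModel(
    on_rate=0.1, off_components=((0.40, 0.3), (0.35, 3.0), (0.25, 12.0))
)

#: Camera timing used for free-DNA movies (100 ms on / 600 ms off).
DNA_ILLUMINATION = IlluminationScheme(t_on_ms=100.0, t_off_ms=600.0, n_frames=1500)

#: Camera timing used for mononucleosome / chromatin movies (quasi-continuous).
NUCLEOSOME_ILLUMINATION = IlluminationScheme(t_on_ms=100.0, t_off_ms=0.3, n_frames=1991)
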