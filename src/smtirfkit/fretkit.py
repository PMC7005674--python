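"""smFRET conformation analysis.

Ensemble FRET from donor quenching, beta/gamma calibration from
acceptor-bleaching steps, corrected per-frame E_FRET, five-criterion trace
selection, per-trace-normalized E histograms (0.02 bins), constrained
3-Gaussian population decomposition with analytic peak areas, and the
preparation quality gate on the low-FRET population.

Population classes follow the center of each Gaussian: LF (c < 0.2, typically
assembly defects), MF (0.2 <= c <= 0.4, open chromatin) and HF (c > 0.4,
compact/stacked chromatin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "CalibrationConstants",
    "FretTrace",
    "GaussianComponent",
    "PopulationSummary",
    "SelectionParams",
    "ensemble_fret",
    "detect_bleach_steps",
    "annotate_bleach_events",
    "estimate_beta_gamma",
    "compute_efret",
    "select_traces",
    "build_efret_histogram",
    "fit_three_gaussians",
    "qc_preparation",
    "classify_center",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Channel corrections: donor bleed-through beta, detection-efficiency
    ratio gamma."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class FretTrace:
    """Donor/acceptor intensity trace with bleach annotations and selection flags."""

    times: np.ndarray
    f_d: np.ndarray
    f_a: np.ndarray
    e_fret: np.ndarray | None = None
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    background: float = 0.0
    clustered: bool = False
    acceptor_direct_excitation: bool | None = None
    flags: dict = field(default_factory=dict)
    accepted: bool | None = None

    @property
    def frame_period(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan

    @property
    def first_bleach_frame(self) -> int | None:
        frames = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame) if f is not None]
        return min(frames) if frames else None

    def prebleach_slice(self) -> slice:
        stop = self.first_bleach_frame
        return slice(0, stop if stop is not None else len(self.times))


@dataclass
class GaussianComponent:
    amplitude: float  # peak height A
    center: float  # E units
    sigma: float
    collapsed: bool = False

    @property
    def area(self) -> float:
        """Analytic peak area A * sigma * sqrt(2*pi)."""
        return float(self.amplitude * self.sigma * np.sqrt(2.0 * np.pi))

    @property
    def kind(self) -> str:
        return classify_center(self.center)


@dataclass
class PopulationSummary:
    lf_percent: float
    mf_percent: float
    hf_percent: float
    n_traces: int
    qc_pass: bool | None = None

    def as_dict(self) -> dict:
        return {
            "LF%": self.lf_percent,
            "MF%": self.mf_percent,
            "HF%": self.hf_percent,
            "n_traces": self.n_traces,
            "qc_pass": self.qc_pass,
        }


def classify_center(center: float) -> str:
    """LF/MF/HF class from a Gaussian center: LF c<0.2, MF 0.2<=c<=0.4, HF c>0.4."""
    if center < 0.2:
        return "LF"
    if center <= 0.4:
        return "MF"
    return "HF"


# ---------------------------------------------------------------------------
# Ensemble FRET
# ---------------------------------------------------------------------------


def ensemble_fret(f_da: float, f_d_only: float) -> float:
    """Bulk FRET efficiency from donor quenching: E = 1 - F_DA / F_D.

    ``f_da`` is donor emission in the presence of the acceptor, ``f_d_only``
    donor emission of a donor-only reference.
    """
    if f_d_only <= 0:
        raise ValueError("donor-only signal must be > 0")
    return 1.0 - f_da / f_d_only


# ---------------------------------------------------------------------------
# Bleach-step detection
# ---------------------------------------------------------------------------


def _best_split(x: np.ndarray, min_seg: int) -> tuple[int, float]:
    """Best two-piece-constant split index and its residual SS."""
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x**2)
    best_k, best_ss = -1, np.inf
    ks = np.arange(min_seg, n - min_seg + 1)
    if len(ks) == 0:
        return -1, float(np.sum((x - x.mean()) ** 2))
    left_n = ks.astype(float)
    left_sum = c1[ks - 1]
    left_sq = c2[ks - 1]
    right_n = n - left_n
    right_sum = c1[-1] - left_sum
    right_sq = c2[-1] - left_sq
    ss = (left_sq - left_sum**2 / left_n) + (right_sq - right_sum**2 / right_n)
    j = int(np.argmin(ss))
    best_k, best_ss = int(ks[j]), float(ss[j])
    return best_k, best_ss


def _noise_sd(x: np.ndarray) -> float:
    """Robust per-point noise from first differences (step-insensitive)."""
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0)) or 1e-12


def detect_bleach_steps(
    x: np.ndarray,
    min_segment: int = 5,
    significance: float = 4.0,
    max_depth: int = 4,
) -> list[int]:
    """Detect downward/upward intensity steps in one channel.

    Recursive two-piece constant change-point fits: a split is accepted when
    the mean change exceeds ``significance`` times the robust point noise.
    Returns sorted frame indices (first frame after the step); 0, 1, or more
    steps may be found (2+ indicates blinking and disqualifies a trace).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * min_segment:
        return []
    # noise floor: a small fraction of the dynamic range, so noiseless
    # piecewise-constant traces do not split on numerically tiny level shifts
    sd = max(_noise_sd(x), 1e-3 * float(np.ptp(x)))

    def recurse(seg: np.ndarray, offset: int, depth: int) -> list[tuple[int, float]]:
        if depth >= max_depth or len(seg) < 2 * min_segment:
            return []
        k, _ = _best_split(seg, min_segment)
        if k < 0:
            return []
        delta = abs(seg[k:].mean() - seg[:k].mean())
        if delta < significance * sd:
            return []
        return (
            recurse(seg[:k], offset, depth + 1)
            + [(offset + k, delta)]
            + recurse(seg[k:], offset + k, depth + 1)
        )

    steps = sorted(recurse(x, 0, 0))
    # partial-overlap frames at a bleach create small satellite steps within a
    # segment length of the true one; keep the largest step of each cluster
    merged: list[tuple[int, float]] = []
    for k, delta in steps:
        if merged and k - merged[-1][0] <= min_segment:
            if delta > merged[-1][1]:
                merged[-1] = (k, delta)
        else:
            merged.append((k, delta))
    return [k for k, _ in merged]


def annotate_bleach_events(
    tr: FretTrace,
    pair_tolerance: int = 3,
    min_segment: int = 5,
    significance: float = 4.0,
) -> dict:
    """Group per-channel intensity steps into per-dye bleach events.

    A dye bleach leaves a signature in *both* channels: a donor bleach drops
    F_D to background and removes its bleed-through from F_A; an acceptor
    bleach drops F_A while F_D rises (the FRET pathway closes).  Steps
    coincident across channels within ``pair_tolerance`` frames are therefore
    one event, not two.  Any step left unexplained (e.g. an intensity
    recovery, i.e. blinking, or a second drop in the same channel) marks the
    trace anomalous.

    Sets ``tr.donor_bleach_frame`` / ``tr.acceptor_bleach_frame`` and returns
    ``{"donor": [...], "acceptor": [...], "anomalous": bool}``.
    """

    def signed_steps(x: np.ndarray) -> list[tuple[int, float]]:
        frames = detect_bleach_steps(x, min_segment=min_segment, significance=significance)
        out = []
        for k in frames:
            w = min_segment
            delta = x[k : k + w].mean() - x[max(k - w, 0) : k].mean()
            out.append((k, float(delta)))
        return out

    d_steps = signed_steps(np.asarray(tr.f_d, dtype=float))
    a_steps = signed_steps(np.asarray(tr.f_a, dtype=float))
    a_unused = list(a_steps)
    d_unused = list(d_steps)
    donor_events: list[int] = []
    acceptor_events: list[int] = []

    # donor bleach: F_D down-step, optionally echoed by an F_A down-step
    for k, delta in list(d_unused):
        if delta >= 0:
            continue
        d_unused.remove((k, delta))
        donor_events.append(k)
        for ka, da in list(a_unused):
            if abs(ka - k) <= pair_tolerance and da < 0:
                a_unused.remove((ka, da))
                break
    # acceptor bleach: F_A down-step, optionally with an F_D up-step
    for k, delta in list(a_unused):
        if delta >= 0:
            continue
        a_unused.remove((k, delta))
        acceptor_events.append(k)
        for kd, dd in list(d_unused):
            if abs(kd - k) <= pair_tolerance and dd > 0:
                d_unused.remove((kd, dd))
                break

    anomalous = bool(d_unused or a_unused)
    tr.donor_bleach_frame = min(donor_events) if donor_events else None
    tr.acceptor_bleach_frame = min(acceptor_events) if acceptor_events else None
    return {"donor": sorted(donor_events), "acceptor": sorted(acceptor_events), "anomalous": anomalous}


# ---------------------------------------------------------------------------
# beta / gamma calibration
# ---------------------------------------------------------------------------


def estimate_beta_gamma(
    traces: list[FretTrace],
    margin: int = 2,
) -> CalibrationConstants:
    """Estimate bleed-through beta and detection-efficiency gamma from
    acceptor-bleaching steps.

    Per qualifying trace (exactly one acceptor bleach occurring while the
    donor is still alive): beta is the post-bleach F_A/F_D ratio — with the
    acceptor dark, any residual acceptor-channel signal is donor
    bleed-through.  gamma is the ratio of the bleed-through-corrected acceptor
    drop to the donor rise across the bleach, which equals the detection
    efficiency of sensitized emission relative to donor photons.  Per-trace
    estimates are aggregated by the median.
    """
    betas, gammas = [], []
    for tr in traces:
        ab = tr.acceptor_bleach_frame
        if ab is None:
            continue
        db = tr.donor_bleach_frame
        end = db if db is not None else len(tr.times)
        if db is not None and db <= ab:
            continue  # donor died first; no usable acceptor step
        pre = slice(0, max(ab - margin, 1))
        post = slice(min(ab + margin, end - 1), end)
        d_pre = tr.f_d[pre].mean() - tr.background
        a_pre = tr.f_a[pre].mean() - tr.background
        d_post = tr.f_d[post].mean() - tr.background
        a_post = tr.f_a[post].mean() - tr.background
        if d_post <= 0 or d_post <= d_pre:
            continue
        beta = a_post / d_post
        gamma = (a_pre - beta * d_pre) / (d_post - d_pre)
        if gamma > 0:
            betas.append(beta)
            gammas.append(gamma)
    if not betas:
        raise ValueError("no traces with a usable single acceptor-bleach step")
    return CalibrationConstants(beta=float(np.median(betas)), gamma=float(np.median(gammas)))


# ---------------------------------------------------------------------------
# E_FRET
# ---------------------------------------------------------------------------


def compute_efret(
    f_d: np.ndarray,
    f_a: np.ndarray,
    calib: CalibrationConstants,
    background: float = 0.0,
) -> np.ndarray:
    """Corrected per-frame FRET efficiency.

    E = (F_A - beta*F_D) / ((F_A - beta*F_D) + gamma*F_D).  Values are not
    clamped to [0, 1]; frames with a non-positive denominator are invalid and
    returned as NaN (excluded from histograms).
    """
    f_d = np.asarray(f_d, dtype=float) - background
    f_a = np.asarray(f_a, dtype=float) - background
    sens = f_a - calib.beta * f_d
    denom = sens + calib.gamma * f_d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, sens / denom, np.nan)
    return e


# ---------------------------------------------------------------------------
# Trace selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the five-criterion smFRET trace filter."""

    donor_intensity_cap: float = 8000.0  # aggregation pre-filter, donor channel
    acceptor_intensity_cap: float = 5000.0
    min_total_emission: float = 2000.0  # criterion ii
    total_emission_cv_max: float = 0.20  # "constant" tolerance for criterion ii
    min_baseline_s: float = 2.0  # criterion iii
    min_donor_s: float = 5.0  # criterion iv


def select_traces(
    traces: list[FretTrace],
    calib: CalibrationConstants,
    params: SelectionParams | None = None,
) -> list[FretTrace]:
    """Apply aggregation pre-filters and the five selection criteria.

    Criteria: (i) a single bleaching event per channel (blinking excluded);
    (ii) constant total emission F_D + F_A/gamma above the minimum;
    (iii) a constant baseline of at least 2 s after donor bleaching;
    (iv) donor emission for at least 5 s; (v) evidence of the acceptor dye
    (an acceptor bleach step while the donor is alive, or direct acceptor
    excitation at the end of the movie).  Each failure is recorded per
    criterion in ``trace.flags``; ``trace.accepted`` summarizes.
    """
    params = params or SelectionParams()
    for tr in traces:
        flags: dict[str, bool] = {}
        dt = tr.frame_period

        events = annotate_bleach_events(tr)
        pre = tr.prebleach_slice()

        clustered = tr.clustered
        aggregated = (
            np.max(tr.f_d) > params.donor_intensity_cap
            or np.max(tr.f_a) > params.acceptor_intensity_cap
        )
        flags["prefilter"] = not (clustered or aggregated)

        n_events = len(events["donor"]) + len(events["acceptor"])
        flags["i"] = (
            not events["anomalous"]
            and len(events["donor"]) <= 1
            and len(events["acceptor"]) <= 1
            and n_events >= 1
        )

        total = (tr.f_a[pre] - tr.background) / calib.gamma + (tr.f_d[pre] - tr.background)
        if len(total) >= 2 and total.mean() > 0:
            flags["ii"] = (
                total.mean() > params.min_total_emission
                and total.std() / total.mean() < params.total_emission_cv_max
            )
        else:
            flags["ii"] = False

        if tr.donor_bleach_frame is not None:
            baseline_s = (len(tr.times) - tr.donor_bleach_frame) * dt
            flags["iii"] = baseline_s >= params.min_baseline_s
            flags["iv"] = tr.donor_bleach_frame * dt >= params.min_donor_s
        else:
            flags["iii"] = True  # no donor bleach observed; criterion vacuous
            flags["iv"] = len(tr.times) * dt >= params.min_donor_s

        acceptor_bleached_first = tr.acceptor_bleach_frame is not None and (
            tr.donor_bleach_frame is None or tr.acceptor_bleach_frame < tr.donor_bleach_frame
        )
        flags["v"] = acceptor_bleached_first or bool(tr.acceptor_direct_excitation)

        tr.flags = flags
        tr.accepted = all(flags.values())
    return [tr for tr in traces if tr.accepted]


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


def build_efret_histogram(
    traces: list[FretTrace],
    calib: CalibrationConstants | None = None,
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.2, 1.2),
    min_trace_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average of per-trace-normalized E_FRET histograms.

    Each trace's pre-bleach valid E samples are histogrammed at ``bin_width``
    and normalized to unit mass, so traces of unequal length contribute
    equally; the returned histogram is the mean over traces.  Traces shorter
    than ``min_trace_s`` of usable signal are skipped.
    Returns (bin_centers, mean_density).
    """
    edges = np.arange(e_range[0], e_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_trace = []
    for tr in traces:
        if tr.e_fret is None:
            if calib is None:
                raise ValueError("trace has no E_FRET and no calibration was given")
            tr.e_fret = compute_efret(tr.f_d, tr.f_a, calib, background=tr.background)
        e = tr.e_fret[tr.prebleach_slice()]
        e = e[np.isfinite(e)]
        if len(e) * tr.frame_period <= min_trace_s:
            continue
        h, _ = np.histogram(e, bins=edges)
        if h.sum() == 0:
            continue
        per_trace.append(h / h.sum())
    if not per_trace:
        raise ValueError("no accepted traces longer than the minimum length")
    return centers, np.mean(per_trace, axis=0)


# ---------------------------------------------------------------------------
# 3-Gaussian decomposition
# ---------------------------------------------------------------------------


def fit_three_gaussians(
    centers: np.ndarray,
    density: np.ndarray,
    init_centers: tuple[float, float, float] = (0.05, 0.30, 0.50),
    init_sigma: float = 0.05,
    bin_width: float = 0.02,
    n_traces: int = 0,
) -> tuple[list[GaussianComponent], PopulationSummary]:
    """Decompose an E histogram into three Gaussian sub-populations.

    Constrained least squares (lmfit): centers are kept ordered via positive
    center offsets, widths bounded away from zero.  Peak areas are computed
    analytically as A*sigma*sqrt(2*pi); population percentages are area
    shares, classified LF/MF/HF by center.  A component narrower than half a
    bin is flagged as collapsed.
    """
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.count_nonzero(density) < 10:
        raise ValueError("histogram must have at least 10 nonzero bins")

    model = (
        lmfit.models.GaussianModel(prefix="g1_")
        + lmfit.models.GaussianModel(prefix="g2_")
        + lmfit.models.GaussianModel(prefix="g3_")
    )
    p = model.make_params()
    lo, hi = centers.min(), centers.max()
    c1, c2, c3 = init_centers
    p["g1_center"].set(value=c1, min=lo, max=hi)
    # ordered centers: c2 = c1 + d21, c3 = c2 + d32 with positive offsets
    p.add("d21", value=c2 - c1, min=bin_width)
    p.add("d32", value=c3 - c2, min=bin_width)
    p["g2_center"].set(expr="g1_center + d21")
    p["g3_center"].set(expr="g2_center + d32")
    total_mass = max(density.sum() * bin_width, 1e-12)
    for i in (1, 2, 3):
        p[f"g{i}_sigma"].set(value=init_sigma, min=1e-4, max=(hi - lo))
        p[f"g{i}_amplitude"].set(value=total_mass / 3, min=0.0)
    result = model.fit(density, p, x=centers)
    if not result.success:
        raise RuntimeError(f"3-Gaussian fit failed: {result.message}")

    comps = []
    for i in (1, 2, 3):
        sigma = float(result.params[f"g{i}_sigma"].value)
        height = float(result.params[f"g{i}_height"].value)
        comps.append(
            GaussianComponent(
                amplitude=height,
                center=float(result.params[f"g{i}_center"].value),
                sigma=sigma,
                collapsed=sigma < bin_width / 2,
            )
        )
    areas = np.array([c.area for c in comps])
    shares = 100.0 * areas / areas.sum()
    pct = {"LF": 0.0, "MF": 0.0, "HF": 0.0}
    for comp, share in zip(comps, shares):
        pct[comp.kind] += float(share)
    summary = PopulationSummary(
        lf_percent=pct["LF"], mf_percent=pct["MF"], hf_percent=pct["HF"], n_traces=n_traces
    )
    return comps, summary


def qc_preparation(summary: PopulationSummary) -> bool:
    """Preparation quality gate under compaction conditions.

    The LF population at high salt / Mg2+ reports uncompacted (defective)
    fibers; a preparation passes only if LF% is strictly below 50.
    """
    passed = summary.lf_percent < 50.0
    summary.qc_pass = passed
    return passed
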