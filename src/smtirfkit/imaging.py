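"""Image processing for two-channel smTIRF movies.

Rolling-ball background subtraction, local-maxima spot detection with 2D
Gaussian PSF refinement, SNR scoring, phase-correlation drift estimation,
fiducial-based affine channel registration, and locator/binder colocalization.
Coordinates are 0-based (row, col) with sub-pixel positions referring to pixel
centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball
from skimage.transform import resize, resize_local_mean

__all__ = [
    "SpotDetection",
    "RegistrationTransform",
    "DriftTrack",
    "subtract_background",
    "detect_spots",
    "fit_psf",
    "filter_by_width",
    "compute_snr",
    "estimate_drift",
    "apply_drift",
    "build_registration",
    "colocalize",
]


@dataclass
class SpotDetection:
    """A fitted diffraction-limited spot in one frame."""

    y: float
    x: float
    amplitude: float
    psf_sigma_fit: float
    frame: int = 0
    snr: float = np.nan
    offset: float = 0.0
    converged: bool = True


@dataclass
class RegistrationTransform:
    """Affine mapping between donor and acceptor channel coordinates."""

    matrix: np.ndarray  # 2x3, maps (y, x) -> (y', x')
    rms_residual: float
    n_fiducials: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        aug = np.column_stack([coords, np.ones(len(coords))])
        return aug @ self.matrix.T

    def inverse(self) -> "RegistrationTransform":
        a = self.matrix[:, :2]
        b = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        m = np.column_stack([a_inv, -a_inv @ b])
        return RegistrationTransform(matrix=m, rms_residual=self.rms_residual, n_fiducials=self.n_fiducials)


@dataclass
class DriftTrack:
    """Per-frame stage drift (dy, dx) in pixels relative to frame 0."""

    dy: np.ndarray
    dx: np.ndarray
    warning: bool = False

    def __post_init__(self) -> None:
        if abs(self.dy[0]) > 1e-12 or abs(self.dx[0]) > 1e-12:
            raise ValueError("drift at frame 0 must be (0, 0)")


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------


def subtract_background(frame: np.ndarray, ball_radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction (ImageJ-style).

    For radii >= 16 px the image is shrunk by local averaging, the ball is
    rolled on the reduced image and the background is upscaled bilinearly —
    the same strategy ImageJ uses, which makes per-frame subtraction on long
    movies tractable.  Output is clipped at zero.
    """
    frame = np.asarray(frame, dtype=float)
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    if ball_radius >= min(frame.shape):
        raise ValueError("ball_radius must be smaller than the image")
    shrink = 1
    if ball_radius >= 16:
        shrink = 4 if ball_radius < 32 else 8
        shrink = min(shrink, min(frame.shape) // 16 or 1)
    if shrink > 1:
        small_shape = (frame.shape[0] // shrink, frame.shape[1] // shrink)
        small = resize_local_mean(frame, small_shape)
        bg_small = rolling_ball(small, radius=ball_radius / shrink)
        background = resize(bg_small, frame.shape, order=1)
    else:
        background = rolling_ball(frame, radius=ball_radius)
    return np.clip(frame - background, 0.0, None)


def subtract_background_stack(stack: np.ndarray, ball_radius: float = 50.0) -> np.ndarray:
    """Apply :func:`subtract_background` to every frame of a (T, H, W) stack."""
    return np.stack([subtract_background(f, ball_radius) for f in stack])


# ---------------------------------------------------------------------------
# Spot detection & PSF fitting
# ---------------------------------------------------------------------------


def fit_psf(
    frame: np.ndarray,
    seed_position: tuple[float, float],
    window: int = 9,
    sigma_guess: float = 1.3,
) -> SpotDetection:
    """Least-squares symmetric 2D Gaussian fit around a seed position.

    Returns a :class:`SpotDetection` with ``converged=False`` when the fit is
    degenerate (flat region, non-positive amplitude, or an implausible width),
    in which case the spot should be dropped.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    yc, xc = seed_position
    if not (0 <= yc < h and 0 <= xc < w):
        raise ValueError("seed position out of bounds")
    r = window // 2
    y0, y1 = int(round(yc)) - r, int(round(yc)) + r + 1
    x0, x1 = int(round(xc)) - r, int(round(xc)) + r + 1
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(h, y1), min(w, x1)
    patch = frame[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]

    offset0 = float(patch.min())
    amp0 = float(patch.max() - offset0)

    def residual(p):
        y, x, a, s, o = p
        return (a * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * s**2)) + o - patch).ravel()

    lower = [y0 - 1, x0 - 1, 0.0, 0.3, -np.inf]
    upper = [y1, x1, np.inf, float(window), np.inf]
    p0 = [yc, xc, max(amp0, 1e-6), sigma_guess, offset0]
    try:
        sol = least_squares(residual, p0, bounds=(lower, upper))
    except Exception:
        return SpotDetection(yc, xc, 0.0, sigma_guess, converged=False)
    y, x, a, s, o = sol.x
    converged = (
        bool(sol.success)
        and np.ptp(patch) > 0
        and a > 0.5 * patch.std()
        and 0.3 < s < window
    )
    return SpotDetection(y=float(y), x=float(x), amplitude=float(a), psf_sigma_fit=float(s), offset=float(o), converged=converged)


def detect_spots(
    frame: np.ndarray,
    threshold_sigma: float = 5.0,
    min_distance: int = 3,
    refine: bool = True,
    frame_index: int = 0,
) -> list[SpotDetection]:
    """Local-maxima spot detection on a background-subtracted frame.

    Candidate maxima must exceed ``mean + threshold_sigma * SD`` of the frame;
    each candidate is refined by a 2D Gaussian PSF fit and dropped if the fit
    does not converge.
    """
    frame = np.asarray(frame, dtype=float)
    thr = frame.mean() + threshold_sigma * frame.std()
    coords = peak_local_max(frame, min_distance=min_distance, threshold_abs=thr, exclude_border=2)
    detections: list[SpotDetection] = []
    for yc, xc in coords:
        if refine:
            det = fit_psf(frame, (float(yc), float(xc)))
            det.frame = frame_index
            if det.converged:
                detections.append(det)
        else:
            detections.append(
                SpotDetection(float(yc), float(xc), float(frame[yc, xc]), np.nan, frame=frame_index)
            )
    return detections


def filter_by_width(
    detections: list[SpotDetection],
    reference_sigma: float,
    max_ratio: float = 1.5,
) -> list[SpotDetection]:
    """Exclude spots whose fitted PSF width exceeds the single-dye reference.

    ``reference_sigma`` is typically the median fitted width of a calibration
    set of single dyes; spots wider than ``max_ratio`` times it are likely
    aggregates or out-of-focus particles and are removed.
    """
    return [d for d in detections if d.psf_sigma_fit <= max_ratio * reference_sigma]


def compute_snr(peak_pixels: np.ndarray, background_pixels: np.ndarray) -> float:
    """Signal-to-noise ratio SNR = (P − B) / sqrt(σ_P² + σ_B²)."""
    p = np.asarray(peak_pixels, dtype=float)
    b = np.asarray(background_pixels, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both regions must be non-empty")
    var = p.var() + b.var()
    if var == 0:
        raise ValueError("zero variance in both regions")
    return float((p.mean() - b.mean()) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------


def estimate_drift(locator_stack: np.ndarray, upsample_factor: int = 50) -> DriftTrack:
    """Estimate per-frame stage drift from the locator channel.

    Whole-frame phase correlation against frame 0 with sub-pixel upsampling.
    Featureless stacks yield zero drift and a warning flag.
    """
    stack = np.asarray(locator_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 frames")
    ref = stack[0]
    n = stack.shape[0]
    dy = np.zeros(n)
    dx = np.zeros(n)
    if ref.std() == 0:
        warnings.warn("featureless locator stack; assuming zero drift", stacklevel=2)
        return DriftTrack(dy=dy, dx=dx, warning=True)
    for k in range(1, n):
        # plain cross-correlation (not phase-whitened): sparse spot images with
        # Poisson noise give noisy phase spectra
        shift, _, _ = phase_cross_correlation(
            ref, stack[k], upsample_factor=upsample_factor, normalization=None
        )
        # `shift` moves frame k onto the reference; drift is the negative
        dy[k], dx[k] = -shift[0], -shift[1]
    return DriftTrack(dy=dy, dx=dx)


def apply_drift(stack: np.ndarray, drift: DriftTrack) -> np.ndarray:
    """Shift every frame back by its estimated drift (bilinear interpolation)."""
    stack = np.asarray(stack, dtype=float)
    out = np.empty_like(stack)
    for k in range(stack.shape[0]):
        out[k] = ndimage.shift(stack[k], (-drift.dy[k], -drift.dx[k]), order=1, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# Channel registration
# ---------------------------------------------------------------------------


def build_registration(
    source_points: np.ndarray,
    target_points: np.ndarray,
) -> RegistrationTransform:
    """Least-squares affine transform from fiducial pairs (e.g. nanoparticles
    visible in both channels).  Requires >= 3 non-collinear pairs."""
    src = np.asarray(source_points, dtype=float)
    dst = np.asarray(target_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (N, 2) arrays")
    n = len(src)
    if n < 3:
        raise ValueError("at least 3 fiducial pairs required for an affine fit")
    design = np.column_stack([src, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("fiducials are collinear or degenerate")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = sol.T  # 2x3
    residuals = design @ sol - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationTransform(matrix=matrix, rms_residual=rms, n_fiducials=n)


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------


def colocalize(
    locator_positions: np.ndarray,
    binder_detections: list[SpotDetection],
    radius_px: float = 2.0,
) -> dict[int, list[SpotDetection]]:
    """Assign binder detections to the nearest locator within ``radius_px``.

    Both inputs must be in a common drift-corrected, registered coordinate
    frame.  Detections with no locator within the radius are discarded; exact
    distance ties resolve to the lowest locator index.
    """
    locator_positions = np.atleast_2d(np.asarray(locator_positions, dtype=float))
    matched: dict[int, list[SpotDetection]] = {i: [] for i in range(len(locator_positions))}
    if len(locator_positions) == 0:
        return matched
    tree = cKDTree(locator_positions)
    for det in binder_detections:
        idx = tree.query_ball_point([det.y, det.x], r=radius_px)
        if not idx:
            continue
        d = np.hypot(locator_positions[idx, 0] - det.y, locator_positions[idx, 1] - det.x)
        best = min(zip(np.round(d, 12), idx))[1]  # tie -> lowest index
        matched[best].append(det)
    return matched
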