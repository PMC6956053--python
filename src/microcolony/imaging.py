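"""Time-lapse microchannel image analysis.

Pipeline for quantifying bacterial colonization of a confined microchannel
segment from micrographs taken every 10 min: per-frame contrast
normalization, straight-line Hough detection of the two channel borders,
rotation/crop rectification about the weighted centre of the enclosed
region, texture segmentation by percentile thresholding of a local-variance
statistic, and extraction of the classic growth phases (lag, exponential,
stationary) from the colonized-area time series.  The segmented-area
baseline of an empty channel is non-zero: channel borders and static image
artifacts contribute a constant offset (about 30% with default settings),
which the phase extraction estimates and reports separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import canny
from skimage.transform import hough_line, hough_line_peaks, resize, rotate

__all__ = [
    "FrameStack",
    "ChannelGeometry",
    "GrowthCurve",
    "BorderDetectionError",
    "preprocess_frame",
    "detect_channel_borders",
    "rectify_and_crop",
    "local_variance",
    "segment_bacteria",
    "colonized_fraction",
    "extract_growth_phases",
    "between_segment_lag",
    "check_segment_overlap",
    "analyze_stack",
]

log = logging.getLogger(__name__)


class BorderDetectionError(RuntimeError):
    """Raised when fewer than two usable border lines are found."""


@dataclass
class FrameStack:
    """Time-lapse frames of one microchannel segment."""

    frames: list[np.ndarray]
    timestamps: np.ndarray
    pixel_scale: float               # px per µm
    segment_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not self.frames:
            raise ValueError("empty stack")
        shape = np.asarray(self.frames[0]).shape
        for f in self.frames:
            if np.asarray(f).shape != shape:
                raise ValueError("all frames must share one shape")
        if len(self.frames) != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ChannelGeometry:
    """Two near-parallel border lines in (angle, offset) Hesse normal form.

    ``border_lines`` holds (theta_rad, rho_px) per line as returned by the
    straight-line Hough transform; ``inclination_deg`` is the channel tilt
    from horizontal, ``width_px`` the perpendicular inter-line distance.
    """

    border_lines: tuple[tuple[float, float], tuple[float, float]]
    inclination_deg: float
    width_px: float
    weighted_center: tuple[float, float]

    def __post_init__(self) -> None:
        a0 = np.degrees(self.border_lines[0][0])
        a1 = np.degrees(self.border_lines[1][0])
        if abs(a0 - a1) > 5.0:
            raise ValueError("border lines are not near-parallel")
        if self.width_px <= 0:
            raise ValueError("width_px must be positive")


@dataclass
class GrowthCurve:
    times: np.ndarray
    colonized_pct: np.ndarray
    offset_pct: float
    lag_end_s: Optional[float]
    stationary_start_s: Optional[float]
    colonization_duration_s: Optional[float]
    lag_only: bool = False
    between_segment_lag_s: Optional[float] = None


def preprocess_frame(frame: np.ndarray) -> np.ndarray:
    """Collapse to luminance and stretch intensities to [0, 255].

    A constant frame is returned unchanged (as float): there is no
    contrast to stretch.
    """
    a = np.asarray(frame, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=2)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a non-empty 2-D (or RGB) frame")
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return a
    return (a - lo) * (255.0 / (hi - lo))


def detect_channel_borders(
    frame: np.ndarray,
    angle_resolution_deg: float = 0.5,
    parallel_tol_deg: float = 5.0,
) -> ChannelGeometry:
    """Locate the two channel borders with a straight-line Hough transform.

    The edge map is a Canny detection whose thresholds adapt to the frame's
    own gradient statistics (the per-image-set threshold).  The two
    highest-scoring near-parallel lines win; anything less raises
    :class:`BorderDetectionError`, mirroring the rejection of obstructed
    microsystems.
    """
    img = preprocess_frame(frame)
    edges = canny(img / 255.0, sigma=2.0)
    if not edges.any():
        raise BorderDetectionError("no edges found")
    thetas = np.deg2rad(np.arange(-90.0, 90.0, angle_resolution_deg))
    h, angles, dists = hough_line(edges, theta=thetas)
    _, peak_angles, peak_dists = hough_line_peaks(
        h, angles, dists, num_peaks=10,
        min_distance=9, min_angle=3, threshold=0.3 * h.max())
    if len(peak_angles) < 2:
        raise BorderDetectionError("fewer than two line candidates")
    # best near-parallel pair among the top-scoring candidates
    pair = None
    for i in range(len(peak_angles)):
        for j in range(i + 1, len(peak_angles)):
            d_ang = np.degrees(abs(peak_angles[i] - peak_angles[j]))
            if d_ang <= parallel_tol_deg and \
                    abs(peak_dists[i] - peak_dists[j]) > 5:
                pair = (i, j)
                break
        if pair:
            break
    if pair is None:
        raise BorderDetectionError("no near-parallel line pair")
    i, j = pair
    lines = ((float(peak_angles[i]), float(peak_dists[i])),
             (float(peak_angles[j]), float(peak_dists[j])))
    # Hesse normal form: col*cos(theta) + row*sin(theta) = rho; a
    # horizontal line sits at |theta| = 90 deg, and an image rotated by
    # phi (counter-clockwise) moves it to theta = sign(phi) * (90 - |phi|)
    mean_theta = float(np.mean([peak_angles[i], peak_angles[j]]))
    theta_deg = np.degrees(mean_theta)
    inclination = float(np.sign(theta_deg) * (90.0 - abs(theta_deg)))
    width = float(abs(peak_dists[i] - peak_dists[j]))
    h_img, w_img = img.shape
    mid_col = w_img / 2.0
    rows = [(rho - mid_col * np.cos(th)) / np.sin(th)
            for th, rho in lines if np.sin(th) != 0]
    center = (float(np.mean(rows)), mid_col)
    return ChannelGeometry(border_lines=lines,
                           inclination_deg=inclination,
                           width_px=width,
                           weighted_center=center)


def rectify_and_crop(
    frame: np.ndarray,
    geometry: ChannelGeometry,
    target_shape: Optional[tuple[int, int]] = None,
    margin_px: int = 4,
) -> np.ndarray:
    """Rotate the channel to horizontal and crop to its interior + margin.

    Crops that would exceed the frame bounds are padded with the background
    median (and logged).  When ``target_shape`` is given the crop is resized
    to it.
    """
    img = np.asarray(preprocess_frame(frame))
    rotated = rotate(img, -geometry.inclination_deg,
                     center=(geometry.weighted_center[1],
                             geometry.weighted_center[0]),
                     preserve_range=True, mode="edge")
    # refine the crop anchor on the rotated image: the Hough offsets are
    # bin-quantized, the darkest row near each predicted border is not
    half_w = geometry.width_px / 2
    profile = rotated.mean(axis=1)
    row_c = geometry.weighted_center[0]
    rows = []
    for guess in (row_c - half_w, row_c + half_w):
        lo = max(0, int(round(guess)) - 8)
        hi = min(rotated.shape[0], int(round(guess)) + 9)
        if hi > lo:
            rows.append(lo + int(np.argmin(profile[lo:hi])))
    if len(rows) == 2 and rows[1] > rows[0]:
        row_c = 0.5 * (rows[0] + rows[1])
        half_w = 0.5 * (rows[1] - rows[0])
    half = half_w + margin_px
    lo = int(round(row_c - half))
    hi = int(round(row_c + half))
    h = rotated.shape[0]
    if lo < 0 or hi > h:
        log.warning("crop [%d, %d) exceeds frame height %d; padding", lo, hi, h)
        pad_lo, pad_hi = max(0, -lo), max(0, hi - h)
        fill = float(np.median(rotated))
        rotated = np.pad(rotated, ((pad_lo, pad_hi), (0, 0)),
                         constant_values=fill)
        lo += pad_lo
        hi += pad_lo
    crop = rotated[lo:hi]
    if target_shape is not None and crop.shape != tuple(target_shape):
        crop = resize(crop, target_shape, preserve_range=True,
                      anti_aliasing=True)
    return crop


def local_variance(frame: np.ndarray, window: int = 5) -> np.ndarray:
    """Local intensity variance in a ``window`` x ``window`` neighbourhood."""
    a = np.asarray(frame, dtype=float)
    m = uniform_filter(a, size=window, mode="reflect")
    m2 = uniform_filter(a * a, size=window, mode="reflect")
    return np.clip(m2 - m * m, 0.0, None)


def segment_bacteria(
    frame: np.ndarray,
    percentile_p: float = 70.0,
    threshold: Optional[float] = None,
    window: int = 5,
) -> np.ndarray:
    """Binary texture segmentation by percentile thresholding.

    Foreground (1) is where the local-variance texture statistic exceeds
    the ``percentile_p`` percentile of the frame-set distribution; pass
    ``threshold`` to reuse a value computed on a reference frame so that
    one threshold serves the whole image set.
    """
    v = local_variance(frame, window=window)
    if threshold is None:
        threshold = float(np.percentile(v, percentile_p))
    return (v > threshold).astype(np.uint8)


def colonized_fraction(mask: np.ndarray) -> float:
    """Foreground percentage of a binary mask."""
    m = np.asarray(mask)
    if m.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(np.count_nonzero(m)) / m.size


def extract_growth_phases(
    times: Sequence[float],
    colonized_pct: Sequence[float],
    rise_margin_pct: float = 3.0,
    derivative_floor_pct_per_frame: float = 0.5,
) -> GrowthCurve:
    """Identify lag, exponential and stationary phases of a growth curve.

    The offset is the robust mean (median) of the pre-growth plateau; the
    lag phase ends when the curve first exceeds the offset by
    ``rise_margin_pct``; the stationary phase starts at the first frame
    after the rise whose increment falls below the derivative floor.  A
    curve with no detected rise is flagged ``lag_only``.
    """
    t = np.asarray(times, dtype=float)
    pct = np.asarray(colonized_pct, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    base = float(np.median(pct[: max(3, t.size // 10)]))
    above = np.nonzero(pct > base + rise_margin_pct)[0]
    if above.size == 0:
        return GrowthCurve(times=t, colonized_pct=pct,
                           offset_pct=float(np.median(pct)),
                           lag_end_s=None, stationary_start_s=None,
                           colonization_duration_s=None, lag_only=True)
    lag_idx = int(above[0])
    offset = float(np.median(pct[:lag_idx])) if lag_idx else base
    d = np.diff(pct)
    flat = np.nonzero(d[lag_idx:] < derivative_floor_pct_per_frame)[0]
    if flat.size == 0:
        stat_idx = t.size - 1
    else:
        stat_idx = lag_idx + int(flat[0]) + 1
    return GrowthCurve(
        times=t, colonized_pct=pct, offset_pct=offset,
        lag_end_s=float(t[lag_idx]),
        stationary_start_s=float(t[stat_idx]),
        colonization_duration_s=float(t[stat_idx] - t[lag_idx]),
    )


def between_segment_lag(curve_a: GrowthCurve, curve_b: GrowthCurve) -> float:
    """Lag-phase end difference between two segments (b minus a)."""
    if curve_a.lag_end_s is None or curve_b.lag_end_s is None:
        raise ValueError("both curves need a detected lag end")
    return float(curve_b.lag_end_s - curve_a.lag_end_s)


def check_segment_overlap(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    nominal_overlap_um: float,
    pixel_scale: float,
) -> float:
    """Width (µm) of the widest contiguous band of agreed foreground.

    The last ``nominal_overlap_um`` of segment a images the same physical
    region as the first ``nominal_overlap_um`` of segment b; a column
    agrees when both masks show foreground there.
    """
    n = int(round(nominal_overlap_um * pixel_scale))
    if n <= 0 or mask_a.shape[0] != mask_b.shape[0]:
        log.warning("no usable overlap region")
        return 0.0
    n = min(n, mask_a.shape[1], mask_b.shape[1])
    tail = np.asarray(mask_a)[:, -n:] > 0
    head = np.asarray(mask_b)[:, :n] > 0
    agree = tail.any(axis=0) & head.any(axis=0)
    # longest run of agreeing columns
    best = run = 0
    for v in agree:
        run = run + 1 if v else 0
        best = max(best, run)
    return best / pixel_scale


def analyze_stack(
    stack: FrameStack,
    percentile_p: float = 70.0,
    reference_frame: int = 0,
    geometry: Optional[ChannelGeometry] = None,
    **phase_kwargs,
) -> tuple[GrowthCurve, ChannelGeometry, list[np.ndarray]]:
    """Full image pipeline for one segment stack.

    Border geometry and the segmentation threshold are determined on the
    reference frame (the image-set calibration) and applied to every
    frame; returns the growth curve, the geometry, and the binary masks.
    """
    if geometry is None:
        geometry = detect_channel_borders(stack.frames[reference_frame])
    rectified = [rectify_and_crop(f, geometry) for f in stack.frames]
    ref_v = local_variance(rectified[reference_frame])
    threshold = float(np.percentile(ref_v, percentile_p))
    masks = [segment_bacteria(f, threshold=threshold) for f in rectified]
    pct = np.array([colonized_fraction(m) for m in masks])
    curve = extract_growth_phases(stack.timestamps, pct, **phase_kwargs)
    return curve, geometry, masks
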