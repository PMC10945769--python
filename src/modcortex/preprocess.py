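"""Movie calibration: rigid registration, baseline estimation, dF/F, ROI masking.

A widefield recording enters the pipeline as a raw fluorescence stack
``F(t, y, x)``.  Slow drifts (bleaching, hemodynamic trends) are removed by a
per-pixel running temporal median F0, and activity is expressed as the
relative change dF/F = (F - F0) / F0.  Mild brain movement is corrected by
integer-pixel translation maximizing phase correlation with a reference frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


@dataclass
class Movie:
    """Calibrated fluorescence movie.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Raw fluorescence in arbitrary units.
    pixel_um : float
        Pixel pitch in micrometres.
    frame_rate_hz : float
        Sampling rate in Hz.
    roi_mask : ndarray of bool, shape (H, W)
        Pixels inside the analysis region of interest.
    meta : dict
        Free-form provenance.
    """

    data: np.ndarray
    pixel_um: float
    frame_rate_hz: float
    roi_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be a T x H x W array with T >= 1")
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.data.shape[1:]:
            raise ValueError("roi_mask shape must match frame shape")
        if not self.roi_mask.any():
            raise ValueError("roi_mask must contain at least one pixel")
        if not (self.pixel_um > 0 and self.frame_rate_hz > 0):
            raise ValueError("pixel_um and frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class DffMovie:
    """Baseline-corrected movie holding dF/F = (F - F0)/F0."""

    data: np.ndarray
    baseline: np.ndarray
    pixel_um: float
    frame_rate_hz: float
    roi_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def roi_mean_trace(self) -> np.ndarray:
        """Mean dF/F over ROI pixels, one value per frame."""
        return self.data[:, self.roi_mask].mean(axis=1)


def _shift_frame(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate by integer pixels, filling exposed borders with the edge value."""
    return ndimage.shift(frame, (dy, dx), order=0, mode="nearest")


def register_translation(
    movie: Movie, reference_frame_index: int = 0
) -> tuple[Movie, np.ndarray]:
    """Rigidly register each frame to a common reference frame.

    The integer-pixel translation maximizing phase correlation with the
    reference frame is applied to every frame.

    Returns the registered movie and the applied per-frame (dy, dx) shifts.
    """
    if not 0 <= reference_frame_index < movie.n_frames:
        raise ValueError("reference_frame_index out of range")
    ref = np.asarray(movie.data[reference_frame_index], dtype=float)
    out = np.empty_like(movie.data, dtype=float)
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    for t in range(movie.n_frames):
        frame = np.asarray(movie.data[t], dtype=float)
        if not np.any(frame):
            warnings.warn(f"frame {t} is all zero; using zero shift")
            out[t] = frame
            continue
        if t == reference_frame_index:
            out[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts[t] = (dy, dx)
        out[t] = _shift_frame(frame, dy, dx) if (dy or dx) else frame
    registered = replace(movie, data=out, meta={**movie.meta, "registered": True})
    return registered, shifts


def _running_median(
    data: np.ndarray, window: int, stride: int = 1
) -> np.ndarray:
    """Centered running median along axis 0 with reflect padding.

    With ``stride > 1`` the median is evaluated on a regular subgrid of
    frames and linearly interpolated in between, which is accurate for the
    slow baselines this filter is meant to follow.
    """
    T = data.shape[0]
    half = window // 2
    if stride == 1:
        return ndimage.median_filter(
            data, size=(window,) + (1,) * (data.ndim - 1), mode="reflect"
        )
    sample_t = np.arange(0, T, stride)
    padded = np.concatenate(
        [data[1 : half + 1][::-1], data, data[-half - 1 : -1][::-1]], axis=0
    )
    flat = padded.reshape(padded.shape[0], -1)
    # medians are also evaluated on a within-window frame subsample (<= 45
    # frames): the window median tracks trends far slower than the frame
    # rate, so the strided estimate is statistically equivalent
    step = max(1, window // 45)
    med = np.empty((sample_t.size, flat.shape[1]), dtype=np.float32)
    for i, t in enumerate(sample_t):
        med[i] = np.median(flat[t : t + window : step], axis=0)
    # vectorized linear interpolation between the sampled medians
    t_all = np.arange(T)
    hi = np.clip(np.searchsorted(sample_t, t_all, side="right"), 1, sample_t.size - 1)
    lo = hi - 1
    denom = np.maximum(sample_t[hi] - sample_t[lo], 1)
    w = np.clip((t_all - sample_t[lo]) / denom, 0.0, 1.0).astype(np.float32)[:, None]
    out = med[lo] * (1.0 - w) + med[hi] * w
    return out.reshape(data.shape)


def compute_dff(
    movie: Movie,
    baseline_window_s: float = 15.0,
    baseline_stride: int = 1,
) -> DffMovie:
    """Convert raw fluorescence to dF/F with a running-median baseline.

    F0 is the per-pixel temporal median over a centered window of
    ``baseline_window_s`` seconds (the slow trend of the trace); the output is
    (F - F0) / F0.

    Parameters
    ----------
    baseline_window_s : float
        Median window length in seconds; sessions in this preparation use
        windows of 10-23 s.
    baseline_stride : int
        Evaluate the median every ``baseline_stride`` frames and interpolate;
        1 computes it exactly at every frame.
    """
    window = int(round(baseline_window_s * movie.frame_rate_hz))
    if window % 2 == 0:
        window += 1
    if window < 3:
        raise ValueError("baseline window must span at least 3 frames")
    data = np.asarray(movie.data, dtype=np.float32)
    f0 = _running_median(data, window, stride=baseline_stride).astype(np.float32)
    bad = (f0 <= 0).any(axis=0) & movie.roi_mask
    if bad.any():
        ys, xs = np.nonzero(bad)
        raise ValueError(
            f"baseline F0 <= 0 inside ROI at {bad.sum()} pixels, "
            f"e.g. (row, col) = ({ys[0]}, {xs[0]})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (data - f0) / f0
    dff[:, ~movie.roi_mask] = np.nan_to_num(dff[:, ~movie.roi_mask])
    return DffMovie(
        data=dff,
        baseline=f0,
        pixel_um=movie.pixel_um,
        frame_rate_hz=movie.frame_rate_hz,
        roi_mask=movie.roi_mask.copy(),
        meta={**movie.meta, "baseline_window_s": baseline_window_s},
    )


def apply_roi(dff: DffMovie, extra_masks: list[np.ndarray]) -> DffMovie:
    """Intersect the movie ROI with additional masks (e.g. artifact exclusions)."""
    mask = dff.roi_mask.copy()
    for m in extra_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != mask.shape:
            raise ValueError("extra mask shape does not match frame shape")
        mask &= m
    if not mask.any():
        raise ValueError("ROI intersection is empty")
    return DffMovie(
        data=dff.data,
        baseline=dff.baseline,
        pixel_um=dff.pixel_um,
        frame_rate_hz=dff.frame_rate_hz,
        roi_mask=mask,
        meta=dict(dff.meta),
    )
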