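"""Regularity and spacing of modular activity patterns.

For each band-pass-filtered event pattern the 2-D spatial autocorrelation is
computed (mask-corrected so the irregular ROI does not bias it), radially
averaged, and summarized by two scalars: the wavelength Lambda, twice the
distance to the first minimum of the radial profile, and the modularity, the
absolute difference between the first minimum and the subsequent maximum.
For an annular-spectrum random field the radial autocorrelation follows
J0(2*pi*r/Lambda_F), placing the first minimum at r = 0.6098 * Lambda_F; this
closed form serves as the analytic oracle for both estimators.

Module amplitude is computed on the unfiltered dF/F event frame: the value at
each activity peak divided by the median dF/F on the ring half a wavelength
away, averaged over peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage


@dataclass
class RadialAutocorr:
    """Radially averaged, normalized spatial autocorrelation."""

    r_mm: np.ndarray          # ascending annulus centers
    values: np.ndarray        # mean autocorrelation per annulus
    n_pixels: np.ndarray      # lag-pixel count per annulus


@dataclass
class ModularityResult:
    """Per-event wavelength and modularity with FOV-level summary."""

    wavelength_mm: np.ndarray
    modularity: np.ndarray
    flags: list[str]
    median_wavelength_mm: float = np.nan
    median_modularity: float = np.nan
    p_value: float = np.nan


@dataclass
class ModuleAmplitudeResult:
    amplitude: float                 # mean over peaks of peak / background
    peak_positions: np.ndarray       # (n_peaks, 2) as (row, col)
    peak_amplitudes: np.ndarray
    background_ring_mm: float        # Lambda / 2
    flags: list[str] = field(default_factory=list)


def spatial_autocorr_radial(
    pattern: np.ndarray,
    mask: np.ndarray,
    pixel_um: float,
    max_r_mm: float | None = None,
) -> RadialAutocorr:
    """Mask-corrected radial average of the spatial autocorrelation.

    The 2-D autocovariance is computed by FFT with zero padding (no
    wrap-around) and divided lag-by-lag by the overlap count of valid mask
    pixels, then normalized to 1 at zero lag and averaged over one-pixel-wide
    annuli.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(pattern, dtype=float)[mask]
    if vals.std() == 0:
        raise ValueError("constant pattern: autocorrelation undefined")
    h, w = pattern.shape
    a = np.where(mask, pattern - vals.mean(), 0.0)
    m = mask.astype(float)
    sh, sw = 2 * h, 2 * w
    fa = sfft.rfft2(a, s=(sh, sw))
    fm = sfft.rfft2(m, s=(sh, sw))
    num = sfft.irfft2(fa * np.conj(fa), s=(sh, sw))
    cnt = sfft.irfft2(fm * np.conj(fm), s=(sh, sw))
    num = sfft.fftshift(num)[sh // 2 - h : sh // 2 + h, sw // 2 - w : sw // 2 + w]
    cnt = sfft.fftshift(cnt)[sh // 2 - h : sh // 2 + h, sw // 2 - w : sw // 2 + w]
    cnt = np.round(cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    cy, cx = h, w  # zero-lag position after the crop above
    acf0 = acf[cy, cx]
    acf = acf / acf0

    yy, xx = np.mgrid[0 : 2 * h, 0 : 2 * w]
    r_px = np.hypot(yy - cy, xx - cx)
    if max_r_mm is None:
        max_r_mm = min(h, w) * pixel_um / 1000.0 / 2.0
    max_r_px = max_r_mm * 1000.0 / pixel_um
    nbins = int(np.floor(max_r_px)) + 1
    bin_idx = np.round(r_px).astype(int)
    good = np.isfinite(acf) & (bin_idx < nbins) & (cnt > 0)
    sums = np.bincount(bin_idx[good], weights=acf[good], minlength=nbins)
    counts = np.bincount(bin_idx[good], minlength=nbins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    r_mm = np.arange(nbins) * pixel_um / 1000.0
    return RadialAutocorr(r_mm=r_mm, values=profile, n_pixels=counts)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin refinement of an extremum across the 3 points around index i.

    Extrema adjacent to the zero-lag bin are left unrefined: the lag-0 value
    of a noisy autocorrelation is a cusp (it carries the full noise
    variance), and a parabola through it badly overshoots.
    """
    if i <= 1 or i >= y.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = x[1] - x[0]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def _first_interior_minimum(values: np.ndarray) -> int | None:
    """Index of the first strict interior local minimum (ties break earlier)."""
    v = values
    for i in range(1, v.size - 1):
        if not (np.isfinite(v[i - 1]) and np.isfinite(v[i]) and np.isfinite(v[i + 1])):
            continue
        if v[i] < v[i - 1] and v[i] < v[i + 1]:
            return i
    return None


def estimate_wavelength(rad: RadialAutocorr) -> tuple[float, str | None]:
    """Wavelength Lambda = twice the distance to the first radial minimum.

    The minimum position is refined parabolically across its 3 surrounding
    bins.  A profile without an interior minimum is flagged and returns NaN.
    """
    i = _first_interior_minimum(rad.values)
    if i is None:
        return np.nan, "no-minimum-found"
    r_min, _ = _parabolic_refine(rad.r_mm, rad.values, i)
    return 2.0 * r_min, None


def estimate_modularity(rad: RadialAutocorr) -> tuple[float, str | None]:
    """|amplitude difference| between the first minimum and next maximum.

    If no strict interior maximum follows the first minimum, the global
    maximum beyond the minimum is used; if even that is undefined the event
    is flagged.
    """
    i = _first_interior_minimum(rad.values)
    if i is None:
        return np.nan, "no-minimum-found"
    _, v_min = _parabolic_refine(rad.r_mm, rad.values, i)
    v = rad.values
    j = None
    for k in range(i + 1, v.size - 1):
        if not (np.isfinite(v[k - 1]) and np.isfinite(v[k]) and np.isfinite(v[k + 1])):
            continue
        if v[k] > v[k - 1] and v[k] > v[k + 1]:
            j = k
            break
    if j is not None:
        _, v_max = _parabolic_refine(rad.r_mm, v, j)
    else:
        tail = v[i + 1 :]
        if not np.isfinite(tail).any():
            return np.nan, "no-maximum-found"
        v_max = float(np.nanmax(tail))
    return abs(v_max - v_min), None


def modularity_of_patterns(
    patterns: np.ndarray,
    mask: np.ndarray,
    pixel_um: float,
    max_r_mm: float | None = None,
) -> ModularityResult:
    """Wavelength and modularity for each pattern in a stack."""
    n = patterns.shape[0]
    wl = np.full(n, np.nan)
    mod = np.full(n, np.nan)
    flags: list[str] = []
    for i in range(n):
        try:
            rad = spatial_autocorr_radial(patterns[i], mask, pixel_um, max_r_mm)
        except ValueError:
            flags.append(f"event {i}: constant pattern")
            continue
        wl[i], f1 = estimate_wavelength(rad)
        mod[i], f2 = estimate_modularity(rad)
        for f in (f1, f2):
            if f:
                flags.append(f"event {i}: {f}")
    return ModularityResult(
        wavelength_mm=wl,
        modularity=mod,
        flags=flags,
        median_wavelength_mm=float(np.nanmedian(wl)) if np.isfinite(wl).any() else np.nan,
        median_modularity=float(np.nanmedian(mod)) if np.isfinite(mod).any() else np.nan,
    )


def modularity_significance(
    event_modularity: np.ndarray,
    control_frame_modularity: dict[int, float],
    control_sets: list[np.ndarray],
) -> dict:
    """Bootstrap significance of event modularity against control frames.

    ``control_frame_modularity`` maps frame index to that frame's modularity
    (computed through the same filter + autocorrelation pipeline as events).
    For each of the (typically 100) event-count-matched control sets the
    median modularity is taken; the p-value is the fraction of control-set
    medians >= the median modularity over real events.
    """
    real = np.nanmedian(np.asarray(event_modularity, dtype=float))
    if not np.isfinite(real):
        raise ValueError("no finite event modularity values")
    medians = []
    for s in control_sets:
        vals = np.array([control_frame_modularity[int(f)] for f in s], dtype=float)
        if np.isfinite(vals).any():
            medians.append(np.nanmedian(vals))
    if not medians:
        raise ValueError("all control sets produced undefined modularity")
    medians = np.asarray(medians)
    p = float((medians >= real).sum() / medians.size)
    return {
        "median_event_modularity": float(real),
        "control_medians": medians,
        "p_value": p,
        "p_reported": max(p, 1.0 / medians.size),
        "n_sets": int(medians.size),
    }


def module_amplitude(
    event_raw_pattern: np.ndarray,
    mask: np.ndarray,
    pixel_um: float,
    wavelength_mm: float,
    smooth_sd_frac: float = 1.0 / 8.0,
    mad_factor: float = 2.0,
) -> ModuleAmplitudeResult:
    """Peak-to-background amplitude of modules in an unfiltered event frame.

    Peaks are local maxima of the Gaussian pre-smoothed frame (SD =
    ``smooth_sd_frac`` * Lambda) exceeding median + ``mad_factor`` * MAD of
    the frame; each peak's amplitude is its raw dF/F divided by the median
    raw dF/F on the one-pixel-wide ring Lambda/2 away (within the ROI).
    """
    if not np.isfinite(wavelength_mm) or wavelength_mm <= 0:
        raise ValueError("wavelength must be positive and finite")
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(event_raw_pattern, dtype=float)
    sd_px = smooth_sd_frac * wavelength_mm * 1000.0 / pixel_um
    smooth = ndimage.gaussian_filter(np.where(mask, img, 0.0), sd_px)
    norm = ndimage.gaussian_filter(mask.astype(float), sd_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth = np.where(mask, smooth / norm, -np.inf)
    vals = img[mask]
    thresh = np.median(vals) + mad_factor * np.median(np.abs(vals - np.median(vals)))
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(
        smooth, footprint=footprint, mode="constant", cval=-np.inf
    )
    peaks = (smooth > neighbor_max) & mask & (smooth > thresh)
    ys, xs = np.nonzero(peaks)
    if ys.size == 0:
        return ModuleAmplitudeResult(
            amplitude=np.nan,
            peak_positions=np.empty((0, 2), dtype=int),
            peak_amplitudes=np.empty(0),
            background_ring_mm=wavelength_mm / 2.0,
            flags=["no-peaks-found"],
        )
    ring_px = wavelength_mm / 2.0 * 1000.0 / pixel_um
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    amps = []
    kept = []
    for y, x in zip(ys, xs):
        d = np.hypot(yy - y, xx - x)
        ring = (np.abs(d - ring_px) <= 0.5) & mask
        if not ring.any():
            continue
        bg = float(np.median(img[ring]))
        if bg <= 0:
            continue
        amps.append(float(img[y, x] / bg))
        kept.append((int(y), int(x)))
    if not amps:
        return ModuleAmplitudeResult(
            amplitude=np.nan,
            peak_positions=np.empty((0, 2), dtype=int),
            peak_amplitudes=np.empty(0),
            background_ring_mm=wavelength_mm / 2.0,
            flags=["no-valid-background"],
        )
    return ModuleAmplitudeResult(
        amplitude=float(np.mean(amps)),
        peak_positions=np.asarray(kept, dtype=int),
        peak_amplitudes=np.asarray(amps),
        background_ring_mm=wavelength_mm / 2.0,
    )
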