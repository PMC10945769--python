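"""Synthetic widefield movies and cellular recordings with known ground truth.

The generator emulates the statistical structure of spontaneous activity in
the developing cortex: spatially band-limited modular patterns (Gaussian
random fields with an annular power spectrum centered on wavelength Lambda),
event ensembles spanned by a controllable number of basis patterns, calcium
indicator kinetics at ~15 Hz with slow baseline drift, and cellular traces
sampled from the underlying field with cell noise and neuropil contamination.

The annular (ring) spectrum is chosen because its autocorrelation has a
closed-form J0(k0 r) expectation, giving an analytic oracle for the
wavelength estimator: the first minimum of J0 sits at k0 r = 3.8317, i.e. at
r = 0.6098 * Lambda, so the estimated wavelength 2 * r_min = 1.2196 * Lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from modcortex.preprocess import Movie

# first positive minimum of the Bessel function J0(x)
J0_FIRST_MIN = 3.8317


@dataclass
class SynthParams:
    """Parameters of the synthetic recording.

    The defaults describe a single widefield field of view of the developing
    cortex: a ~3.0 x 2.6 mm window on a 160 x 135 grid (19 um/pixel, the
    downsampled analysis grid), modular activity with a 0.9 mm wavelength,
    events every ~50 s sampled at 15 Hz with GCaMP6s-like kinetics, and a
    peak event amplitude of 10x the pixel noise floor.
    """

    fov_mm: float = 3.04            # field width (mm)
    fov_height_mm: float | None = None  # default: 135/160 of fov_mm
    pixel_um: float = 19.0
    wavelength_mm: float = 0.9      # target Fourier wavelength Lambda_F
    spectral_bandwidth: float = 0.15  # annulus width relative to k0
    n_basis: int = 8
    n_events: int = 100
    frame_rate_hz: float = 15.0
    event_rate_hz: float = 0.02     # sparse events, one per ~50 s
    indicator_rise_s: float = 0.2
    indicator_decay_s: float = 2.0
    pattern_noise_sd: float = 0.1   # per-event unstructured noise, rel. to pattern SD
    pixel_noise_sd: float = 0.05    # per-frame sensor noise, dF/F units
    n_cells: int = 150
    cell_noise_sd: float = 0.1
    neuropil_weight: float = 0.3    # fraction of local field mixed into raw trace
    seed: int = 0
    # generator shape details
    event_amplitude: float = 0.5    # peak dF/F of a planted event
    event_offset: float = 2.0       # uniform activation offset, pattern-SD units
    orthogonalize_basis: bool = True
    baseline_counts: float = 100.0  # mean raw fluorescence level
    drift_amplitude: float = 0.03   # relative amplitude of slow baseline drift
    drift_period_s: float = 120.0
    cell_fov_mm: float = 1.2        # side of the centered square holding cells

    def __post_init__(self) -> None:
        if self.fov_height_mm is None:
            self.fov_height_mm = self.fov_mm * 135.0 / 160.0
        positive = {
            "fov_mm": self.fov_mm,
            "fov_height_mm": self.fov_height_mm,
            "pixel_um": self.pixel_um,
            "wavelength_mm": self.wavelength_mm,
            "spectral_bandwidth": self.spectral_bandwidth,
            "frame_rate_hz": self.frame_rate_hz,
            "event_rate_hz": self.event_rate_hz,
            "indicator_rise_s": self.indicator_rise_s,
            "indicator_decay_s": self.indicator_decay_s,
            "event_amplitude": self.event_amplitude,
            "baseline_counts": self.baseline_counts,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.n_events > 0 and self.n_basis > self.n_events:
            raise ValueError("n_basis must not exceed n_events")
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if self.pixel_um > 1000.0 * self.wavelength_mm / 4.0:
            raise ValueError(
                "grid too coarse: need at least 4 pixels per wavelength "
                f"(pixel_um={self.pixel_um}, wavelength_mm={self.wavelength_mm})"
            )
        if self.indicator_rise_s >= self.indicator_decay_s:
            raise ValueError("indicator_rise_s must be below indicator_decay_s")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(H, W) pixel grid implied by FOV and pixel pitch."""
        ny = int(round(self.fov_height_mm * 1000.0 / self.pixel_um))
        nx = int(round(self.fov_mm * 1000.0 / self.pixel_um))
        return ny, nx

    def roi_mask(self) -> np.ndarray:
        return np.ones(self.grid_shape, dtype=bool)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic recording."""

    basis_patterns: np.ndarray | None = None      # (n_basis, H, W)
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    event_coefficients: np.ndarray | None = None  # (n_events, n_basis)
    cell_positions: np.ndarray | None = None      # (n_cells, 2) in um, (x, y)
    cell_field_values: np.ndarray | None = None   # (n_events, n_cells)


def _grf_stack(
    n: int, shape: tuple[int, int], pixel_um: float, k0_per_um: float,
    rel_bandwidth: float, rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random fields with annular power spectrum centered at k0."""
    ny, nx = shape
    ky = np.fft.fftfreq(ny, d=pixel_um) * 2 * np.pi
    kx = np.fft.fftfreq(nx, d=pixel_um) * 2 * np.pi
    kr = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    sigma_k = rel_bandwidth * k0_per_um
    amp = np.exp(-0.5 * ((kr - k0_per_um) / sigma_k) ** 2)
    amp[0, 0] = 0.0  # no DC
    white = rng.standard_normal((n, ny, nx))
    fields = np.fft.ifft2(np.fft.fft2(white, axes=(1, 2)) * amp, axes=(1, 2)).real
    return fields


def make_modular_basis(
    params: SynthParams,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Generate zero-mean, unit-SD modular basis fields.

    Each field is a Gaussian random field whose power spectrum is an annulus
    at k0 = 2*pi/Lambda_F with relative width ``spectral_bandwidth``.  With
    ``orthogonalize_basis`` the fields are Gram-Schmidt orthogonalized under
    the ROI-weighted inner product (and re-standardized, which preserves
    orthogonality).
    """
    if n is None:
        n = params.n_basis
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = params.grid_shape
    mask = params.roi_mask()
    k0 = 2 * np.pi / (params.wavelength_mm * 1000.0)
    fields = _grf_stack(n, shape, params.pixel_um, k0, params.spectral_bandwidth, rng)
    flat = fields[:, mask]
    flat = flat - flat.mean(axis=1, keepdims=True)
    if params.orthogonalize_basis and n > 1:
        for i in range(n):
            for j in range(i):
                proj = flat[i] @ flat[j] / (flat[j] @ flat[j])
                flat[i] -= proj * flat[j]
            flat[i] -= flat[i].mean()
    flat /= flat.std(axis=1, keepdims=True)
    out = []
    for i in range(n):
        f = np.zeros(shape)
        f[mask] = flat[i]
        out.append(f)
    return out


def synth_event_patterns(
    basis: list[np.ndarray],
    params: SynthParams,
    rng: np.random.Generator | None = None,
    coefficients: np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Build raw event patterns as rectified random mixtures of the basis.

    Each pattern is the nonnegative (half-wave rectified) part of a random
    Gaussian mixture of the basis, riding on an activation offset of
    ``event_offset`` mixture-SD units, plus ``pattern_noise_sd`` fresh field
    noise; mixing coefficients are recorded in the returned ground truth.

    The offset emulates the spatially extended activation of real event
    frames, where inter-module cortex is elevated (module peak / background
    of roughly 3) rather than silent.  It also keeps rectification a mild
    nonlinearity (only the deep negative tail clips), so the ensemble
    covariance remains that of the planted mixture and the effective
    dimensionality of the ensemble is controlled by ``n_basis``.  With
    ``event_offset = 0`` patterns reduce to pure half-wave rectified
    mixtures.
    """
    if len(basis) == 0:
        raise ValueError("basis must be nonempty")
    shape = basis[0].shape
    if params.n_events == 0:
        return (
            np.empty((0,) + shape),
            GroundTruth(
                basis_patterns=np.stack(basis),
                event_coefficients=np.empty((0, len(basis))),
            ),
        )
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    nb = len(basis)
    if coefficients is not None:
        coeffs = np.asarray(coefficients, dtype=float)
        if coeffs.shape != (params.n_events, nb):
            raise ValueError("coefficients must be (n_events, n_basis)")
    else:
        coeffs = rng.standard_normal((params.n_events, nb))
    stack = np.stack(basis)
    mixed = np.tensordot(coeffs, stack, axes=(1, 0))
    sd_mix = mixed.std(axis=(1, 2), keepdims=True)
    sd_mix[sd_mix == 0] = 1.0
    if params.pattern_noise_sd > 0:
        k0 = 2 * np.pi / (params.wavelength_mm * 1000.0)
        noise = _grf_stack(
            params.n_events, shape, params.pixel_um, k0,
            params.spectral_bandwidth, rng,
        )
        noise /= noise.std(axis=(1, 2), keepdims=True)
        mixed = mixed + params.pattern_noise_sd * sd_mix * noise
    patterns = np.maximum(mixed + params.event_offset * sd_mix, 0.0)
    truth = GroundTruth(basis_patterns=stack, event_coefficients=coeffs)
    return patterns, truth


def calcium_kernel(params: SynthParams) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, normalized to unit peak."""
    rate = params.frame_rate_hz
    t = np.arange(0.0, params.indicator_rise_s + 6.0 * params.indicator_decay_s, 1.0 / rate)
    k = np.exp(-t / params.indicator_decay_s) - np.exp(-t / params.indicator_rise_s)
    k /= k.max()
    return k


def _event_profiles(patterns: np.ndarray, params: SynthParams) -> np.ndarray:
    """Spatial dF/F profile of each planted event.

    Event patterns already carry the activation offset (see
    :func:`synth_event_patterns`); here each is scaled so that the
    offset-plus-one-SD level — a typical module flank — reaches
    ``event_amplitude`` in dF/F.
    """
    sd = patterns.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return params.event_amplitude * patterns / (sd * (params.event_offset + 1.0))


def synth_widefield_movie(
    params: SynthParams,
    return_clean_dff: bool = False,
) -> tuple[Movie, GroundTruth]:
    """Generate a raw widefield movie with planted modular events.

    The movie is ``baseline(t) * (1 + s(x, t)) + noise`` where the baseline
    carries a slow multiplicative drift and ``s`` sums the planted event
    profiles convolved with the indicator kernel.  Events are placed on a
    regular schedule (one per ``1/event_rate_hz`` seconds) with random
    within-slot jitter, guaranteeing quiet inter-event frames.  Ground-truth
    ``event_times`` record the frame of each event's kernel peak.
    """
    rng = np.random.default_rng(params.seed)
    basis = make_modular_basis(params, rng=rng)
    patterns, truth = synth_event_patterns(basis, params, rng=rng)
    kernel = calcium_kernel(params)
    rate = params.frame_rate_hz
    slot = int(round(rate / params.event_rate_hz))
    span = kernel.size
    if params.n_events > 0 and slot < span + int(2 * rate):
        raise ValueError(
            "event_rate_hz too high for non-overlapping events: "
            f"slot of {slot} frames < event span of {span} frames plus margin"
        )
    n_frames = max(slot * max(params.n_events, 1) + int(5 * rate), int(20 * rate))
    shape = params.grid_shape
    mask = params.roi_mask()

    onset_frames = np.empty(params.n_events, dtype=int)
    jitter_max = max(slot - span - int(rate), 1)
    for i in range(params.n_events):
        onset_frames[i] = i * slot + int(rate) + rng.integers(0, jitter_max)
    peak_offset = int(np.argmax(kernel))
    truth.event_times = onset_frames + peak_offset

    signal = np.zeros((n_frames,) + shape, dtype=np.float32)
    if params.n_events > 0:
        profiles = _event_profiles(patterns, params).astype(np.float32)
        for i, onset in enumerate(onset_frames):
            stop = min(onset + span, n_frames)
            signal[onset:stop] += kernel[: stop - onset, None, None].astype(
                np.float32
            ) * profiles[i]

    t_s = np.arange(n_frames) / rate
    drift = 1.0 + params.drift_amplitude * np.sin(
        2 * np.pi * t_s / params.drift_period_s
    )
    baseline = (params.baseline_counts * drift).astype(np.float32)
    data = baseline[:, None, None] * (1.0 + signal)
    if params.pixel_noise_sd > 0:
        data = data + (
            np.float32(params.pixel_noise_sd * params.baseline_counts)
        ) * rng.standard_normal(data.shape, dtype=np.float32)
    movie = Movie(
        data=data,
        pixel_um=params.pixel_um,
        frame_rate_hz=rate,
        roi_mask=mask,
        meta={"synthetic": True, "n_events": params.n_events},
    )
    if return_clean_dff:
        movie.meta["clean_dff"] = signal
    return movie, truth


def synth_cell_recording(
    params: SynthParams,
    field_movie: Movie,
    truth: GroundTruth,
    salt_and_pepper: bool = False,
    rng: np.random.Generator | None = None,
):
    """Sample a cellular recording from an underlying field movie.

    Each raw cell trace is the field value at the cell position (bilinear),
    contaminated by ``neuropil_weight`` times the local field average in a
    20 um window and additive cell noise.  The neuropil trace itself (the
    local field average) is returned alongside.  With ``salt_and_pepper`` the
    reported cell positions are randomly permuted among cells, destroying the
    spatial coherence of the recording while preserving every trace.
    """
    from modcortex.cellular import CellRecording

    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    ny, nx = field_movie.frame_shape
    pix = field_movie.pixel_um
    side_um = params.cell_fov_mm * 1000.0
    cx_um, cy_um = nx * pix / 2.0, ny * pix / 2.0
    if side_um > nx * pix or side_um > ny * pix:
        raise ValueError("cell_fov_mm exceeds the field of view")
    xs = cx_um + (rng.random(params.n_cells) - 0.5) * side_um
    ys = cy_um + (rng.random(params.n_cells) - 0.5) * side_um
    positions = np.column_stack([xs, ys])

    cols = np.clip(xs / pix - 0.5, 0, nx - 1.001)
    rows = np.clip(ys / pix - 0.5, 0, ny - 1.001)
    r0, c0 = np.floor(rows).astype(int), np.floor(cols).astype(int)
    fr, fc = rows - r0, cols - c0
    data = field_movie.data
    cell_field = (
        data[:, r0, c0] * (1 - fr) * (1 - fc)
        + data[:, r0 + np.minimum(1, ny - 1 - r0), c0] * fr * (1 - fc)
        + data[:, r0, c0 + np.minimum(1, nx - 1 - c0)] * (1 - fr) * fc
        + data[:, r0 + np.minimum(1, ny - 1 - r0), c0 + np.minimum(1, nx - 1 - c0)]
        * fr * fc
    ).T.astype(float)  # (n_cells, T)

    npil_px = max(int(round(20.0 / pix)), 1)
    local = ndimage.uniform_filter(
        np.asarray(data, dtype=np.float32), size=(1, 2 * npil_px + 1, 2 * npil_px + 1)
    )
    f_neuropil = local[:, np.round(rows).astype(int), np.round(cols).astype(int)].T

    f_raw = cell_field + params.neuropil_weight * f_neuropil
    if params.cell_noise_sd > 0:
        f_raw = f_raw + (
            params.cell_noise_sd * params.baseline_counts
        ) * rng.standard_normal(f_raw.shape)

    if salt_and_pepper:
        positions = positions[rng.permutation(params.n_cells)]

    rec = CellRecording(
        f_raw=f_raw,
        f_neuropil=np.asarray(f_neuropil, dtype=float),
        positions_um=positions,
        frame_rate_hz=field_movie.frame_rate_hz,
    )
    cell_truth = GroundTruth(
        basis_patterns=truth.basis_patterns,
        event_times=truth.event_times,
        event_coefficients=truth.event_coefficients,
        cell_positions=positions,
        cell_field_values=(
            cell_field[:, truth.event_times].T if truth.event_times.size else None
        ),
    )
    return rec, cell_truth
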