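"""Seed-point correlation networks over spontaneous event patterns.

Event frames are Gaussian band-pass filtered (difference of Gaussians,
s_high = 195 um, s_low = 26-41 um), downsampled to a 160 x 135 analysis
grid, and correlated across events: for a seed point s, the correlation
field is the pixelwise Pearson correlation

    C(x, s) = (1/N) sum_i (A_i(x) - <A(x)>) (A_i(s) - <A(s)>) / (sigma_x sigma_s)

over the N patterns A_i.  Statistical significance of long-range structure
is assessed against a surrogate ensemble in which each pattern is randomly
rotated (10-degree steps) and reflected about the ROI center, destroying
systematic inter-pattern relationships while preserving single-pattern
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class PatternEnsemble:
    """Band-pass filtered, downsampled event patterns on a shared masked grid."""

    patterns: np.ndarray          # (N, H', W')
    grid_pixel_um: float
    roi_mask: np.ndarray          # (H', W')
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (N, H, W)")
        if self.patterns.shape[1:] != self.roi_mask.shape:
            raise ValueError("pattern and mask shapes differ")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def subsample(self, n: int, rng: np.random.Generator) -> "PatternEnsemble":
        if n >= self.n_patterns:
            warnings.warn("subsample size >= ensemble size; using all patterns")
            return self
        idx = rng.choice(self.n_patterns, size=n, replace=False)
        return PatternEnsemble(
            self.patterns[idx], self.grid_pixel_um, self.roi_mask, dict(self.filter_params)
        )


@dataclass
class CorrelationField:
    seed: tuple[int, int]         # (row, col)
    values: np.ndarray            # (H', W'), NaN where undefined
    n_patterns: int


@dataclass
class SurrogateEnsemble:
    """Lazy ensemble of rotated/reflected pattern sets.

    Stores the per-surrogate, per-pattern transform draws; surrogate pattern
    stacks are materialized one at a time via :meth:`surrogate`.
    """

    source: PatternEnsemble
    angles_deg: np.ndarray        # (n_surrogates, N)
    flip_x: np.ndarray            # (n_surrogates, N) bool, reflect across x-axis
    flip_y: np.ndarray            # (n_surrogates, N) bool
    center: tuple[float, float]   # (row, col) of ROI centroid

    @property
    def n_surrogates(self) -> int:
        return self.angles_deg.shape[0]

    def surrogate(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (patterns, valid_mask) for surrogate j.

        valid_mask marks pixels whose transformed value is defined (mapped
        from inside the ROI) in every pattern of this surrogate.
        """
        pats = np.empty_like(self.source.patterns)
        valid = self.source.roi_mask.copy()
        for i in range(self.source.n_patterns):
            p, v = transform_pattern(
                self.source.patterns[i],
                self.source.roi_mask,
                self.angles_deg[j, i],
                self.flip_x[j, i],
                self.flip_y[j, i],
                self.center,
            )
            pats[i] = p
            valid &= v
        return pats, valid

    def valid_mask(self, j: int) -> np.ndarray:
        return self.surrogate(j)[1]


@dataclass
class DistanceProfile:
    bin_centers_mm: np.ndarray
    statistic: np.ndarray
    n_per_bin: np.ndarray
    kind: str = "median_maxima_r"
    samples: list | None = None   # raw (distance_mm, value) pools per bin


def _masked_gaussian(img: np.ndarray, mask: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian low-pass that does not leak across the mask boundary."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(np.where(mask, img, 0.0), sigma_px)
    den = ndimage.gaussian_filter(m, sigma_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask] = 0.0
    return out


def _block_average(img: np.ndarray, factor: int) -> np.ndarray:
    h, w = img.shape
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def bandpass_filter_patterns(
    patterns,
    roi_mask: np.ndarray | None = None,
    pixel_um: float | None = None,
    s_high_um: float = 195.0,
    s_low_um: float = 33.0,
    target_grid: tuple[int, int] = (135, 160),
) -> PatternEnsemble:
    """Band-pass filter event patterns and downsample to the analysis grid.

    Each pattern is difference-of-Gaussians filtered (low-pass at ``s_low_um``
    minus low-pass at ``s_high_um``, both mask-normalized so values outside
    the ROI never leak in), then block-averaged onto ``target_grid``; the
    mask is downsampled by majority vote.

    ``patterns`` may be an :class:`~modcortex.events.EventSet` (its peak
    patterns are used) or an (N, H, W) array with ``roi_mask``/``pixel_um``.
    """
    from modcortex.events import EventSet

    if isinstance(patterns, EventSet):
        stack = patterns.peak_patterns()
        roi_mask = patterns.roi_mask
        pixel_um = patterns.pixel_um
    else:
        stack = np.asarray(patterns, dtype=float)
        if roi_mask is None or pixel_um is None:
            raise ValueError("roi_mask and pixel_um required for array input")
    if stack.shape[0] < 1:
        raise ValueError("need at least one pattern")
    if s_low_um >= s_high_um:
        raise ValueError("s_low_um must be smaller than s_high_um")

    h, w = stack.shape[1:]
    th, tw = target_grid
    if h % th or w % tw:
        raise ValueError(f"frame shape {(h, w)} not an integer multiple of {target_grid}")
    fy, fx = h // th, w // tw
    if fy != fx:
        raise ValueError("anisotropic downsampling factors not supported")
    factor = fy

    mask = np.asarray(roi_mask, dtype=bool)
    s_low_px = s_low_um / pixel_um
    s_high_px = s_high_um / pixel_um
    filtered = np.empty((stack.shape[0], th, tw))
    for i, p in enumerate(stack):
        f = _masked_gaussian(p, mask, s_low_px) - _masked_gaussian(p, mask, s_high_px)
        filtered[i] = _block_average(f, factor) if factor > 1 else f
    small_mask = (
        _block_average(mask.astype(float), factor) > 0.5 if factor > 1 else mask
    )
    return PatternEnsemble(
        patterns=filtered,
        grid_pixel_um=pixel_um * factor,
        roi_mask=small_mask,
        filter_params={"s_high_um": s_high_um, "s_low_um": s_low_um},
    )


def dog_transfer(k_per_um: float, s_low_um: float, s_high_um: float) -> float:
    """Closed-form amplitude transfer of the DoG filter at spatial frequency k."""
    return float(
        np.exp(-0.5 * (k_per_um * s_low_um) ** 2)
        - np.exp(-0.5 * (k_per_um * s_high_um) ** 2)
    )


def _standardize(ensemble_patterns: np.ndarray, mask: np.ndarray):
    """Z-score patterns per pixel across the ensemble; return (z, sd) flat arrays."""
    flat = ensemble_patterns[:, mask]
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (flat - mu) / sd
    return z, sd


def correlation_pattern(
    ensemble: PatternEnsemble, seed: tuple[int, int]
) -> CorrelationField:
    """Pixelwise Pearson correlation with the seed point across patterns."""
    if ensemble.n_patterns < 2:
        raise ValueError("need at least 2 patterns for correlations")
    r, c = seed
    if not ensemble.roi_mask[r, c]:
        raise ValueError("seed point outside ROI")
    z, sd = _standardize(ensemble.patterns, ensemble.roi_mask)
    flat_idx = np.flatnonzero(ensemble.roi_mask)
    seed_flat = np.searchsorted(flat_idx, r * ensemble.roi_mask.shape[1] + c)
    if sd[seed_flat] == 0:
        raise ValueError("degenerate seed: zero variance across patterns")
    vals = np.full(ensemble.roi_mask.shape, np.nan)
    with np.errstate(invalid="ignore"):
        vals[ensemble.roi_mask] = (z * z[:, [seed_flat]]).mean(axis=0)
    return CorrelationField(seed=seed, values=vals, n_patterns=ensemble.n_patterns)


def correlation_fields_stack(
    patterns: np.ndarray, mask: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """Correlation values for many seeds at once.

    Returns an array (n_seeds, n_valid_pixels) of Pearson correlations, NaN
    for zero-variance pixels or seeds.  ``seeds`` holds (row, col) pairs that
    must lie inside ``mask``.
    """
    z, sd = _standardize(patterns, mask)
    flat_idx = np.flatnonzero(mask)
    seed_flat = np.searchsorted(flat_idx, seeds[:, 0] * mask.shape[1] + seeds[:, 1])
    n = patterns.shape[0]
    with np.errstate(invalid="ignore"):
        out = (z[:, seed_flat].T @ z) / n
    return out


def make_surrogate_ensemble(
    ensemble: PatternEnsemble, n_surrogates: int = 100, seed: int = 0
) -> SurrogateEnsemble:
    """Draw rotation/reflection transforms for a surrogate null ensemble.

    Every pattern of every surrogate is independently rotated about the ROI
    centroid by an angle drawn uniformly from {0, 10, ..., 350} degrees and
    reflected with probability 0.5 independently across each axis.
    """
    rng = np.random.default_rng(seed)
    n = ensemble.n_patterns
    angles = rng.integers(0, 36, size=(n_surrogates, n)) * 10.0
    flip_x = rng.random((n_surrogates, n)) < 0.5
    flip_y = rng.random((n_surrogates, n)) < 0.5
    com = ndimage.center_of_mass(ensemble.roi_mask.astype(float))
    return SurrogateEnsemble(
        source=ensemble,
        angles_deg=angles,
        flip_x=flip_x,
        flip_y=flip_y,
        center=(float(com[0]), float(com[1])),
    )


def transform_pattern(
    pattern: np.ndarray,
    mask: np.ndarray,
    angle_deg: float,
    flip_x: bool,
    flip_y: bool,
    center: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate/reflect a pattern about ``center`` (bilinear interpolation).

    Output pixels whose source location falls outside the ROI are undefined:
    they are set to NaN and excluded from the returned validity mask.
    Exclusion, rather than filling, guarantees no fabricated values enter
    downstream correlations.
    """
    h, w = pattern.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = center
    dy, dx = rows - cy, cols - cx
    if flip_y:   # reflect across the y-axis: x -> -x
        dx = -dx
    if flip_x:   # reflect across the x-axis: y -> -y
        dy = -dy
    # inverse rotation of the output grid into source coordinates; snap the
    # trig values at multiples of 90 degrees so axis-aligned rotations map
    # exactly onto the grid instead of epsilon outside it
    th = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)
    cos_t = 0.0 if abs(cos_t) < 1e-12 else (round(cos_t) if abs(abs(cos_t) - 1) < 1e-12 else cos_t)
    sin_t = 0.0 if abs(sin_t) < 1e-12 else (round(sin_t) if abs(abs(sin_t) - 1) < 1e-12 else sin_t)
    src_y = cy + cos_t * dy - sin_t * dx
    src_x = cx + sin_t * dy + cos_t * dx
    coords = np.stack([src_y.ravel(), src_x.ravel()])
    vals = ndimage.map_coordinates(
        np.where(mask, pattern, 0.0), coords, order=1, cval=0.0
    ).reshape(h, w)
    mval = ndimage.map_coordinates(
        mask.astype(float), coords, order=1, cval=0.0
    ).reshape(h, w)
    valid = (mval > 0.999) & mask
    out = np.where(valid, vals, np.nan)
    return out, valid


def find_correlation_maxima(
    field: CorrelationField | np.ndarray,
    pixel_um: float,
    min_separation_um: float = 800.0,
    valid_mask: np.ndarray | None = None,
) -> list[tuple[tuple[int, int], float]]:
    """Local maxima of a correlation field with greedy minimum separation.

    Strict 8-neighborhood local maxima are accepted in descending order of
    correlation, suppressing any candidate within ``min_separation_um`` of
    an already accepted maximum.  The seed's own peak (r = 1) is therefore
    always included.
    """
    vals = field.values if isinstance(field, CorrelationField) else np.asarray(field)
    v = np.array(vals, dtype=float)
    if valid_mask is not None:
        v[~valid_mask] = np.nan
    finite = np.isfinite(v)
    if not finite.any():
        return []
    filled = np.where(finite, v, -np.inf)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False  # strict: exclude the center from the neighborhood
    neighbor_max = ndimage.maximum_filter(
        filled, footprint=footprint, mode="constant", cval=-np.inf
    )
    peaks = (filled > neighbor_max) & finite
    ys, xs = np.nonzero(peaks)
    if ys.size == 0:
        return []
    order = np.argsort(v[ys, xs])[::-1]
    ys, xs = ys[order], xs[order]
    accepted: list[tuple[tuple[int, int], float]] = []
    min_sep_px = min_separation_um / pixel_um
    acc_pos = np.empty((0, 2))
    for y, x in zip(ys, xs):
        if acc_pos.size:
            d = np.sqrt(((acc_pos - (y, x)) ** 2).sum(axis=1))
            if (d < min_sep_px).any():
                continue
        accepted.append(((int(y), int(x)), float(v[y, x])))
        acc_pos = np.vstack([acc_pos, (y, x)])
    return accepted


def seed_grid(mask: np.ndarray, stride: int = 4) -> np.ndarray:
    """(row, col) seed points on a strided grid of valid pixels."""
    ys, xs = np.nonzero(mask)
    keep = (ys % stride == 0) & (xs % stride == 0)
    return np.column_stack([ys[keep], xs[keep]])


def _pool_maxima(
    patterns: np.ndarray,
    mask: np.ndarray,
    pixel_um: float,
    seeds: np.ndarray,
    min_separation_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (distance_mm, r) of correlation maxima over all seed points."""
    corr = correlation_fields_stack(patterns, mask, seeds)
    shape = mask.shape
    dists, rs = [], []
    template = np.full(shape, np.nan)
    for i, (sy, sx) in enumerate(seeds):
        template[mask] = corr[i]
        maxima = find_correlation_maxima(template, pixel_um, min_separation_um)
        for (y, x), r in maxima:
            d_mm = np.hypot(y - sy, x - sx) * pixel_um / 1000.0
            dists.append(d_mm)
            rs.append(r)
    return np.asarray(dists), np.asarray(rs)


def correlation_vs_distance(
    ensemble: PatternEnsemble,
    n_subsample_events: int = 100,
    seed_stride: int = 4,
    min_separation_um: float = 800.0,
    bin_width_mm: float = 0.2,
    max_distance_mm: float = 3.0,
    seed: int = 0,
) -> DistanceProfile:
    """Distance-binned median correlation at maxima, pooled over seed points.

    Correlation fields are computed on ``n_subsample_events`` randomly
    subsampled patterns (standardizing event counts across recordings); the
    amplitudes of local maxima are pooled across all seeds and binned by
    distance from the seed.
    """
    rng = np.random.default_rng(seed)
    sub = ensemble.subsample(n_subsample_events, rng)
    seeds = seed_grid(sub.roi_mask, seed_stride)
    dists, rs = _pool_maxima(
        sub.patterns, sub.roi_mask, sub.grid_pixel_um, seeds, min_separation_um
    )
    edges = np.arange(0.0, max_distance_mm + bin_width_mm, bin_width_mm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    stat = np.full(centers.size, np.nan)
    n_per = np.zeros(centers.size, dtype=int)
    samples = []
    for b in range(centers.size):
        in_bin = (dists >= edges[b]) & (dists < edges[b + 1])
        n_per[b] = in_bin.sum()
        samples.append(rs[in_bin])
        if n_per[b]:
            stat[b] = np.median(rs[in_bin])
    return DistanceProfile(
        bin_centers_mm=centers, statistic=stat, n_per_bin=n_per, samples=samples
    )


def _band_median(
    patterns: np.ndarray,
    mask: np.ndarray,
    pixel_um: float,
    seeds: np.ndarray,
    band_mm: tuple[float, float],
    min_separation_um: float,
) -> float:
    dists, rs = _pool_maxima(patterns, mask, pixel_um, seeds, min_separation_um)
    in_band = (dists >= band_mm[0]) & (dists <= band_mm[1])
    if not in_band.any():
        return np.nan
    return float(np.median(rs[in_band]))


def longrange_significance(
    ensemble: PatternEnsemble,
    surrogates: SurrogateEnsemble,
    band_mm: tuple[float, float] = (1.8, 2.2),
    n_subsample_events: int = 100,
    seed_stride: int = 4,
    min_separation_um: float = 800.0,
    seed: int = 0,
) -> dict:
    """Significance of long-range correlations against the surrogate null.

    The statistic is the median correlation at maxima ``band_mm`` away from
    the seed point, pooled over seeds; the p-value is the fraction of
    surrogates whose statistic is >= the real one.  With ``n`` surrogates the
    resolution floor is 1/n, so a zero count is reported as "< 1/n".
    """
    ys, xs = np.nonzero(ensemble.roi_mask)
    extent_mm = (
        np.hypot(ys.max() - ys.min(), xs.max() - xs.min())
        * ensemble.grid_pixel_um / 1000.0
    )
    if extent_mm < band_mm[0]:
        raise ValueError(
            f"FOV too small: ROI extent {extent_mm:.2f} mm below band {band_mm}"
        )
    rng = np.random.default_rng(seed)
    sub = ensemble.subsample(n_subsample_events, rng)
    seeds = seed_grid(sub.roi_mask, seed_stride)
    real_stat = _band_median(
        sub.patterns, sub.roi_mask, sub.grid_pixel_um, seeds, band_mm,
        min_separation_um,
    )
    surr_stats = np.empty(surrogates.n_surrogates)
    src = surrogates.source
    for j in range(surrogates.n_surrogates):
        pats, valid = surrogates.surrogate(j)
        if src.n_patterns > n_subsample_events:
            idx = rng.choice(src.n_patterns, size=n_subsample_events, replace=False)
            pats = pats[idx]
        sseeds = seed_grid(valid, seed_stride)
        pats = np.where(np.isfinite(pats), pats, 0.0)
        surr_stats[j] = _band_median(
            pats, valid, src.grid_pixel_um, sseeds, band_mm, min_separation_um
        )
    defined = np.isfinite(surr_stats)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no surrogate produced maxima in the distance band")
    p = float((surr_stats[defined] >= real_stat).sum() / n_def)
    return {
        "real_median_r": real_stat,
        "surrogate_medians": surr_stats,
        "p_value": p,
        "p_reported": max(p, 1.0 / n_def),
        "n_surrogates": n_def,
    }


def correlation_variance_rings(
    ensemble: PatternEnsemble,
    surrogates: SurrogateEnsemble | None = None,
    radii_mm: np.ndarray | None = None,
    ring_width_mm: float = 0.2,
    seed_stride: int = 4,
    n_surrogates_used: int | None = None,
) -> DistanceProfile:
    """Variance of pixelwise correlations in rings around the seed point.

    For each ring radius, correlation values at pixels in the ring are pooled
    over all seed points and their variance computed; the same quantity from
    a matched-count surrogate ensemble (mean over surrogates) is subtracted
    when surrogates are provided, correcting for the finite event count.
    """
    if radii_mm is None:
        radii_mm = np.arange(0.8, 2.2001, 0.2)
    radii_mm = np.asarray(radii_mm)

    def ring_variances(patterns, mask, pixel_um):
        seeds = seed_grid(mask, seed_stride)
        corr = correlation_fields_stack(patterns, mask, seeds)
        ys, xs = np.nonzero(mask)
        out = np.full(radii_mm.size, np.nan)
        pools = [[] for _ in radii_mm]
        for i, (sy, sx) in enumerate(seeds):
            d_mm = np.hypot(ys - sy, xs - sx) * pixel_um / 1000.0
            for b, r0 in enumerate(radii_mm):
                sel = (d_mm >= r0) & (d_mm < r0 + ring_width_mm)
                if sel.any():
                    pools[b].append(corr[i][sel])
        for b in range(radii_mm.size):
            if pools[b]:
                allv = np.concatenate(pools[b])
                allv = allv[np.isfinite(allv)]
                if allv.size > 1:
                    out[b] = allv.var()
        return out

    real = ring_variances(
        ensemble.patterns, ensemble.roi_mask, ensemble.grid_pixel_um
    )
    n_per = np.full(radii_mm.size, ensemble.n_patterns)
    if surrogates is None:
        return DistanceProfile(radii_mm, real, n_per, kind="ring_variance")
    n_use = n_surrogates_used or surrogates.n_surrogates
    surr = np.full((n_use, radii_mm.size), np.nan)
    for j in range(n_use):
        pats, valid = surrogates.surrogate(j)
        pats = np.where(np.isfinite(pats), pats, 0.0)
        surr[j] = ring_variances(pats, valid, surrogates.source.grid_pixel_um)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corrected = real - np.nanmean(surr, axis=0)
    return DistanceProfile(
        radii_mm, corrected, n_per, kind="ring_variance_surrogate_subtracted"
    )
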