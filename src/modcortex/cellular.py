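"""Cellular-resolution pipeline for 2-photon recordings.

Per-cell raw traces are neuropil-corrected (F_cell = F_raw - alpha *
F_neuropil, alpha = 0.4), converted to dF/F against a 60-s running-median
baseline, and median-smoothed over 7 frames.  Population events are frames
on which more than 5% of cells exceed their own mean by 2 SD; each event
contributes one event frame whose activity is z-scored across cells.
Pairwise Pearson correlations across event frames, their distance profile,
a within-cell shuffle null, and the local coherence index

    LCI = (N_pos - N_neg) / (N_pos + N_neg)

(counted over cells in a distance annulus, excluding |r| < 0.01) quantify
whether nearby neurons are coherently co-active or intermixed
salt-and-pepper fashion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class CellRecording:
    """Per-cell raw and neuropil fluorescence with centroid positions."""

    f_raw: np.ndarray         # (n_cells, T)
    f_neuropil: np.ndarray    # (n_cells, T)
    positions_um: np.ndarray  # (n_cells, 2) as (x, y)
    frame_rate_hz: float
    alpha: float = 0.4

    def __post_init__(self) -> None:
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.f_raw.shape != self.f_neuropil.shape:
            raise ValueError("f_raw and f_neuropil shapes differ")
        if self.positions_um.shape != (self.f_raw.shape[0], 2):
            raise ValueError("positions_um must be (n_cells, 2)")
        if not np.isfinite(self.positions_um).all():
            raise ValueError("positions must be finite")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_cells(self) -> int:
        return self.f_raw.shape[0]


@dataclass
class CellEventSet:
    events: list[tuple[int, int, int]]    # (start, end, event_frame)
    event_frame_matrix: np.ndarray        # (n_events, n_cells) dF/F
    zscored_matrix: np.ndarray            # z-scored across cells per frame
    positions_um: np.ndarray

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class PairCorrMatrix:
    r: np.ndarray             # (n_cells, n_cells)
    distances_um: np.ndarray  # (n_cells, n_cells)
    n_events: int
    undefined_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class LCIProfile:
    radii_um: np.ndarray      # annulus centers
    lci: np.ndarray           # FOV mean per annulus
    per_seed: np.ndarray      # (n_cells, n_annuli), NaN where undefined
    n_excluded_pairs: int


def neuropil_correct(rec: CellRecording, alpha: float | None = None) -> np.ndarray:
    """F_cell = F_raw - alpha * F_neuropil (elementwise)."""
    a = rec.alpha if alpha is None else alpha
    return rec.f_raw - a * rec.f_neuropil


def cell_dff(
    traces: np.ndarray,
    frame_rate_hz: float,
    baseline_window_s: float = 60.0,
    smooth_frames: int = 7,
    baseline_stride: int = 1,
) -> np.ndarray:
    """dF/F of per-cell traces with a running-median baseline.

    F0 is a per-cell running median over ``baseline_window_s``; the dF/F
    trace is then median-smoothed over ``smooth_frames`` frames, which
    removes single-frame artifacts without blunting multi-frame transients.
    ``baseline_stride`` > 1 evaluates the median on a frame subgrid and
    interpolates, accurate for the slow baselines the filter tracks.
    """
    from modcortex.preprocess import _running_median

    traces = np.asarray(traces, dtype=float)
    window = int(round(baseline_window_s * frame_rate_hz))
    if window % 2 == 0:
        window += 1
    if traces.shape[1] <= window // 2:
        raise ValueError("trace shorter than the baseline window")
    if baseline_stride > 1:
        f0 = _running_median(traces.T, window, stride=baseline_stride).T
    else:
        f0 = ndimage.median_filter(traces, size=(1, window), mode="reflect")
    bad = (f0 <= 0).any(axis=1)
    if bad.any():
        raise ValueError(
            f"baseline F0 <= 0 for cells {np.nonzero(bad)[0].tolist()[:10]}"
        )
    dff = (traces - f0) / f0
    if smooth_frames > 1:
        dff = ndimage.median_filter(dff, size=(1, smooth_frames), mode="reflect")
    return dff


def _split_runs_at_count_minima(run: np.ndarray, counts: np.ndarray) -> list[np.ndarray]:
    if run.size < 3:
        return [run]
    vals = counts[run]
    interior = np.arange(1, run.size - 1)
    is_min = (vals[interior] < vals[interior - 1]) & (vals[interior] < vals[interior + 1])
    cuts = interior[is_min]
    if cuts.size == 0:
        return [run]
    pieces, start = [], 0
    for c in cuts:
        pieces.append(run[start : c + 1])
        start = c + 1
    pieces.append(run[start:])
    return [p for p in pieces if p.size > 0]


def detect_cell_events(
    dff: np.ndarray,
    positions_um: np.ndarray,
    cell_thresh_sd: float = 2.0,
    frame_fraction: float = 0.05,
) -> CellEventSet:
    """Detect population events in cells x T dF/F traces.

    A cell is active on a frame when its dF/F exceeds its own mean by
    ``cell_thresh_sd`` SD; frames with strictly more than ``frame_fraction``
    of cells active are event frames.  Runs of consecutive event frames are
    split at interior local minima of the active-cell count.  Each event's
    single event frame (highest mean signal across all cells) is z-scored
    across cells.
    """
    dff = np.asarray(dff, dtype=float)
    n_cells, T = dff.shape
    if n_cells < 2 or T < 2:
        raise ValueError("need at least 2 cells and 2 frames")
    mu = dff.mean(axis=1, keepdims=True)
    sd = dff.std(axis=1, keepdims=True)
    zero_sd = sd[:, 0] == 0
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} zero-SD cells treated as never active")
    sd[zero_sd, :] = np.inf
    active = dff > mu + cell_thresh_sd * sd
    counts = active.sum(axis=0)
    event_frames = counts > frame_fraction * n_cells  # strictly 'over 5%'
    mean_signal = dff.mean(axis=0)

    events: list[tuple[int, int, int]] = []
    idx = np.nonzero(event_frames)[0]
    if idx.size:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            for piece in _split_runs_at_count_minima(run, counts):
                ef = int(piece[np.argmax(mean_signal[piece])])
                events.append((int(piece[0]), int(piece[-1]), ef))

    if events:
        matrix = dff[:, [e[2] for e in events]].T  # (n_events, n_cells)
        zmu = matrix.mean(axis=1, keepdims=True)
        zsd = matrix.std(axis=1, keepdims=True)
        zsd[zsd == 0] = 1.0
        z = (matrix - zmu) / zsd
    else:
        matrix = np.empty((0, n_cells))
        z = np.empty((0, n_cells))
    return CellEventSet(
        events=events,
        event_frame_matrix=matrix,
        zscored_matrix=z,
        positions_um=np.asarray(positions_um, dtype=float),
    )


def pairwise_correlations(evset: CellEventSet) -> PairCorrMatrix:
    """Pearson correlations between cells' z-scored event-frame vectors."""
    z = evset.zscored_matrix
    if z.shape[0] < 2:
        raise ValueError("need at least 2 events for pairwise correlations")
    sd = z.std(axis=0)
    undefined = np.nonzero(sd == 0)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(z.T)
    r[undefined, :] = np.nan
    r[:, undefined] = np.nan
    np.fill_diagonal(r, 1.0)
    pos = evset.positions_um
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=-1))
    return PairCorrMatrix(
        r=r, distances_um=d, n_events=z.shape[0], undefined_cells=undefined
    )


def _nearby_median(r: np.ndarray, d: np.ndarray, lo: float, hi: float) -> float:
    iu = np.triu_indices_from(r, k=1)
    sel = (d[iu] >= lo) & (d[iu] <= hi) & np.isfinite(r[iu])
    if not sel.any():
        return np.nan
    return float(np.median(r[iu][sel]))


def cell_shuffle_null(
    evset: CellEventSet,
    n_shuffles: int = 100,
    seed: int = 0,
    nearby_um: tuple[float, float] = (30.0, 100.0),
) -> dict:
    """Within-cell shuffle null for nearby pairwise correlations.

    Each shuffle permutes every cell's event-frame values independently
    across events (preserving each cell's marginal distribution exactly) and
    recomputes the median correlation over nearby pairs.  The p-value is the
    fraction of shuffles with a statistic >= the real one.
    """
    if len(evset) < 2:
        raise ValueError("need at least 2 events")
    rng = np.random.default_rng(seed)
    pc = pairwise_correlations(evset)
    real = _nearby_median(pc.r, pc.distances_um, *nearby_um)
    z = evset.zscored_matrix
    n_events, n_cells = z.shape
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        shuffled = np.empty_like(z)
        for c in range(n_cells):
            shuffled[:, c] = z[rng.permutation(n_events), c]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(shuffled.T)
        null[j] = _nearby_median(r, pc.distances_um, *nearby_um)
    defined = np.isfinite(null)
    p = float((null[defined] >= real).sum() / max(defined.sum(), 1))
    return {
        "real_median_r": real,
        "null_medians": null,
        "p_value": p,
        "p_reported": max(p, 1.0 / max(int(defined.sum()), 1)),
        "n_shuffles": int(defined.sum()),
    }


def correlation_by_distance(
    pc: PairCorrMatrix,
    bin_edges_um: np.ndarray | list[float] = (30, 100, 200, 300, 400, 500, 600),
) -> dict:
    """Mean and SEM of pairwise r binned by inter-cell distance.

    Pairs closer than the first edge are excluded (analysis starts at 30 um
    to avoid overlapping somata / shared neuropil).
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    iu = np.triu_indices_from(pc.r, k=1)
    r, d = pc.r[iu], pc.distances_um[iu]
    good = np.isfinite(r)
    r, d = r[good], d[good]
    n_bins = edges.size - 1
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (d >= edges[b]) & (d < edges[b + 1])
        count[b] = sel.sum()
        if count[b] >= 1:
            mean[b] = r[sel].mean()
        if count[b] >= 2:
            sem[b] = r[sel].std(ddof=1) / np.sqrt(count[b])
    if count.sum() == 0:
        warnings.warn("no pairs beyond the first distance edge")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"bin_centers_um": centers, "mean_r": mean, "sem_r": sem, "n_pairs": count}


def local_coherence_index(
    pc: PairCorrMatrix,
    annuli_um: np.ndarray | None = None,
    annulus_width_um: float = 50.0,
    exclude_below: float = 0.01,
) -> LCIProfile:
    """Sign coherence of correlations in distance annuli around each cell.

    For each seed cell and annulus, cells with |r| >= ``exclude_below`` are
    counted as positively or negatively correlated and LCI = (N_pos - N_neg)
    / (N_pos + N_neg) computed; annuli with no countable cells are omitted
    from the FOV mean.
    """
    if annuli_um is None:
        annuli_um = np.arange(30.0, 600.0, annulus_width_um)
    annuli_um = np.asarray(annuli_um, dtype=float)
    n_cells = pc.r.shape[0]
    per_seed = np.full((n_cells, annuli_um.size), np.nan)
    n_excluded = 0
    for s in range(n_cells):
        r_row = pc.r[s].copy()
        r_row[s] = np.nan  # seed itself never counted
        d_row = pc.distances_um[s]
        for a, r0 in enumerate(annuli_um):
            in_ann = (d_row >= r0) & (d_row < r0 + annulus_width_um)
            vals = r_row[in_ann]
            vals = vals[np.isfinite(vals)]
            weak = np.abs(vals) < exclude_below
            n_excluded += int(weak.sum())
            vals = vals[~weak]
            if vals.size == 0:
                continue
            n_pos = int((vals > 0).sum())
            n_neg = int((vals < 0).sum())
            per_seed[s, a] = (n_pos - n_neg) / (n_pos + n_neg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fov_mean = np.nanmean(per_seed, axis=0)
    return LCIProfile(
        radii_um=annuli_um + annulus_width_um / 2.0,
        lci=fov_mean,
        per_seed=per_seed,
        n_excluded_pairs=n_excluded,
    )


def lci_zero_crossing_um(profile: LCIProfile) -> float:
    """First radius where the FOV-mean LCI crosses zero (linear interpolation)."""
    r, v = profile.radii_um, profile.lci
    good = np.isfinite(v)
    r, v = r[good], v[good]
    for i in range(1, r.size):
        if v[i - 1] > 0 >= v[i]:
            frac = v[i - 1] / (v[i - 1] - v[i])
            return float(r[i - 1] + frac * (r[i] - r[i - 1]))
    return np.nan
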