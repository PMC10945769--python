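"""Spontaneous-event detection in widefield dF/F movies.

A pixel is active on a frame when it exceeds its own temporal mean by 3 SD
and belongs to a contiguous active region of at least 0.01 mm^2; a frame is
active when more than 40% of ROI pixels are active.  Runs of consecutive
active frames form events, split at interior local minima of the ROI-mean
trace.  The "event frame" is the maximally active frame of each event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from modcortex.preprocess import DffMovie


@dataclass
class Event:
    start_frame: int
    end_frame: int            # inclusive
    event_frame: int          # frame of maximal ROI-mean activity
    peak_pattern: np.ndarray  # H x W dF/F at event_frame
    mean_activity: float      # ROI-mean dF/F at event_frame
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.start_frame <= self.event_frame <= self.end_frame:
            raise ValueError("event_frame must lie within [start_frame, end_frame]")


@dataclass
class EventSet:
    events: list[Event]
    frame_shape: tuple[int, int]
    pixel_um: float
    frame_rate_hz: float
    roi_mask: np.ndarray
    detection_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def event_frames(self) -> np.ndarray:
        return np.array([e.event_frame for e in self.events], dtype=int)

    def peak_patterns(self) -> np.ndarray:
        """Stack of event frames, shape (n_events, H, W)."""
        if not self.events:
            return np.empty((0,) + self.frame_shape)
        return np.stack([e.peak_pattern for e in self.events])

    def frame_in_event(self, n_frames: int) -> np.ndarray:
        """Boolean mask over frames covered by any event span."""
        covered = np.zeros(n_frames, dtype=bool)
        for e in self.events:
            covered[e.start_frame : e.end_frame + 1] = True
        return covered


@dataclass
class ControlFrameSets:
    sets: list[np.ndarray]    # each: event-count-matched frame indices
    pool: np.ndarray          # candidate low-activity frames

    def __len__(self) -> int:
        return len(self.sets)


def find_active_pixels(
    dff_frame: np.ndarray,
    pixel_mean: np.ndarray,
    pixel_sd: np.ndarray,
    pixel_um: float,
    roi_mask: np.ndarray,
    min_region_mm2: float = 0.01,
    threshold_sd: float = 3.0,
    connectivity: int = 2,
) -> np.ndarray:
    """Active-pixel mask for one frame.

    A pixel is active iff its value exceeds ``pixel_mean + threshold_sd *
    pixel_sd`` and it belongs to an active connected component of area at
    least ``min_region_mm2`` (8-connected by default).  Zero-SD pixels are
    never active.
    """
    zero_sd = (pixel_sd == 0) & roi_mask
    if zero_sd.any():
        warnings.warn(f"{zero_sd.sum()} zero-SD pixels treated as never active")
    with np.errstate(invalid="ignore"):
        raw = (dff_frame > pixel_mean + threshold_sd * pixel_sd) & roi_mask & ~zero_sd
    if not raw.any():
        return raw
    min_pixels = int(np.ceil(min_region_mm2 * 1e6 / (pixel_um**2)))
    if min_pixels <= 1:
        return raw
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(raw, structure=structure)
    if n == 0:
        return raw
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_pixels
    return keep[labels]


def _split_runs_at_minima(run: np.ndarray, trace: np.ndarray) -> list[np.ndarray]:
    """Split a run of frames at interior strict local minima of ``trace``.

    A frame is a split point when its trace value is strictly less than both
    neighbors within the run; ties break toward the earlier frame (a frame
    equal to its successor is not a minimum).  The minimum frame ends the
    earlier event.
    """
    if run.size < 3:
        return [run]
    vals = trace[run]
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


def detect_events(
    dff: DffMovie,
    active_fraction: float = 0.40,
    min_region_mm2: float = 0.01,
    threshold_sd: float = 3.0,
    connectivity: int = 2,
) -> EventSet:
    """Detect spontaneous events in a dF/F movie.

    Frames whose active-pixel fraction (within the ROI) exceeds
    ``active_fraction`` are active; maximal runs of consecutive active frames
    become events, split at interior local minima of the ROI-mean dF/F.
    """
    if dff.n_frames < 2:
        raise ValueError("need at least 2 frames")
    mask = dff.roi_mask
    data = dff.data
    pixel_mean = data.mean(axis=0)
    pixel_sd = data.std(axis=0)
    n_roi = int(mask.sum())
    roi_trace = dff.roi_mean_trace()

    zero_sd = (pixel_sd == 0) & mask
    if zero_sd.any():
        warnings.warn(f"{zero_sd.sum()} zero-SD pixels treated as never active")
    thresh = pixel_mean + threshold_sd * pixel_sd

    # cheap per-frame screen: the contiguity filter only removes pixels, so a
    # frame whose raw suprathreshold fraction fails the cut can be skipped
    frac_raw = np.array(
        [((data[t][mask] > thresh[mask])).mean() for t in range(dff.n_frames)]
    )
    active_frames = np.zeros(dff.n_frames, dtype=bool)
    for t in np.nonzero(frac_raw > active_fraction)[0]:
        act = find_active_pixels(
            data[t], pixel_mean, pixel_sd, dff.pixel_um, mask,
            min_region_mm2=min_region_mm2, threshold_sd=threshold_sd,
            connectivity=connectivity,
        )
        active_frames[t] = act[mask].mean() > active_fraction

    events: list[Event] = []
    idx = np.nonzero(active_frames)[0]
    if idx.size:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        for run in runs:
            for piece in _split_runs_at_minima(run, roi_trace):
                ef = int(piece[np.argmax(roi_trace[piece])])
                events.append(
                    Event(
                        start_frame=int(piece[0]),
                        end_frame=int(piece[-1]),
                        event_frame=ef,
                        peak_pattern=np.array(data[ef], dtype=float),
                        mean_activity=float(roi_trace[ef]),
                        at_boundary=piece[0] == 0 or piece[-1] == dff.n_frames - 1,
                    )
                )
    return EventSet(
        events=events,
        frame_shape=dff.frame_shape,
        pixel_um=dff.pixel_um,
        frame_rate_hz=dff.frame_rate_hz,
        roi_mask=mask.copy(),
        detection_params={
            "active_fraction": active_fraction,
            "min_region_mm2": min_region_mm2,
            "threshold_sd": threshold_sd,
            "connectivity": connectivity,
        },
    )


def select_control_frames(
    dff: DffMovie,
    events: EventSet,
    n_sets: int = 100,
    seed: int = 0,
) -> ControlFrameSets:
    """Draw event-count-matched sets of low-activity control frames.

    The candidate pool is the bottom decile of non-event frames ranked by
    ROI-mean dF/F; each of ``n_sets`` sets samples an event-matched number of
    frames from the pool without replacement.
    """
    rng = np.random.default_rng(seed)
    n_events = len(events)
    covered = events.frame_in_event(dff.n_frames)
    candidates = np.nonzero(~covered)[0]
    if candidates.size < n_events:
        raise ValueError("not enough non-event frames to match event count")
    trace = dff.roi_mean_trace()
    order = candidates[np.argsort(trace[candidates], kind="stable")]
    pool = np.sort(order[: max(int(np.ceil(candidates.size * 0.10)), 1)])
    sets = []
    replace = pool.size < n_events
    if replace:
        warnings.warn("control pool smaller than event count; sampling with replacement")
    for _ in range(n_sets):
        if n_events == 0:
            sets.append(np.empty(0, dtype=int))
        else:
            sets.append(np.sort(rng.choice(pool, size=n_events, replace=replace)))
    return ControlFrameSets(sets=sets, pool=pool)


def temporal_autocorrelation(
    dff: DffMovie,
    max_lag_s: float = 10.0,
    per_pixel: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson autocorrelation of activity at integer-frame lags up to max_lag_s.

    By default the autocorrelation of the ROI-mean dF/F trace; with
    ``per_pixel`` the mean over per-pixel autocorrelations instead.

    Returns (lag_s, r).
    """
    max_lag = int(np.floor(max_lag_s * dff.frame_rate_hz))
    if dff.n_frames <= max_lag:
        raise ValueError("record shorter than the maximum lag")
    lags = np.arange(max_lag + 1)
    if per_pixel:
        traces = dff.data[:, dff.roi_mask].astype(float)
        if np.any(traces.std(axis=0) == 0):
            traces = traces[:, traces.std(axis=0) > 0]
        r = np.array([_mean_pearson_lag(traces, k) for k in lags])
    else:
        x = dff.roi_mean_trace().astype(float)
        if x.std() == 0:
            raise ValueError("constant trace: autocorrelation undefined")
        r = np.array([_pearson_lag(x, k) for k in lags])
    return lags / dff.frame_rate_hz, r


def _pearson_lag(x: np.ndarray, k: int) -> float:
    if k == 0:
        return 1.0
    a, b = x[:-k], x[k:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _mean_pearson_lag(traces: np.ndarray, k: int) -> float:
    if k == 0:
        return 1.0
    a, b = traces[:-k], traces[k:]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = a.std(axis=0) * b.std(axis=0)
    good = denom > 0
    return float((((a * b).mean(axis=0))[good] / denom[good]).mean())
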