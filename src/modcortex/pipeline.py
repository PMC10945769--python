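"""End-to-end orchestration of the widefield and cellular analyses.

A :class:`RunConfig` carries every stage parameter (defaults are the
analysis constants used throughout this pipeline: 3 SD pixel threshold,
0.01 mm^2 minimum region, 40% active fraction, 195/33 um band-pass, 800 um
maxima separation, 1.8-2.2 mm long-range band, 100 surrogates and control
sets, alpha = 0.4 neuropil weight, 2 SD / 5% cellular detection, 50 cells x
100 frames x 100 samples for size-controlled dimensionality).  One global
seed deterministically derives per-stage seeds by stage-name hashing, so a
run is reproducible end to end while stages stay statistically independent.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from modcortex import corrnet, dimensionality, events, modularity, preprocess, synthdata


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """All stage parameters of a widefield run."""

    # input: either a movie path or synthetic parameters
    movie_path: str | None = None
    synth: dict = field(default_factory=dict)
    out_dir: str = "modcortex_out"
    seed: int = 0
    # preprocessing
    baseline_window_s: float = 15.0
    baseline_stride: int = 1
    register: bool = False
    # event detection
    threshold_sd: float = 3.0
    min_region_mm2: float = 0.01
    active_fraction: float = 0.40
    n_control_sets: int = 100
    # pattern filtering
    s_high_um: float = 195.0
    s_low_um: float = 33.0
    target_grid: tuple[int, int] | None = None
    # correlation networks
    min_separation_um: float = 800.0
    band_mm: tuple[float, float] = (1.8, 2.2)
    n_surrogates: int = 100
    n_subsample_events: int = 100
    seed_stride: int = 4
    # dimensionality
    n_splits: int = 20

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band_mm"] = list(d["band_mm"])
        if d["target_grid"] is not None:
            d["target_grid"] = list(d["target_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band_mm" in d:
            d["band_mm"] = tuple(d["band_mm"])
        if d.get("target_grid") is not None:
            d["target_grid"] = tuple(d["target_grid"])
        return cls(**d)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_widefield(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute synth/load -> preprocess -> events -> modularity -> corrnet -> dimensionality.

    Returns the run report as a dict; with ``write_outputs`` the report and
    config are persisted under ``config.out_dir``.
    """
    report: dict = {"config": _json_safe(dataclasses.asdict(config))}
    if config.movie_path is not None:
        from modcortex.io import load_movie_h5

        movie = load_movie_h5(config.movie_path)
        truth = None
    else:
        params = synthdata.SynthParams(
            **{**config.synth, "seed": config.synth.get("seed", stage_seed(config.seed, "synth"))}
        )
        movie, truth = synthdata.synth_widefield_movie(params)
        report["synth_n_events_planted"] = int(params.n_events)

    if config.register:
        movie, _ = preprocess.register_translation(movie)
    dff = preprocess.compute_dff(
        movie, config.baseline_window_s, baseline_stride=config.baseline_stride
    )
    del movie

    evset = events.detect_events(
        dff,
        active_fraction=config.active_fraction,
        min_region_mm2=config.min_region_mm2,
        threshold_sd=config.threshold_sd,
    )
    report["n_events_detected"] = len(evset)
    if len(evset) == 0:
        report["status"] = "no events detected; downstream stages skipped"
        if write_outputs:
            _write_report(config, report)
        return report

    controls = events.select_control_frames(
        dff, evset, n_sets=config.n_control_sets, seed=stage_seed(config.seed, "controls")
    )

    target = config.target_grid
    if target is None:
        h, w = dff.frame_shape
        target = (h, w)  # synthetic movies are generated on the analysis grid
    ensemble = corrnet.bandpass_filter_patterns(
        evset, s_high_um=config.s_high_um, s_low_um=config.s_low_um, target_grid=target
    )

    # modularity and wavelength
    modres = modularity.modularity_of_patterns(
        ensemble.patterns, ensemble.roi_mask, ensemble.grid_pixel_um
    )
    report["median_wavelength_mm"] = modres.median_wavelength_mm
    report["median_modularity"] = modres.median_modularity

    control_frames = np.unique(np.concatenate(controls.sets))
    ctrl_stack = np.stack([dff.data[f] for f in control_frames])
    ctrl_ens = corrnet.bandpass_filter_patterns(
        ctrl_stack, dff.roi_mask, dff.pixel_um,
        s_high_um=config.s_high_um, s_low_um=config.s_low_um, target_grid=target,
    )
    ctrl_mod = modularity.modularity_of_patterns(
        ctrl_ens.patterns, ctrl_ens.roi_mask, ctrl_ens.grid_pixel_um
    )
    frame_to_mod = dict(zip(control_frames.tolist(), ctrl_mod.modularity))
    sig = modularity.modularity_significance(modres.modularity, frame_to_mod, controls.sets)
    report["modularity_p"] = sig["p_value"]

    # module amplitude on the unfiltered event frames, FOV-mean wavelength
    wl = float(np.nanmean(modres.wavelength_mm))
    amps = []
    for e in evset.events:
        res = modularity.module_amplitude(
            e.peak_pattern, dff.roi_mask, dff.pixel_um, wl
        )
        if np.isfinite(res.amplitude):
            amps.append(res.amplitude)
    report["mean_module_amplitude"] = float(np.mean(amps)) if amps else None

    # long-range correlation network vs surrogate null
    if len(evset) >= 2:
        surr = corrnet.make_surrogate_ensemble(
            ensemble, n_surrogates=config.n_surrogates,
            seed=stage_seed(config.seed, "surrogates"),
        )
        try:
            lr = corrnet.longrange_significance(
                ensemble, surr, band_mm=config.band_mm,
                n_subsample_events=config.n_subsample_events,
                seed_stride=config.seed_stride,
                min_separation_um=config.min_separation_um,
                seed=stage_seed(config.seed, "longrange"),
            )
            report["longrange_median_r"] = lr["real_median_r"]
            report["longrange_p"] = lr["p_value"]
        except ValueError as err:
            report["longrange_error"] = str(err)

    # cross-validated dimensionality of the filtered ensemble
    if len(evset) >= 4:
        dim = dimensionality.crossval_dimensionality(
            ensemble, n_splits=config.n_splits, seed=stage_seed(config.seed, "dimensionality")
        )
        report["d_eff"] = dim.d_eff
        report["n_variance_75"] = dim.n_variance_75

    if truth is not None:
        report["planted_event_times"] = truth.event_times.tolist()
    report["status"] = "ok"
    if write_outputs:
        _write_report(config, report)
    return report


def _write_report(config: RunConfig, report: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(_json_safe(report), indent=2, sort_keys=True)
    )
    config.to_yaml(out / "config.yaml")


def compare_groups(values_by_group: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis comparison of a metric across groups.

    Thin wrapper over the standard nonparametric test; post hoc pairwise
    comparisons are out of scope and left to dedicated packages.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    h, p = stats.kruskal(*groups.values())
    return {"H": float(h), "p_value": float(p), "groups": list(groups)}
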