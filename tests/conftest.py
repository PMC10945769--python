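"""Shared fixtures: synthetic recordings reused across test modules.

The heavier synthetic datasets are session-scoped so that the event
detection, correlation, modularity and cellular tests all analyze the same
generated recordings.
"""

from __future__ import annotations

import numpy as np
import pytest

from modcortex import cellular as cell
from modcortex.corrnet import bandpass_filter_patterns
from modcortex.events import detect_events
from modcortex.preprocess import compute_dff
from modcortex.synthdata import (
    SynthParams,
    make_modular_basis,
    synth_cell_recording,
    synth_event_patterns,
    synth_widefield_movie,
)


@pytest.fixture(scope="session")
def structured():
    """n_basis=8 modular ensemble of 100 raw and filtered event patterns."""
    params = SynthParams(n_basis=8, n_events=100, seed=13)
    basis = make_modular_basis(params)
    raw, truth = synth_event_patterns(basis, params)
    ensemble = bandpass_filter_patterns(
        raw, params.roi_mask(), params.pixel_um, target_grid=params.grid_shape
    )
    return {
        "params": params,
        "basis": basis,
        "raw": raw,
        "truth": truth,
        "ensemble": ensemble,
    }


@pytest.fixture(scope="session")
def wf_movie20():
    """Widefield movie with 20 planted events at 10x the pixel noise SD."""
    params = SynthParams(fov_mm=1.9, n_events=20, n_basis=8, seed=42)
    movie, truth = synth_widefield_movie(params)
    dff = compute_dff(movie, 15.0, baseline_stride=25)
    events = detect_events(dff)
    return {"params": params, "truth": truth, "dff": dff, "events": events}


@pytest.fixture(scope="session")
def cellular_setup():
    """Cells sampled from a Lambda = 0.9 mm modular field, plus the
    position-permuted (salt-and-pepper) variant of the same recording."""
    params = SynthParams(
        fov_mm=1.6,
        n_events=60,
        event_rate_hz=0.05,
        n_basis=8,
        wavelength_mm=0.9,
        n_cells=150,
        seed=21,
    )
    movie, truth = synth_widefield_movie(params)
    rec, cell_truth = synth_cell_recording(params, movie, truth)
    rec_sp, _ = synth_cell_recording(params, movie, truth, salt_and_pepper=True)

    def analyze(recording):
        dff = cell.cell_dff(
            cell.neuropil_correct(recording),
            recording.frame_rate_hz,
            baseline_stride=15,
        )
        evset = cell.detect_cell_events(dff, recording.positions_um)
        pc = cell.pairwise_correlations(evset)
        return dff, evset, pc

    dff, evset, pc = analyze(rec)
    _, evset_sp, pc_sp = analyze(rec_sp)
    return {
        "params": params,
        "truth": cell_truth,
        "rec": rec,
        "evset": evset,
        "pc": pc,
        "evset_sp": evset_sp,
        "pc_sp": pc_sp,
    }
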