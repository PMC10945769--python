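"""Neuropil correction, cellular events, pairwise correlations, LCI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modcortex.cellular import (
    CellEventSet,
    CellRecording,
    PairCorrMatrix,
    _split_runs_at_count_minima,
    cell_dff,
    cell_shuffle_null,
    correlation_by_distance,
    detect_cell_events,
    lci_zero_crossing_um,
    local_coherence_index,
    neuropil_correct,
    pairwise_correlations,
)


def _rec(f_raw, f_np=None, positions=None, rate=30.0):
    f_raw = np.asarray(f_raw, dtype=float)
    if f_np is None:
        f_np = np.zeros_like(f_raw)
    if positions is None:
        positions = np.zeros((f_raw.shape[0], 2))
    return CellRecording(f_raw, f_np, positions, rate)


class TestNeuropilCorrection:
    def test_arithmetic(self):
        rec = _rec(np.full((1, 10), 10.0), np.full((1, 10), 5.0))
        assert np.allclose(neuropil_correct(rec), 8.0)  # 10 - 0.4 * 5

    def test_zero_alpha_identity(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.random((3, 20)), rng.random((3, 20)))
        assert np.array_equal(neuropil_correct(rec, alpha=0.0), rec.f_raw)

    def test_full_contamination(self):
        rng = np.random.default_rng(1)
        f = rng.random((2, 15))
        rec = _rec(f, f)
        assert np.allclose(neuropil_correct(rec), 0.6 * f)


class TestCellDff:
    def test_constant_trace_zero(self):
        out = cell_dff(np.full((2, 3000), 4.0), 30.0)
        assert np.allclose(out, 0.0)

    def test_single_frame_spike_removed_by_smoothing(self):
        trace = np.full((1, 4000), 10.0)
        trace[0, 2000] = 30.0
        out = cell_dff(trace, 30.0)
        assert abs(out[0, 2000]) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        trace = 10 + rng.random((2, 4000))
        a = cell_dff(trace, 30.0)
        b = cell_dff(2.0 * trace, 30.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError, match="F0 <= 0"):
            cell_dff(np.zeros((1, 3000)), 30.0)


class TestDetectCellEvents:
    def test_count_minimum_splits_run(self):
        run = np.arange(5)
        counts = np.array([10, 30, 8, 25, 12])
        pieces = _split_runs_at_count_minima(run, counts)
        assert [p.tolist() for p in pieces] == [[0, 1, 2], [3, 4]]

    def test_planted_coactivation_detected_as_one_event(self):
        # bounded (uniform) background noise never exceeds its own 2 SD
        # (2 * a / sqrt(3) > a), isolating the detection logic itself
        rng = np.random.default_rng(3)
        n_cells, T = 50, 2000
        dff = 0.01 * rng.uniform(-1, 1, size=(n_cells, T))
        dff[:20, 1000:1005] += 1.0  # 40% of cells co-active for 5 frames
        ev = detect_cell_events(dff, np.zeros((n_cells, 2)))
        assert len(ev) == 1
        start, end, ef = ev.events[0]
        assert (start, end) == (1000, 1004)

    def test_quiet_recording_has_no_events(self):
        rng = np.random.default_rng(4)
        dff = 0.01 * rng.uniform(-1, 1, size=(30, 500))
        ev = detect_cell_events(dff, np.zeros((30, 2)))
        assert len(ev) == 0

    def test_event_frames_zscored_across_cells(self, cellular_setup):
        z = cellular_setup["evset"].zscored_matrix
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-6)


class TestPairwiseCorrelations:
    def test_identical_and_anticorrelated_vectors(self):
        z = np.array([[1.0, 1.0, -1.0], [-1.0, -1.0, 1.0], [2.0, 2.0, -2.0]])
        ev = CellEventSet(
            events=[(0, 0, 0), (1, 1, 1), (2, 2, 2)],
            event_frame_matrix=z,
            zscored_matrix=z,
            positions_um=np.array([[0, 0], [50, 0], [100, 0]]),
        )
        pc = pairwise_correlations(ev)
        assert pc.r[0, 1] == pytest.approx(1.0)
        assert pc.r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(pc.r, pc.r.T)
        assert np.allclose(np.diag(pc.r), 1.0)

    def test_field_sampled_cells_correlate_nearby_anticorrelate_at_half_wavelength(
        self, cellular_setup
    ):
        pc = cellular_setup["pc"]
        prof = correlation_by_distance(pc, bin_edges_um=[30, 100, 200, 300, 400, 500])
        assert prof["mean_r"][0] > 0.5
        # near Lambda/2 = 450 um the field correlation is negative
        assert prof["mean_r"][4] < 0.0
        # monotone decay over the first three bins
        assert prof["mean_r"][0] > prof["mean_r"][1] > prof["mean_r"][2]


class TestShuffleNull:
    @given(st.integers(min_value=0, max_value=1000))
    @settings(derandomize=True, max_examples=10)
    def test_shuffle_preserves_each_cells_marginal(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(12, 5))
        shuffled = np.empty_like(z)
        gen = np.random.default_rng(seed + 1)
        for c in range(5):
            shuffled[:, c] = z[gen.permutation(12), c]
        for c in range(5):
            assert np.array_equal(np.sort(shuffled[:, c]), np.sort(z[:, c]))

    def test_same_seed_identical_null(self, cellular_setup):
        ev = cellular_setup["evset"]
        a = cell_shuffle_null(ev, n_shuffles=5, seed=3)
        b = cell_shuffle_null(ev, n_shuffles=5, seed=3)
        assert np.array_equal(a["null_medians"], b["null_medians"])

    def test_iid_cells_give_unremarkable_p(self):
        # exchangeable (unstandardized) i.i.d. event values: within-cell
        # shuffling is then an exact symmetry, so p is uniform.  (Per-frame
        # z-scoring would add a -1/(n_cells - 1) correlation bias that makes
        # the null conservative, never anticonservative.)
        ps = []
        for rep in range(11):
            rng = np.random.default_rng(100 + rep)
            z = rng.normal(size=(80, 40))
            pos = rng.random((40, 2)) * 300
            ev = CellEventSet(
                events=[(i, i, i) for i in range(80)],
                event_frame_matrix=z,
                zscored_matrix=z,
                positions_um=pos,
            )
            ps.append(cell_shuffle_null(ev, n_shuffles=40, seed=rep)["p_value"])
        assert 0.05 < np.median(ps) < 0.95


class TestDistanceAndLci:
    def test_pairs_below_first_edge_excluded(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        d = np.array([[0, 10, 400], [10, 0, 400], [400, 400, 0]])
        pc = PairCorrMatrix(r=r, distances_um=d, n_events=10)
        prof = correlation_by_distance(pc, bin_edges_um=[30, 100, 500])
        assert prof["n_pairs"][0] == 0
        assert prof["n_pairs"][1] == 2

    def test_single_pair_bin_mean_defined_sem_flagged(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.42
        d = np.array([[0, 60], [60, 0]])
        pc = PairCorrMatrix(r=r, distances_um=d, n_events=10)
        prof = correlation_by_distance(pc, bin_edges_um=[30, 100])
        assert prof["mean_r"][0] == pytest.approx(0.42)
        assert np.isnan(prof["sem_r"][0])

    def test_uniform_positive_correlations_give_unit_lci(self):
        n = 10
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 1.0)
        rng = np.random.default_rng(6)
        pos = rng.random((n, 2)) * 400
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        pc = PairCorrMatrix(r=r, distances_um=d, n_events=20)
        prof = local_coherence_index(pc)
        defined = np.isfinite(prof.lci)
        assert np.allclose(prof.lci[defined], 1.0)

    def test_balanced_signs_give_zero_lci(self):
        # two interleaved populations, + within and - across, equal counts
        n = 8
        r = np.full((n, n), -0.5)
        labels = np.arange(n) % 2
        same = labels[:, None] == labels[None, :]
        r[same] = 0.5
        np.fill_diagonal(r, 1.0)
        d = np.full((n, n), 50.0)
        np.fill_diagonal(d, 0.0)
        pc = PairCorrMatrix(r=r, distances_um=d, n_events=20)
        prof = local_coherence_index(pc, annuli_um=np.array([30.0]), annulus_width_um=50.0)
        # each seed sees 3 positive and 4 negative neighbors -> LCI -1/7
        assert prof.lci[0] == pytest.approx(-1 / 7)

    def test_zero_crossing_near_field_prediction(self, cellular_setup):
        pc = cellular_setup["pc"]
        prof = local_coherence_index(pc)
        crossing = lci_zero_crossing_um(prof)
        # first zero of J0(2 pi r / Lambda): r = 0.383 * 900 um
        assert crossing == pytest.approx(0.383 * 900, abs=100)
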