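"""Band-pass filtering, seed correlations, surrogate transforms, maxima."""

import itertools

import numpy as np
import pytest

from modcortex.corrnet import (
    PatternEnsemble,
    bandpass_filter_patterns,
    correlation_pattern,
    correlation_variance_rings,
    correlation_vs_distance,
    dog_transfer,
    find_correlation_maxima,
    longrange_significance,
    make_surrogate_ensemble,
    transform_pattern,
)


class TestBandpass:
    def test_constant_pattern_filters_to_zero(self):
        mask = np.ones((40, 40), bool)
        ens = bandpass_filter_patterns(
            np.full((1, 40, 40), 7.0), mask, 19.0, target_grid=(40, 40)
        )
        assert np.abs(ens.patterns).max() < 1e-10

    def test_sinusoid_attenuation_matches_closed_form(self):
        pix, lam = 19.0, 900.0
        ny, nx = 135, 160
        x = np.arange(nx) * pix
        pat = np.sin(2 * np.pi * x / lam)[None, :] * np.ones((ny, 1))
        mask = np.ones((ny, nx), bool)
        ens = bandpass_filter_patterns(
            pat[None], mask, pix, s_high_um=195, s_low_um=33, target_grid=(ny, nx)
        )
        measured = np.sqrt(2) * ens.patterns[0][30:100, 30:130].std()
        expected = dog_transfer(2 * np.pi / lam, 33, 195)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_downsamples_camera_grid_to_analysis_grid(self):
        rng = np.random.default_rng(0)
        pat = rng.random((1, 540, 640))
        ens = bandpass_filter_patterns(
            pat, np.ones((540, 640), bool), 4.7, target_grid=(135, 160)
        )
        assert ens.patterns.shape == (1, 135, 160)
        assert ens.grid_pixel_um == pytest.approx(4.7 * 4)

    def test_invalid_filter_scales_rejected(self):
        with pytest.raises(ValueError, match="s_low"):
            bandpass_filter_patterns(
                np.zeros((1, 40, 40)), np.ones((40, 40), bool), 19.0,
                s_high_um=100, s_low_um=200, target_grid=(40, 40),
            )

    def test_linearity_in_pattern_scale(self):
        rng = np.random.default_rng(1)
        pat = rng.normal(size=(1, 40, 40))
        mask = np.ones((40, 40), bool)
        a = bandpass_filter_patterns(pat, mask, 19.0, target_grid=(20, 20))
        b = bandpass_filter_patterns(3.0 * pat, mask, 19.0, target_grid=(20, 20))
        assert np.allclose(b.patterns, 3.0 * a.patterns)


class TestCorrelationPattern:
    def test_matches_per_pixel_pearson_loop(self):
        rng = np.random.default_rng(2)
        pats = rng.normal(size=(20, 10, 10))
        ens = PatternEnsemble(pats, 100.0, np.ones((10, 10), bool))
        cf = correlation_pattern(ens, (3, 4))
        for y, x in itertools.product(range(10), range(10)):
            expected = np.corrcoef(pats[:, y, x], pats[:, 3, 4])[0, 1]
            assert cf.values[y, x] == pytest.approx(expected, abs=1e-12)

    def test_seed_correlation_is_unity(self):
        rng = np.random.default_rng(3)
        ens = PatternEnsemble(rng.normal(size=(10, 8, 8)), 100.0, np.ones((8, 8), bool))
        assert correlation_pattern(ens, (2, 2)).values[2, 2] == pytest.approx(1.0)

    def test_symmetry_in_seed_and_target(self):
        rng = np.random.default_rng(4)
        ens = PatternEnsemble(rng.normal(size=(15, 6, 6)), 100.0, np.ones((6, 6), bool))
        c1 = correlation_pattern(ens, (1, 2)).values[4, 5]
        c2 = correlation_pattern(ens, (4, 5)).values[1, 2]
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_antipodal_pair_gives_sign_field(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(12, 12))
        ens = PatternEnsemble(np.stack([P, -P]), 100.0, np.ones((12, 12), bool))
        cf = correlation_pattern(ens, (6, 6))
        assert np.allclose(np.abs(cf.values), 1.0)
        assert np.allclose(cf.values, np.sign(P * P[6, 6]))

    def test_null_correlations_bounded(self):
        rng = np.random.default_rng(6)
        pats = rng.normal(size=(100, 30, 30))
        ens = PatternEnsemble(pats, 100.0, np.ones((30, 30), bool))
        cf = correlation_pattern(ens, (15, 15))
        far = np.ones((30, 30), bool)
        far[12:19, 12:19] = False
        assert (np.abs(cf.values[far]) < 0.3).mean() > 0.99

    def test_degenerate_seed_rejected(self):
        rng = np.random.default_rng(7)
        pats = rng.normal(size=(10, 5, 5))
        pats[:, 2, 2] = 1.0
        ens = PatternEnsemble(pats, 100.0, np.ones((5, 5), bool))
        with pytest.raises(ValueError, match="degenerate seed"):
            correlation_pattern(ens, (2, 2))


class TestSurrogates:
    def test_zero_rotation_no_flip_is_identity(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(30, 40))
        m = np.ones((30, 40), bool)
        out, valid = transform_pattern(f, m, 0.0, False, False, (14.5, 19.5))
        assert valid.all()
        assert np.allclose(out, f)

    def test_half_turn_is_involution(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(31, 41))
        m = np.ones((31, 41), bool)
        c = (15.0, 20.0)
        p1, v1 = transform_pattern(f, m, 180, False, False, c)
        p2, v2 = transform_pattern(np.where(v1, p1, 0.0), m, 180, False, False, c)
        inner = v1 & v2
        assert np.abs(p2[inner] - f[inner]).max() < 1e-10

    def test_half_turn_preserves_value_multiset(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=(20, 20))
        m = np.ones((20, 20), bool)
        p1, v1 = transform_pattern(f, m, 180, False, False, (9.5, 9.5))
        assert v1.all()
        assert np.allclose(np.sort(p1.ravel()), np.sort(f.ravel()))

    def test_same_seed_same_transforms(self, structured):
        a = make_surrogate_ensemble(structured["ensemble"], n_surrogates=3, seed=5)
        b = make_surrogate_ensemble(structured["ensemble"], n_surrogates=3, seed=5)
        assert np.array_equal(a.angles_deg, b.angles_deg)
        assert np.array_equal(a.flip_x, b.flip_x)

    def test_angles_are_ten_degree_multiples(self, structured):
        s = make_surrogate_ensemble(structured["ensemble"], n_surrogates=5, seed=6)
        assert np.all(s.angles_deg % 10 == 0)
        assert s.angles_deg.max() < 360


class TestMaxima:
    @staticmethod
    def _bumps(centers, pix=19.0, shape=(135, 160), sigma=150.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float) * pix
        f = np.zeros(shape)
        for i, (cy, cx) in enumerate(centers):
            f += (1.0 - 0.1 * i) * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
            )
        return f

    def test_well_separated_bumps_both_found(self):
        f = self._bumps([(1300, 1000), (1300, 2500)])
        maxima = find_correlation_maxima(f, 19.0, 800.0)
        assert len(maxima) == 2

    def test_close_bumps_suppressed_to_higher(self):
        f = self._bumps([(1300, 1000), (1300, 1500)])
        maxima = find_correlation_maxima(f, 19.0, 800.0)
        assert len(maxima) == 1
        (pos, r) = maxima[0]
        assert abs(pos[1] * 19.0 - 1000) < 3 * 19.0

    def test_constant_field_has_no_strict_maxima(self):
        assert find_correlation_maxima(np.ones((30, 30)), 19.0, 800.0) == []


class TestDistanceProfiles:
    def test_rank_one_ensemble_correlates_at_all_distances(self):
        from modcortex.synthdata import SynthParams, make_modular_basis, synth_event_patterns

        p = SynthParams(n_basis=1, n_events=60, pattern_noise_sd=0.05, seed=30)
        basis = make_modular_basis(p)
        raw, _ = synth_event_patterns(basis, p)
        ens = bandpass_filter_patterns(
            raw, p.roi_mask(), p.pixel_um, target_grid=p.grid_shape
        )
        prof = correlation_vs_distance(ens, n_subsample_events=60, seed_stride=12, seed=1)
        defined = np.isfinite(prof.statistic) & (prof.n_per_bin > 5)
        assert (prof.statistic[defined] > 0.9).all()

    def test_fov_too_small_for_band_raises(self):
        rng = np.random.default_rng(11)
        ens = PatternEnsemble(rng.normal(size=(10, 20, 20)), 19.0, np.ones((20, 20), bool))
        surr = make_surrogate_ensemble(ens, n_surrogates=2, seed=0)
        with pytest.raises(ValueError, match="FOV too small"):
            longrange_significance(ens, surr, band_mm=(1.8, 2.2), n_subsample_events=10)

    def test_ring_variance_nonnegative_without_subtraction(self, structured):
        prof = correlation_variance_rings(structured["ensemble"], None, seed_stride=16)
        vals = prof.statistic[np.isfinite(prof.statistic)]
        assert (vals >= 0).all()
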