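"""Density accumulation, direction maps, count series, activation maps."""

import numpy as np
import pytest

from ulmloc.config import ImagingConfig
from ulmloc.decode import Localization
from ulmloc.reconstruct import (ActivationMap, StimulationPattern,
                                accumulate_density, activated_pixel_count,
                                activation_map, directional_map,
                                mb_count_series)
from ulmloc.tracking import Track


def L(frame, row, col):
    return Localization(frame, row, col, 1.0, 1.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def cfg():
    return ImagingConfig()      # lambda = 77 um, fine px 12.3 um, 80x80


class TestDensity:
    def test_point_mass_conservation(self, cfg):
        tr = Track(0, [L(f, 40.0, 40.0) for f in range(100)])
        img = accumulate_density([tr], cfg)
        assert img.density.sum() == 100
        assert img.density.max() == 100

    def test_total_mass_equals_points(self, cfg, rng):
        tracks = []
        total = 0
        for i in range(10):
            n = int(rng.integers(2, 20))
            pts = [L(f, rng.uniform(0, 79), rng.uniform(0, 79))
                   for f in range(n)]
            tracks.append(Track(i, pts))
            total += n
        assert accumulate_density(tracks, cfg).density.sum() == total

    def test_diagonal_track_rasterizes_distinct_pixels(self, cfg):
        # 10 steps of 2 fine px (24.6 um) along the diagonal: larger than
        # the lambda/5 = 15.4 um reconstruction pixel, so all distinct
        tr = Track(0, [L(f, 10.0 + 2 * f, 10.0 + 2 * f) for f in range(10)])
        img = accumulate_density([tr], cfg)
        assert np.count_nonzero(img.density) == 10

    def test_default_grid_is_lambda_over_5(self, cfg):
        img = accumulate_density([Track(0, [L(0, 1, 1)])], cfg)
        assert img.pixel_um == pytest.approx(cfg.wavelength_um / 5)


class TestDirectionalMap:
    def test_upward_track_positive(self, cfg):
        tr = Track(0, [L(f, 60.0 - 2 * f, 40.0) for f in range(10)])
        out = directional_map([tr], cfg)
        assert out.min() >= 0 and out.max() > 0

    def test_balanced_traffic_cancels(self, cfg):
        up = Track(0, [L(f, 60.0 - 2 * f, 40.0) for f in range(10)])
        down = Track(1, [L(f, 60.0 - 2 * (9 - f), 40.0) for f in range(10)])
        out = directional_map([up, down], cfg)
        assert np.allclose(out, 0.0)

    def test_sign_flips_with_axial_axis(self, cfg):
        tr_up = Track(0, [L(f, 60.0 - 2 * f, 40.0) for f in range(10)])
        h = cfg.fov_fine[0]
        tr_flip = Track(0, [L(f, (h - 1) - (60.0 - 2 * f), 40.0)
                            for f in range(10)])
        a = directional_map([tr_up], cfg)
        b = directional_map([tr_flip], cfg)
        assert a.sum() == -b.sum()


class TestCountSeries:
    def test_single_crossing_counted_once(self, cfg):
        # frame_rate 1000: window of 1 s = 1000 frames; crossing in window 2
        tr = Track(0, [L(2000 + f, 40.0, 40.0 + f) for f in range(5)])
        series = mb_count_series([tr], cfg, n_windows=4)
        per_window = series.reshape(4, -1).sum(axis=1)
        assert per_window[2] >= 1
        assert per_window[0] == per_window[1] == per_window[3] == 0

    def test_lingering_track_still_counts_once(self, cfg):
        tr = Track(0, [L(f, 40.0, 40.0) for f in range(5)])  # same pixel
        series = mb_count_series([tr], cfg, n_windows=1)
        assert series.max() == 1

    def test_every_track_touches_some_pixel(self, cfg, rng):
        tracks = [Track(i, [L(0, rng.uniform(0, 79), rng.uniform(0, 79))])
                  for i in range(20)]
        series = mb_count_series(tracks, cfg, n_windows=1)
        assert series.sum() >= len(tracks)


class TestStimulationPattern:
    def test_block_design_and_mask(self):
        p = StimulationPattern(n_cycles=2)
        a = p.series()
        m = p.analysis_mask()
        assert len(a) == 140
        assert a[:30].all() and not a[30:70].any()
        assert m[:30].all() and not m[30:40].any() and m[40:70].all()


class TestActivationMap:
    def _series_from_vector(self, v):
        return np.tile(v[:, None, None], (1, 1, 1))

    def test_perfect_correlation(self):
        p = StimulationPattern(n_cycles=3)
        s = self._series_from_vector(3.0 * p.series() + 1.0)
        amap = activation_map(s, p)
        assert amap.r[0, 0] == pytest.approx(1.0)
        assert amap.activated[0, 0]

    def test_anticorrelation(self):
        p = StimulationPattern(n_cycles=3)
        s = self._series_from_vector(-p.series() + 5.0)
        assert activation_map(s, p).r[0, 0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_zero(self):
        p = StimulationPattern(n_cycles=2)
        s = np.ones((p.total_s, 1, 1))
        amap = activation_map(s, p)
        assert amap.r[0, 0] == 0.0
        assert amap.flagged[0, 0]

    def test_null_noise_rarely_activates(self, rng):
        p = StimulationPattern(n_cycles=15)
        s = rng.standard_normal((p.total_s, 25, 40))
        amap = activation_map(s, p)
        assert np.abs(amap.r).mean() < 0.1
        assert amap.activated.mean() < 0.02

    def test_block_constant_signals_invariant_to_window_doubling(self):
        """Averaging adjacent seconds pairwise leaves r unchanged for
        signals constant within 2-s blocks (transition-free design)."""
        p = StimulationPattern(n_cycles=2, stim_s=4, transition_s=0, rest_s=4)
        base = np.repeat([2.0, 2.0, 0.5, 0.5], 2)
        v = np.tile(base, 2)
        r1 = activation_map(v[:, None, None], p).r[0, 0]
        p2 = StimulationPattern(n_cycles=2, stim_s=2, transition_s=0, rest_s=2)
        v2 = v.reshape(-1, 2).mean(axis=1)
        r2 = activation_map(v2[:, None, None], p2).r[0, 0]
        assert r1 == pytest.approx(r2)


class TestSyntheticVesselRecovery:
    def test_modulated_vessels_detected_nulls_quiet(self, rng):
        """A vessel whose bubble rate doubles under stimulation is flagged
        activated; unmodulated vessels almost never are."""
        from ulmloc.reconstruct import simulate_vessel_counts
        p = StimulationPattern(n_cycles=15)
        series, flags = simulate_vessel_counts(p, rng)
        amap = activation_map(series, p)
        act = amap.activated[:, 0]
        assert act[flags].mean() >= 0.95
        assert act[~flags].mean() <= 0.05


class TestActivatedCount:
    def test_counts_and_boundary(self):
        amap = ActivationMap(np.full((10, 10), 0.3))
        assert activated_pixel_count(amap) == 100
        amap2 = ActivationMap(np.full((10, 10), 0.2))
        assert activated_pixel_count(amap2) == 0        # strict >

    def test_roi_and_monotonicity(self):
        r = np.linspace(0, 1, 100).reshape(10, 10)
        amap = ActivationMap(r)
        roi = np.zeros((10, 10), dtype=bool)
        roi[:5] = True
        assert activated_pixel_count(amap, roi) <= activated_pixel_count(amap)
        counts = [activated_pixel_count(amap, threshold=t)
                  for t in (0.1, 0.3, 0.5, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
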