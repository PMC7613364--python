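"""Season detection and indicator extraction."""

import numpy as np
import pytest
from scipy.optimize import brentq

from phenofill import detect_seasons, extract_pixel_phenology, season_metrics
from phenofill.core_gpr import PredictiveSeries
from phenofill.phenology import phenology_maps
from phenofill.synthetic import CropCurveParams, double_logistic


def _series(t, v):
    return PredictiveSeries(np.asarray(t, float), np.asarray(v, float),
                            np.zeros(len(t)))


class TestDetectSeasons:
    def test_single_triangle(self, triangle_series):
        segs = detect_seasons(triangle_series)
        assert len(segs) == 1
        assert segs[0].peak == (100.0, 5.0)
        assert segs[0].base_level == 0.0

    def test_two_peaks_share_valley_minimum(self):
        t = np.arange(0.0, 401.0)
        v = np.interp(t, [0, 50, 100, 200, 300, 350, 400],
                      [0, 0, 5, 0.5, 5, 0, 0])
        segs = detect_seasons(_series(t, v))
        assert len(segs) == 2
        # brute-force deepest interior minimum between the two peaks
        lo, hi = 100, 300
        valley = lo + int(np.argmin(v[lo:hi + 1]))
        assert segs[0].right_min == (t[valley], v[valley])
        assert segs[0].right_min == segs[1].left_min

    def test_monotone_ramp_has_no_season(self):
        t = np.arange(0.0, 100.0)
        assert detect_seasons(_series(t, t / 100)) == []

    def test_flat_series_has_no_season(self):
        t = np.arange(0.0, 100.0)
        assert detect_seasons(_series(t, np.ones_like(t))) == []

    def test_min_season_length_filters_short_bumps(self):
        t = np.arange(0.0, 200.0)
        v = np.interp(t, [0, 90, 95, 100, 200], [0, 0, 5, 0, 0])
        assert detect_seasons(_series(t, v), min_season_length=150) == []
        assert len(detect_seasons(_series(t, v), min_season_length=30)) == 1

    def test_low_prominence_peaks_ignored(self):
        t = np.arange(0.0, 300.0)
        v = np.interp(t, [0, 50, 100, 150, 200, 250, 300],
                      [0, 0, 5, 4.9, 5.05, 0, 0])
        # the 5.05 bump has prominence 0.15 ~ 3% of range: one season
        assert len(detect_seasons(_series(t, v), min_prominence=0.1)) == 1


class TestSeasonMetrics:
    def test_triangle_analytic_values(self, triangle_series):
        seg = detect_seasons(triangle_series)[0]
        m = season_metrics(seg, triangle_series, threshold_frac=0.20)
        assert m.sos == pytest.approx(60.0)
        assert m.eos == pytest.approx(140.0)
        assert m.los == pytest.approx(80.0)
        assert m.dom == pytest.approx(100.0)
        assert m.amplitude == pytest.approx(5.0)
        assert m.max_value == pytest.approx(5.0)
        assert m.blue_area == pytest.approx(240.0)
        assert m.green_area == pytest.approx(240.0)

    def test_lifted_triangle_distinguishes_blue_from_green(self, triangle_series):
        lifted = _series(triangle_series.times, triangle_series.mean + 1.0)
        seg = detect_seasons(lifted)[0]
        m = season_metrics(seg, lifted)
        assert m.amplitude == pytest.approx(5.0)
        assert (m.sos, m.eos) == (pytest.approx(60.0), pytest.approx(140.0))
        assert m.green_area == pytest.approx(240.0)
        assert m.blue_area == pytest.approx(240.0 + 1.0 * 80.0)

    def test_zero_threshold_spans_minimum_to_minimum(self, triangle_series):
        seg = detect_seasons(triangle_series)[0]
        m = season_metrics(seg, triangle_series, threshold_frac=0.0)
        assert m.sos == seg.left_min[0]
        assert m.eos == seg.right_min[0]

    def test_uncrossed_threshold_reports_missing(self):
        # right minimum far above the threshold level: no EOS crossing
        t = np.arange(0.0, 151.0)
        v = np.interp(t, [0, 50, 100, 150], [0, 0, 5, 4.2])
        segs = detect_seasons(_series(t, v), min_prominence=0.05)
        assert segs, "season should still be detected"
        m = season_metrics(segs[0], _series(t, v))
        assert m.missing_reason is not None
        assert np.isnan(m.eos)

    def test_los_and_amplitude_identities_on_random_curves(self, rng):
        t = np.arange(0.0, 365.0)
        for _ in range(10):
            p = CropCurveParams(rng.uniform(0, 0.5), rng.uniform(1, 4),
                                rng.uniform(60, 120), rng.uniform(180, 280))
            v = double_logistic(t, p) + rng.normal(0, 0.02, t.size)
            for m in extract_pixel_phenology(_series(t, v)):
                if m.missing_reason:
                    continue
                assert m.los == pytest.approx(m.eos - m.sos, abs=1e-9)
                assert m.sos < m.dom < m.eos

    def test_constant_shift_only_moves_blue_area(self, triangle_series):
        shifted = _series(triangle_series.times, triangle_series.mean + 0.7)
        m0 = season_metrics(detect_seasons(triangle_series)[0], triangle_series)
        m1 = season_metrics(detect_seasons(shifted)[0], shifted)
        assert m1.sos == pytest.approx(m0.sos)
        assert m1.eos == pytest.approx(m0.eos)
        assert m1.amplitude == pytest.approx(m0.amplitude)
        assert m1.green_area == pytest.approx(m0.green_area)
        assert m1.blue_area == pytest.approx(m0.blue_area + 0.7 * m0.los)

    @pytest.mark.parametrize("p", [
        CropCurveParams(0.30, 2.6, 90, 200, 0.10, 0.12),
        CropCurveParams(0.25, 3.6, 160, 290, 0.11, 0.10),
        CropCurveParams(0.40, 1.9, 80, 300, 0.08, 0.08),
    ])
    def test_double_logistic_crossings_within_one_day(self, p):
        """On a daily grid the extracted SOS/EOS agree with the closed-form
        20%-amplitude crossings of the generating curve to within a day."""
        t = np.arange(0.0, 366.0)
        series = _series(t, double_logistic(t, p))
        found = extract_pixel_phenology(series)
        assert len(found) == 1
        m = found[0]
        level = p.base + 0.2 * p.amplitude
        f = lambda x: double_logistic(np.array([x]), p)[0] - level
        sos_exact = brentq(f, p.sos_true - 60, (p.sos_true + p.eos_true) / 2)
        eos_exact = brentq(f, (p.sos_true + p.eos_true) / 2, p.eos_true + 60)
        assert abs(m.sos - sos_exact) <= 1.0
        assert abs(m.eos - eos_exact) <= 1.0


class TestPhenologyMaps:
    def _uniform_recon(self, triangle_series, H=4, W=4):
        from phenofill.gapfill import ReconstructionResult
        T = triangle_series.times.size
        mean = np.broadcast_to(triangle_series.mean[:, None, None],
                               (T, H, W)).copy()
        sd = np.zeros_like(mean)
        return ReconstructionResult(mean, sd, triangle_series.times,
                                    np.zeros((H, W), int), "fixed")

    def test_uniform_scene_gives_constant_maps(self, triangle_series):
        recon = self._uniform_recon(triangle_series)
        records, maps = phenology_maps(recon)
        assert len(records) == 16
        sos_map = maps[0]["sos"]
        assert np.allclose(sos_map, 60.0)
        assert np.allclose(maps[0]["amplitude"], 5.0)

    def test_flagged_pixel_is_nodata_everywhere(self, triangle_series):
        recon = self._uniform_recon(triangle_series)
        recon.flags[1, 2] = 1  # insufficient data
        records, maps = phenology_maps(recon)
        assert not ((records["row"] == 1) & (records["col"] == 2)).any()
        for layer in maps[0].values():
            assert np.isnan(layer[1, 2])

    def test_year_slotting_assigns_by_dom(self):
        t = np.arange(0.0, 731.0)
        p = CropCurveParams(0.3, 2.6, 90, 200)
        v = double_logistic(t, p, years=2)
        recon = self._uniform_recon(_series(t, v), H=1, W=1)
        records, maps = phenology_maps(recon, slot_by="year")
        assert set(records["slot"]) == {0, 1}
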