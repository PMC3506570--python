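"""Transmural curves, TCI, HA histogram/variance ratio, zero crossing."""

import numpy as np
import pytest

from cardiotract.helix_angle import CardiacFrame, summarize_ha
from cardiotract.quantify import (
    TransmuralCurves,
    ha_histogram,
    tci,
    transmural_curves,
    zero_crossing,
)
from cardiotract.tractography import Streamline, TractSet


def _linear_curves(n=2001, spread=10.0):
    x = np.linspace(0.0, 1.0, n)
    med = 60.0 - 120.0 * x
    return TransmuralCurves(x, med - spread, med, med + spread, np.ones(n, int))


def _tract(point, stats):
    s = Streamline(np.asarray(point, float).reshape(1, 3), "length_cap", "length_cap")
    s.classification = summarize_ha(stats)
    return s


def _straight_frame():
    # axis +z through the origin
    t = np.linspace(-10.0, 10.0, 5)
    cents = np.zeros((5, 3))
    cents[:, 2] = t
    return CardiacFrame(np.array([0.0, 0.0, 1.0]), np.zeros(3), t, cents)


class TestTransmuralCurves:
    def test_constant_ha_gives_constant_curves(self):
        frame = _straight_frame()
        roi = np.zeros((14, 4, 4), bool)
        roi[10:12, 1, :2] = True
        tracts = TractSet([
            _tract([10.5, 1.5, 0.5], [5.0, 5.0, 5.0]),
            _tract([11.5, 1.5, 1.5], [5.0, 5.0, 5.0]),
        ])
        cv = transmural_curves(tracts, roi, frame, (1.0, 1.0, 1.0))
        assert np.allclose(cv.ha_min, 5.0) and np.allclose(cv.ha_med, 5.0)
        assert np.allclose(cv.ha_max, 5.0)

    def test_nested_averaging_matches_hand_computation(self):
        # 2x2x2 ROI: two transmural depths (x index), two anterior-posterior
        # positions (y), two base-apex slices (z); four single-voxel tracts
        frame = _straight_frame()
        roi = np.zeros((14, 4, 4), bool)
        roi[10:12, 1:3, 0:2] = True
        tracts = TractSet([
            _tract([10.5, 1.5, 0.5], [10.0, 20.0, 30.0]),   # t0, a0, z0
            _tract([10.5, 1.5, 1.5], [20.0, 30.0, 40.0]),   # t0, a0, z1
            _tract([10.5, 2.5, 0.5], [0.0, 10.0, 20.0]),    # t0, a1, z0
            _tract([11.5, 1.5, 0.5], [40.0, 50.0, 60.0]),   # t1, a0, z0
        ])
        cv = transmural_curves(tracts, roi, frame, (1.0, 1.0, 1.0))
        # depth 0: columns (a0): mean over z of (10,20,30),(20,30,40) ->
        # (15,25,35); (a1): (0,10,20); then mean over a -> (7.5, 17.5, 27.5)
        assert cv.x[0] == pytest.approx(0.0) and cv.x[-1] == pytest.approx(1.0)
        assert cv.ha_min[0] == pytest.approx(7.5)
        assert cv.ha_med[0] == pytest.approx(17.5)
        assert cv.ha_max[0] == pytest.approx(27.5)
        # depth 1: single tract
        assert (cv.ha_min[1], cv.ha_med[1], cv.ha_max[1]) == (40.0, 50.0, 60.0)
        assert cv.counts[0] == 3 and cv.counts[1] == 1

    def test_curves_ordered_min_med_max(self, sheep_run):
        cv = sheep_run.curves
        assert np.all(cv.ha_min <= cv.ha_med + 1e-9)
        assert np.all(cv.ha_med <= cv.ha_max + 1e-9)
        assert np.all(np.diff(cv.x) > 0)

    def test_noiseless_phantom_median_curve_is_linear_and_symmetric(self, sheep_run_noiseless):
        cv = sheep_run_noiseless.curves
        # the generating profile is linear in depth: the median curve must be
        # linear (small residuals), decreasing, and antisymmetric about its
        # zero crossing for the symmetric +/-50 architecture
        interior = (cv.x > 0.0) & (cv.x < 1.0)  # surface layers flatten slightly
        slope, intercept = np.polyfit(cv.x[interior], cv.ha_med[interior], 1)
        resid = cv.ha_med[interior] - (slope * cv.x[interior] + intercept)
        assert np.abs(resid).max() < 2.0
        assert slope < -60.0  # spans most of the +/-50 range across the wall
        assert np.abs(cv.ha_med + cv.ha_med[::-1]).max() < 4.0  # antisymmetry
        assert sheep_run_noiseless.zero_crossing == pytest.approx(0.5, abs=0.05)

    def test_empty_roi_raises(self, sheep_run):
        with pytest.raises(ValueError):
            transmural_curves(sheep_run.tracts, np.zeros((3, 3, 3), bool),
                              sheep_run.phantom.frame, (2.0, 2.0, 2.0))


class TestTCI:
    def test_closed_form_linear_family(self):
        res = tci(_linear_curves())
        # int (60-120x)^2 dx = 1200; envelopes +/-10 -> 2 * 100
        assert res.numerator == pytest.approx(1200.0, rel=1e-4)
        assert res.denominator == pytest.approx(200.0, rel=1e-6)
        assert res.tci == pytest.approx(6.0, rel=1e-4)

    def test_perfect_coherence_gives_infinity_sentinel(self):
        x = np.linspace(0, 1, 11)
        med = np.full(11, 30.0)
        res = tci(TransmuralCurves(x, med, med, med, np.ones(11, int)))
        assert np.isinf(res.tci) and res.coherent_flag

    def test_zero_over_zero_raises(self):
        x = np.linspace(0, 1, 11)
        z = np.zeros(11)
        with pytest.raises(ValueError):
            tci(TransmuralCurves(x, z, z, z, np.ones(11, int)))

    def test_invariant_under_global_sign_flip(self):
        cv = _linear_curves()
        flipped = TransmuralCurves(cv.x, -cv.ha_max, -cv.ha_med, -cv.ha_min, cv.counts)
        assert tci(flipped).tci == pytest.approx(tci(cv).tci, rel=1e-12)

    @pytest.mark.parametrize("delta", [5.0, 10.0, 20.0])
    def test_strictly_decreases_with_envelope_spread(self, delta):
        base = tci(_linear_curves(spread=delta)).tci
        wider = tci(_linear_curves(spread=delta + 1.0)).tci
        assert wider < base

    def test_requires_three_samples(self):
        x = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            tci(TransmuralCurves(x, x, x + 1, x + 2, np.ones(2, int)))


class TestHistogram:
    def _tractset(self, medians):
        return TractSet([_tract([0, 0, 0], [m, m, m]) for m in medians])

    def test_mirror_symmetric_values_give_unit_ratio(self):
        h = ha_histogram(self._tractset([-40.0, -20.0, 20.0, 40.0]))
        assert h.variance_ratio == pytest.approx(1.0)

    def test_zero_negative_variance(self):
        h = ha_histogram(self._tractset([-10.0, -10.0, 30.0, 50.0]))
        assert h.variance_ratio == pytest.approx(0.0)

    def test_reciprocal_under_sign_flip(self):
        vals = [-35.0, -10.0, -5.0, 12.0, 30.0, 44.0]
        a = ha_histogram(self._tractset(vals)).variance_ratio
        b = ha_histogram(self._tractset([-v for v in vals])).variance_ratio
        assert b == pytest.approx(1.0 / a)

    def test_zero_excluded_and_undefined_flag(self):
        h = ha_histogram(self._tractset([0.0, 0.0, -5.0, 10.0, 20.0]))
        assert not h.ratio_defined and np.isnan(h.variance_ratio)
        assert h.n_negative == 1 and h.n_positive == 2

    def test_bins_cover_half_circle(self):
        h = ha_histogram(self._tractset([-40.0, -20.0, 20.0, 40.0]), bin_width=5.0)
        assert h.bin_edges[0] == -90.0 and h.bin_edges[-1] == 90.0
        assert h.counts.sum() == 4


class TestZeroCrossing:
    def test_linear_root(self):
        x = np.linspace(0, 1, 13)
        cv = TransmuralCurves(x, x, 60.0 - 120.0 * x, x, np.ones(13, int))
        zc, all_zc = zero_crossing(cv)
        assert zc == pytest.approx(0.5, abs=1e-9)
        assert len(all_zc) == 1

    def test_all_positive_none_found(self):
        x = np.linspace(0, 1, 5)
        cv = TransmuralCurves(x, x, 10.0 + x, x, np.ones(5, int))
        zc, all_zc = zero_crossing(cv)
        assert zc is None and all_zc == []

    def test_remote_phantom_crossing_shifted_toward_epicardium(self, remote_run, sheep_run):
        assert remote_run.zero_crossing is not None
        assert remote_run.zero_crossing > 0.5
        assert remote_run.zero_crossing > sheep_run.zero_crossing


class TestStudyOrderings:
    def test_roi_tci_exceeds_pi_r_tci(self, sheep_run, sheep_run_roi):
        assert sheep_run_roi.tci.tci > sheep_run.tci.tci

    def test_remote_variance_ratio_below_normal(self, remote_run, sheep_run):
        assert remote_run.histogram.variance_ratio < sheep_run.histogram.variance_ratio
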