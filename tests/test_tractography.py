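"""RK4 streamline integration, termination, seeding, length policies."""

import numpy as np
import pytest

from cardiotract.tensor_field import EigenField
from cardiotract.tractography import (
    LengthPolicy,
    TrackingParams,
    effective_radius,
    grow_branch,
    make_seeds,
    track,
)


def _uniform_field(direction, n=16, spacing=(1.0, 1.0, 1.0)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    evecs = np.zeros((n, n, n, 3, 3))
    evecs[..., :, 0] = d
    evals = np.tile([1e-3, 5e-4, 2e-4], (n, n, n, 1))
    return EigenField(evals, evecs, spacing, np.ones((n, n, n), bool))


def _circle_sampler():
    def sample(pts, refs):
        d = np.stack([-pts[:, 1], pts[:, 0], np.zeros(len(pts))], axis=1)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        flip = np.sum(d * refs, axis=1) < 0
        d[flip] *= -1
        return d, np.ones(len(pts), bool), np.zeros(len(pts), bool)

    return sample


def _all_inside(pts):
    return np.ones(len(pts), bool)


class TestRK4:
    def test_uniform_field_gives_straight_equispaced_polyline(self):
        f = _uniform_field([1, 0, 0])
        params = TrackingParams(max_steps=10)
        ts = track(f, np.array([[8.0, 8.0, 8.0]]), params, LengthPolicy("unlimited"))
        p = ts.streamlines[0].points
        assert np.allclose(p[:, 1], 8.0) and np.allclose(p[:, 2], 8.0)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        assert np.allclose(seg, 0.25, atol=1e-9)

    def test_circular_field_radial_drift_below_tolerance(self):
        # tangents of circles about the z axis: after one full revolution at
        # step R/100 the streamline must stay within 1e-3 R of the circle
        R, h = 10.0, 0.1
        pts, _, _ = grow_branch(
            _circle_sampler(), _all_inside,
            np.array([[R, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]),
            h, np.cos(np.radians(35)), int(np.ceil(2 * np.pi * R / h)),
        )
        drift = np.abs(np.linalg.norm(pts[0][:, :2], axis=1) - R)
        assert drift.max() < 1e-3 * R

    def test_step_halving_reduces_endpoint_error_fourth_order(self):
        R = 10.0
        errs = []
        for h, k in ((R / 100, 150), (R / 200, 300)):
            pts, _, _ = grow_branch(
                _circle_sampler(), _all_inside,
                np.array([[R, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]),
                h, np.cos(np.radians(35)), k,
            )
            ang = k * h / R
            target = R * np.array([np.cos(ang), np.sin(ang), 0.0])
            errs.append(np.linalg.norm(pts[0][-1] - target))
        assert errs[0] / errs[1] >= 8.0

    def test_antipodal_invariance_of_tract_geometry(self, small_phantom):
        from cardiotract.tensor_field import eigendecompose

        field = eigendecompose(small_phantom.tensors)
        rng = np.random.default_rng(0)
        signs = rng.choice([-1.0, 1.0], size=field.mask.shape)[..., None]
        flipped = EigenField(
            field.eigenvalues, field.eigenvectors * signs[..., None], field.spacing, field.mask
        )
        seeds = np.array([[23.0, 18.0, 22.0], [18.0, 24.5, 20.0], [30.5, 18.5, 18.0]])
        params = TrackingParams(max_steps=60)
        a = track(field, seeds, params, LengthPolicy("unlimited"))
        b = track(flipped, seeds, params, LengthPolicy("unlimited"))
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.allclose(sa.points, sb.points, atol=1e-9)


class TestTermination:
    def test_abrupt_direction_change_terminates_with_angle_reason(self):
        # 80 deg change across the x=16 plane; with one-voxel steps the
        # propagation angle between consecutive segments exceeds 35 deg
        n = 32
        e1 = np.zeros((n, n, n, 3))
        e1[...] = [1.0, 0.0, 0.0]
        th = np.radians(80)
        e1[16:] = [np.cos(th), np.sin(th), 0.0]
        evecs = np.zeros((n, n, n, 3, 3))
        evecs[..., :, 0] = e1
        evals = np.tile([1e-3, 5e-4, 2e-4], (n, n, n, 1))
        f = EigenField(evals, evecs, (1.0, 1.0, 1.0), np.ones((n, n, n), bool))
        seeds = np.array([[4.5, 16.5, 16.5], [6.5, 10.5, 16.5], [3.5, 20.5, 12.5]])
        ts = track(f, seeds, TrackingParams(step_fraction=1.0), LengthPolicy("unlimited"))
        assert len(ts) == 3
        for s in ts:
            assert s.termination_fwd == "angle"
            assert s.points[:, 0].max() < 17.5  # stops at the interface

    def test_every_streamline_has_termination_reasons(self, sheep_run):
        reasons = {"angle", "mask_exit", "length_cap", "invalid_voxel"}
        for s in sheep_run.tracts:
            assert s.termination_fwd in reasons
            assert s.termination_bwd in reasons

    def test_nan_field_terminates_as_invalid_voxel(self):
        f = _uniform_field([1, 0, 0])
        f.eigenvectors[10:, :, :, :, 0] = np.nan
        ts = track(f, np.array([[8.0, 8.0, 8.0]]), TrackingParams(max_steps=50),
                   LengthPolicy("unlimited"))
        assert ts.streamlines[0].termination_fwd == "invalid_voxel"


class TestLengthPolicies:
    def test_pi_r_caps_arc_length(self, sheep_run):
        h = 0.25 * min(sheep_run.phantom.tensors.spacing)
        cap = np.pi * sheep_run.R + h
        for s in sheep_run.tracts:
            assert s.length <= cap

    def test_roi_clip_keeps_points_inside_roi(self, sheep_run_roi):
        from cardiotract.phantom import sector_roi

        roi = sector_roi(sheep_run_roi.phantom)
        sp = np.asarray(sheep_run_roi.phantom.tensors.spacing)
        for s in sheep_run_roi.tracts:
            iv = np.floor(s.points / sp).astype(int)
            assert roi[iv[:, 0], iv[:, 1], iv[:, 2]].all()

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            LengthPolicy("pi_r")
        with pytest.raises(ValueError):
            LengthPolicy("bogus")


class TestSeeds:
    def test_single_density_uses_voxel_centers(self):
        region = np.zeros((4, 4, 4), bool)
        region[1, 2, 3] = True
        region[0, 0, 0] = True
        s = make_seeds(region, (2.0, 2.0, 2.0), TrackingParams())
        assert s.shape == (2, 3)
        assert {tuple(p) for p in s} == {(1.0, 1.0, 1.0), (3.0, 5.0, 7.0)}

    def test_jitter_deterministic_and_seed_dependent(self):
        region = np.ones((3, 3, 1), bool)
        p = TrackingParams(seeds_per_voxel=4, seed=9)
        a = make_seeds(region, (1.0, 1.0, 1.0), p)
        b = make_seeds(region, (1.0, 1.0, 1.0), p)
        c = make_seeds(region, (1.0, 1.0, 1.0), TrackingParams(seeds_per_voxel=4, seed=10))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert len(a) == 36
        # jittered seeds stay inside their voxels
        assert np.all((a >= 0) & (a <= 3))

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            make_seeds(np.zeros((2, 2, 2), bool), (1, 1, 1), TrackingParams())

    def test_seed_outside_mask_skipped(self):
        f = _uniform_field([0, 0, 1])
        seeds = np.array([[8.0, 8.0, 8.0], [100.0, 8.0, 8.0]])
        ts = track(f, seeds, TrackingParams(max_steps=5), LengthPolicy("unlimited"))
        assert len(ts) == 1
        assert ts.n_skipped_seeds == 1


class TestEffectiveRadius:
    def test_annulus_mean_radius(self):
        from cardiotract import PhantomSpec, generate_phantom

        # inner 25 / outer 35 mm annulus: area-weighted mean radius ~ 30.3
        ph = generate_phantom(
            PhantomSpec(inner_radius=25.0, outer_radius=35.0, height=80.0, spacing=(2.0, 2.0, 2.0))
        )
        r = effective_radius(ph.mask, (2.0, 2.0, 2.0), ph.frame)
        assert r == pytest.approx(30.0, abs=0.5)

    def test_scales_with_spacing(self, small_phantom):
        m = small_phantom.mask
        r1 = effective_radius(m, (1.0, 1.0, 1.0), small_phantom.frame)
        r2 = effective_radius(m, (2.0, 2.0, 2.0))
        assert r2 == pytest.approx(2 * r1, rel=0.02)

    def test_single_slice_falls_back_to_whole_mask(self, small_phantom):
        k = small_phantom.mask.shape[2] // 2
        single = np.zeros_like(small_phantom.mask)
        single[:, :, k] = small_phantom.mask[:, :, k]
        r = effective_radius(single, (1.0, 1.0, 1.0), small_phantom.frame)
        assert 10.0 < r < 16.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            effective_radius(np.zeros((3, 3, 3), bool), (1, 1, 1))
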