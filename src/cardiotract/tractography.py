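"""Streamline tractography of the primary-eigenvector field.

Fiber tracts are grown bidirectionally from seed points by fourth-order
Runge-Kutta integration of the primary eigenvector field e1, with a step
length of one-quarter voxel by default.  Because e1 is axial (e and -e are
the same fiber), every field evaluation is sign-aligned with the incoming
direction before use.  A propagation angle above the threshold (35 degrees
by default) between consecutive streamline segments is the single geometric
termination criterion; tracking also stops on mask exit, invalid tensors,
and the active length policy:

* ``pi_r`` — total tract length capped at half the LV circumference, pi*R,
  shared between the two branches (pi*R/2 each from the seed);
* ``roi_clip`` — growth stops when the streamline leaves a region of
  interest;
* ``unlimited`` — only the hard step cap applies.

All integration happens in batch: every active streamline advances one RK4
step per iteration, so the cost per step is a few vectorized trilinear
interpolations over the whole front.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .tensor_field import EigenField

TERMINATION_NAMES = {0: "active", 1: "angle", 2: "mask_exit", 3: "length_cap", 4: "invalid_voxel"}


@dataclass
class TrackingParams:
    step_fraction: float = 0.25          # step length as fraction of (min) voxel size
    max_propagation_angle: float = 35.0  # degrees, between consecutive segments
    min_points: int = 3                  # shorter tracts are discarded (counted)
    seeds_per_voxel: int = 1
    seed: int = 0                        # RNG seed for jittered seeding
    max_steps: int = 2000                # hard per-branch cap when no pi_r budget applies

    def __post_init__(self) -> None:
        if not (0 < self.step_fraction <= 1):
            raise ValueError("step_fraction must lie in (0, 1]")
        if not (0 < self.max_propagation_angle < 90):
            raise ValueError("max_propagation_angle must lie in (0, 90) degrees")


@dataclass
class LengthPolicy:
    mode: str = "unlimited"              # one of {pi_r, roi_clip, unlimited}
    R: float | None = None               # effective mid-wall radius, mm (pi_r)
    roi: np.ndarray | None = None        # boolean volume (roi_clip)

    def __post_init__(self) -> None:
        if self.mode not in ("pi_r", "roi_clip", "unlimited"):
            raise ValueError(f"unknown length policy mode {self.mode!r}")
        if self.mode == "pi_r" and (self.R is None or self.R <= 0):
            raise ValueError("pi_r policy requires R > 0")
        if self.mode == "roi_clip" and self.roi is None:
            raise ValueError("roi_clip policy requires a roi mask")


@dataclass
class Streamline:
    """An ordered polyline in world millimeters with branch provenance."""

    points: np.ndarray
    termination_fwd: str
    termination_bwd: str
    seed_index: int = -1
    hard_cap_hit: bool = False
    classification: object = field(default=None, repr=False)

    @property
    def length(self) -> float:
        """Arc length: sum of segment norms, mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TractSet:
    streamlines: list[Streamline]
    n_skipped_seeds: int = 0
    n_discarded_short: int = 0

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def make_seeds(region: np.ndarray, spacing, params: TrackingParams) -> np.ndarray:
    """Seed points (world mm) for a boolean region.

    One seed per voxel sits at the voxel center; higher densities jitter
    each seed uniformly within its voxel, reproducibly from ``params.seed``.
    """
    region = np.asarray(region, dtype=bool)
    idx = np.argwhere(region)
    if len(idx) == 0:
        raise ValueError("seeding region is empty")
    sp = np.asarray(spacing, dtype=float)
    if params.seeds_per_voxel == 1:
        return (idx + 0.5) * sp
    rng = np.random.default_rng(params.seed)
    rep = np.repeat(idx, params.seeds_per_voxel, axis=0)
    return (rep + rng.uniform(0.0, 1.0, size=rep.shape)) * sp


def _sample_e1(
    e1: np.ndarray,
    mask: np.ndarray,
    spacing: np.ndarray,
    pts: np.ndarray,
    refs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign-aligned trilinear interpolation of the e1 field at world points.

    Each contributing voxel's eigenvector is flipped to a nonnegative dot
    product with ``refs`` before weighting; out-of-mask corners get zero
    weight.  Returns (unit directions, valid, nan_hit).
    """
    g = pts / spacing - 0.5
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    shape = np.asarray(mask.shape)

    acc = np.zeros_like(pts)
    wsum = np.zeros(len(pts))
    nan_hit = np.zeros(len(pts), dtype=bool)
    for corner in itertools.product((0, 1), repeat=3):
        idx = i0 + corner
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        ci = np.clip(idx, 0, shape - 1)
        w = np.ones(len(pts))
        for ax in range(3):
            w *= f[:, ax] if corner[ax] else (1.0 - f[:, ax])
        w *= inb & mask[ci[:, 0], ci[:, 1], ci[:, 2]]
        v = e1[ci[:, 0], ci[:, 1], ci[:, 2]]
        bad = ~np.all(np.isfinite(v), axis=1) & (w > 0)
        nan_hit |= bad
        w = np.where(bad, 0.0, w)
        sgn = np.where(np.sum(v * refs, axis=1) < 0, -1.0, 1.0)
        acc += (w * sgn)[:, None] * np.where(np.isfinite(v), v, 0.0)
        wsum += w
    norm = np.linalg.norm(acc, axis=1)
    valid = (wsum > 1e-12) & (norm > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = acc / norm[:, None]
    return dirs, valid, nan_hit


def _in_mask(mask: np.ndarray, spacing: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Whether each world point's containing voxel lies inside the mask."""
    idx = np.floor(np.nan_to_num(pts, nan=-1.0) / spacing).astype(np.int64)
    shape = np.asarray(mask.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    ci = np.clip(idx, 0, shape - 1)
    return inb & mask[ci[:, 0], ci[:, 1], ci[:, 2]]


def make_field_sampler(field: EigenField):
    """Build (sample, inside) callables for an eigenvector field.

    ``sample(points, refs)`` returns sign-aligned trilinearly interpolated
    unit directions; ``inside(points)`` tests mask membership of the
    containing voxel.  Analytic samplers with the same signatures can be
    passed to :func:`grow_branch` directly (used by the integrator tests).
    """
    spacing = np.asarray(field.spacing, dtype=float)
    e1 = field.primary
    mask = field.mask

    def sample(pts, refs):
        return _sample_e1(e1, mask, spacing, pts, refs)

    def inside(pts):
        return _in_mask(mask, spacing, pts)

    return sample, inside


def grow_branch(
    sample,
    inside,
    starts: np.ndarray,
    init_dirs: np.ndarray,
    h: float,
    cos_thresh: float,
    n_steps: int,
    budget_is_hard_cap: bool = False,
    roi_inside=None,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Grow one RK4 branch for every seed simultaneously.

    ``sample(points, refs) -> (dirs, valid, nan_hit)`` supplies the (axial)
    direction field; ``inside(points)`` the tracking domain.  Returns
    per-seed point arrays (excluding the start point), termination codes,
    and hard-cap flags.
    """
    n = len(starts)
    pos = starts.copy()
    prev_seg = init_dirs.copy()
    first_step = np.ones(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    reason = np.zeros(n, dtype=np.int8)
    hard_cap = np.zeros(n, dtype=bool)
    history = np.full((n_steps, n, 3), np.nan)
    n_recorded = np.zeros(n, dtype=np.int64)

    for step_i in range(n_steps):
        if not active.any():
            break
        a = np.flatnonzero(active)
        p = pos[a]
        ref = prev_seg[a]

        k1, v1, nan1 = sample(p, ref)
        k2, v2, nan2 = sample(p + 0.5 * h * k1, k1)
        k3, v3, nan3 = sample(p + 0.5 * h * k2, k2)
        k4, v4, nan4 = sample(p + h * k3, k3)
        stage_ok = v1 & v2 & v3 & v4
        nan_any = nan1 | nan2 | nan3 | nan4

        delta = (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        newpos = p + delta
        seg_norm = np.linalg.norm(delta, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            seg_dir = delta / seg_norm[:, None]

        cosang = np.sum(seg_dir * ref, axis=1)
        angle_ok = first_step[a] | (cosang >= cos_thresh)
        in_dom = inside(newpos) & stage_ok
        in_roi = np.ones(len(a), dtype=bool) if roi_inside is None else roi_inside(newpos)

        ok = stage_ok & angle_ok & in_dom & in_roi & (seg_norm > 1e-12)
        # termination reason priority: invalid field > angle > roi cap > mask exit
        code = np.full(len(a), 2, dtype=np.int8)
        code[stage_ok & ~angle_ok] = 1
        code[stage_ok & angle_ok & in_dom & ~in_roi] = 3
        code[nan_any & ~stage_ok] = 4

        ia = a[ok]
        history[step_i, ia] = newpos[ok]
        n_recorded[ia] += 1
        pos[ia] = newpos[ok]
        prev_seg[ia] = seg_dir[ok]
        first_step[ia] = False

        stopped = a[~ok]
        reason[stopped] = code[~ok]
        active[stopped] = False

    still = np.flatnonzero(active)
    reason[still] = 3
    hard_cap[still] = budget_is_hard_cap

    pts_out = []
    for i in range(n):
        m = n_recorded[i]
        pts_out.append(history[:m, i, :].copy())
    return pts_out, reason, hard_cap


def track(
    field: EigenField,
    seeds: np.ndarray,
    params: TrackingParams,
    policy: LengthPolicy | None = None,
) -> TractSet:
    """Track bidirectional streamlines from seeds through the e1 field.

    The backward branch integrates -e1; branches are concatenated through
    the seed point.  Seeds outside the mask are skipped and counted; tracts
    with fewer than ``params.min_points`` vertices are discarded and
    counted.  Flagged voxels (non-SPD fits) must already be excluded from
    the mask by the caller, or carry NaN eigenvectors.
    """
    policy = policy or LengthPolicy()
    spacing = np.asarray(field.spacing, dtype=float)
    h = params.step_fraction * float(spacing.min())
    cos_thresh = float(np.cos(np.radians(params.max_propagation_angle)))
    mask = field.mask
    e1 = field.primary

    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    ok = _in_mask(mask, spacing, seeds)
    if policy.mode == "roi_clip":
        ok &= _in_mask(policy.roi, spacing, seeds)
    n_skipped = int((~ok).sum())
    seeds_in = seeds[ok]
    seed_ids = np.flatnonzero(ok)
    if len(seeds_in) == 0:
        return TractSet([], n_skipped_seeds=n_skipped)

    # initial direction: e1 of the containing voxel, sign fixed to the
    # +hemisphere by the first nonzero component
    vi = np.floor(seeds_in / spacing).astype(np.int64)
    d0 = e1[vi[:, 0], vi[:, 1], vi[:, 2]].copy()
    for comp in range(3):
        sel = np.abs(d0[:, comp]) > 1e-12
        flip = sel & (d0[:, comp] < 0)
        d0[flip] *= -1.0
        if comp == 0:
            fixed = sel
        else:
            flip &= ~fixed
            fixed |= sel

    if policy.mode == "pi_r":
        per_branch = max(int(np.floor((np.pi * policy.R / 2.0) / h)), 1)
        hard = False
    else:
        per_branch = params.max_steps
        hard = True
    roi_inside = None
    if policy.mode == "roi_clip":
        roi = np.asarray(policy.roi, dtype=bool)
        roi_inside = lambda pts: _in_mask(roi, spacing, pts)  # noqa: E731

    sample, inside = make_field_sampler(field)
    fw_pts, fw_reason, fw_cap = grow_branch(
        sample, inside, seeds_in, d0, h, cos_thresh, per_branch, hard, roi_inside
    )
    bw_pts, bw_reason, bw_cap = grow_branch(
        sample, inside, seeds_in, -d0, h, cos_thresh, per_branch, hard, roi_inside
    )

    streamlines: list[Streamline] = []
    n_short = 0
    for i in range(len(seeds_in)):
        pts = np.vstack([bw_pts[i][::-1], seeds_in[i][None, :], fw_pts[i]])
        if len(pts) < params.min_points:
            n_short += 1
            continue
        streamlines.append(
            Streamline(
                points=pts,
                termination_fwd=TERMINATION_NAMES[int(fw_reason[i])],
                termination_bwd=TERMINATION_NAMES[int(bw_reason[i])],
                seed_index=int(seed_ids[i]),
                hard_cap_hit=bool(fw_cap[i] or bw_cap[i]),
            )
        )
    return TractSet(streamlines, n_skipped_seeds=n_skipped, n_discarded_short=n_short)


def effective_radius(mask: np.ndarray, spacing, frame=None) -> float:
    """Effective LV mid-wall radius R (mm) for the pi*R length policy.

    Mean in-plane distance from the LV long axis over mask voxels in the
    central third of the axial extent (whole mask when the band is
    degenerate, e.g. a single slice).
    """
    from .helix_angle import fit_lv_frame, voxel_centers_world

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if frame is None:
        frame = fit_lv_frame(mask, spacing)
    pts = voxel_centers_world(mask, spacing)
    t = (pts - frame.origin) @ frame.long_axis
    lo, hi = t.min(), t.max()
    third = (hi - lo) / 3.0
    band = (t >= lo + third) & (t <= hi - third)
    if not band.any():
        band = np.ones(len(pts), dtype=bool)
    return float(frame.radial_distance(pts[band]).mean())
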