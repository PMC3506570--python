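"""LV local coordinate frame and helix-angle computation.

The helix angle (HA) of a myofiber is its inclination out of the LV
short-axis plane, measured against the local circumferential direction:
subendocardial fibers run as right-handed helices (positive HA), midwall
fibers are circumferential (HA ~ 0), subepicardial fibers are left-handed
(negative HA).  HA is computed per streamline vertex from the local
orthonormal triad (circumferential c, longitudinal l, radial r) and a whole
tract is then classified by the min / max / median / mean HA along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Global handedness constant: +1 makes subendocardial (right-handed helix)
#: fibers positive, matching the convention that c circulates
#: counterclockwise viewed from the base with the long axis pointing
#: base->apex.  Flip to -1 to invert the HA sign convention globally.
GLOBAL_HA_SIGN = +1.0

#: fibers within this angle of radial have no defined in-plane projection
_RADIAL_TOL = 1e-9


@dataclass
class CardiacFrame:
    """LV local frame: long axis plus a per-slice centerline.

    ``centroid_t`` are sample positions along the long axis (mm, projection
    coordinate) and ``centroids`` the LV in-plane center at each; the frame
    at an arbitrary point uses the linearly interpolated centerline.
    """

    long_axis: np.ndarray          # (3,) unit
    origin: np.ndarray             # (3,) a point on the axis (mm)
    centroid_t: np.ndarray         # (M,) increasing axis coordinates (mm)
    centroids: np.ndarray          # (M, 3) centerline points (mm)

    def center_at(self, t: np.ndarray) -> np.ndarray:
        """Interpolated centerline point for axis coordinate(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(t), 3))
        for k in range(3):
            out[:, k] = np.interp(t, self.centroid_t, self.centroids[:, k])
        return out

    def triads(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (c, l, r) triads at world points, each (N, 3).

        r points outward from the centerline, l is the long axis, and
        c = l x r (circumferential).  Points on the axis raise no error but
        yield NaN radial directions; callers must guard.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        l = np.broadcast_to(self.long_axis, p.shape)
        t = (p - self.origin) @ self.long_axis
        offset = p - self.center_at(t)
        offset = offset - (offset @ self.long_axis)[:, None] * self.long_axis
        norm = np.linalg.norm(offset, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = offset / norm
        c = np.cross(l, r)
        return c, l.copy(), r

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """In-plane distance (mm) of world points from the centerline."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        t = (p - self.origin) @ self.long_axis
        offset = p - self.center_at(t)
        offset = offset - (offset @ self.long_axis)[:, None] * self.long_axis
        return np.linalg.norm(offset, axis=1)


@dataclass
class HAClassification:
    """Whole-tract HA statistics plus the discrete per-vertex values."""

    discrete: np.ndarray           # per-vertex HA, degrees (undefined removed)
    ha_min: float
    ha_max: float
    ha_median: float
    ha_mean: float
    n_undefined: int = 0
    wrap_flag: bool = field(default=False)  # discrete HA jumps > 90 deg


def voxel_centers_world(mask: np.ndarray, spacing) -> np.ndarray:
    """World coordinates (mm) of the centers of True voxels: (i + 0.5) * spacing."""
    idx = np.argwhere(mask)
    return (idx + 0.5) * np.asarray(spacing, dtype=float)


def fit_lv_frame(mask: np.ndarray, spacing) -> CardiacFrame:
    """Fit the LV long axis and per-slice centerline from a myocardium mask.

    The long axis is the principal axis (largest spread) of the mask voxel
    centers; the centerline is the in-plane centroid binned along the axis
    at one-voxel resolution.  The axis sign is fixed deterministically (its
    largest-magnitude component is made positive); HA is invariant to this
    choice because flipping the axis flips both c and l.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    pts = voxel_centers_world(mask, spacing)
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    w, v = np.linalg.eigh(cov)
    if w[0] < 1e-12 * max(w[-1], 1.0):
        raise ValueError("degenerate mask: voxels are coplanar or collinear")
    axis = v[:, -1]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis

    t = (pts - center) @ axis
    step = float(min(spacing))
    bins = np.round(t / step).astype(int)
    order = np.argsort(bins, kind="stable")
    uniq, start = np.unique(bins[order], return_index=True)
    cent_t = uniq * step
    cents = np.empty((len(uniq), 3))
    groups = np.split(order, start[1:])
    for i, g in enumerate(groups):
        cents[i] = pts[g].mean(axis=0)
    if len(uniq) == 1:
        # single-slice mask: constant centerline
        cent_t = np.array([cent_t[0] - step, cent_t[0] + step])
        cents = np.vstack([cents, cents])
    return CardiacFrame(axis, center, cent_t, cents)


def helix_angle(fibers: np.ndarray, c: np.ndarray, l: np.ndarray) -> np.ndarray:
    """HA in degrees for fiber direction(s) given local c and l axes.

    The fiber is projected onto the wall tangent plane span(c, l); its sign
    is folded so the circumferential component is >= 0, making
    HA(f) = HA(-f), with the result in (-90, 90].  Fibers parallel to the
    radial axis (in-plane projection below 1e-9) return NaN.
    """
    f = np.atleast_2d(np.asarray(fibers, dtype=float))
    fc = np.sum(f * np.atleast_2d(c), axis=1)
    fl = np.sum(f * np.atleast_2d(l), axis=1)
    flip = fc < 0
    fc = np.where(flip, -fc, fc)
    fl = np.where(flip, -fl, fl)
    ha = np.degrees(np.arctan2(fl, fc)) * GLOBAL_HA_SIGN
    # fold atan2's 180 (fc==0, fl<0 after flip cannot occur; fl==0, fc==0 -> undefined)
    ha = np.where(ha <= -90.0, ha + 180.0, ha)
    undefined = np.hypot(fc, fl) < _RADIAL_TOL
    return np.where(undefined, np.nan, ha)


def tract_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents per vertex: central differences, one-sided at the ends."""
    p = np.asarray(points, dtype=float)
    t = np.empty_like(p)
    t[1:-1] = p[2:] - p[:-2]
    t[0] = p[1] - p[0]
    t[-1] = p[-1] - p[-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def summarize_ha(values: np.ndarray, n_undefined: int = 0) -> HAClassification:
    """Whole-tract statistics of a discrete HA list.

    min/max/mean over the list; the median of an even count is the mean of
    the two central values.  A discrete jump above 90 degrees between
    consecutive vertices sets the wrap flag (possible fold across +/-90).
    """
    vals = np.asarray(values, dtype=float)
    wrap = bool(np.any(np.abs(np.diff(vals)) > 90.0))
    return HAClassification(
        discrete=vals,
        ha_min=float(vals.min()),
        ha_max=float(vals.max()),
        ha_median=float(np.median(vals)),
        ha_mean=float(vals.mean()),
        n_undefined=n_undefined,
        wrap_flag=wrap,
    )


def classify_tract(points: np.ndarray, frame: CardiacFrame) -> HAClassification | None:
    """Classify a streamline by its per-vertex HA statistics.

    Vertex tangents come from central differences; undefined-HA vertices
    (radial fibers) are excluded rather than imputed.  Returns None when
    every vertex has undefined HA — such tracts are excluded from all
    statistics.
    """
    points = np.asarray(points, dtype=float)
    tang = tract_tangents(points)
    c, l, _ = frame.triads(points)
    ha = helix_angle(tang, c, l)
    good = np.isfinite(ha)
    vals = ha[good]
    if vals.size == 0:
        return None
    return summarize_ha(vals, n_undefined=int((~good).sum()))
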