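"""Transmural HA curves, the tractographic coherence index, and histograms.

The min / median / max HA classifications of the tracts crossing a region
of interest are reduced to three transmural curves by a two-step averaging:
each tract deposits its scalar statistics into every ROI voxel its polyline
traverses; per (transmural, anterior-posterior) column the deposits are
averaged along the base-apex direction, and the resulting 2D maps are then
averaged along the anterior-posterior direction, leaving one value per
transmural depth.  The tractographic coherence index is

    TCI = int HA_med(x)^2 dx /
          [ int (HA_max - HA_med)^2 dx + int (HA_min - HA_med)^2 dx ]

over normalized depth x in [0, 1] (endo -> epi): the reciprocal of the
normalized quadratic error of the envelope curves about the median.  High
TCI means the tracts crossing each depth agree on their HA; values below
about 0.1 indicate noisy data or genuinely disorganized fibers.

The HA histogram and its variance ratio — var(negative HA) / var(positive
HA) of the tract median values — quantify the left/right symmetry of the
architecture; the ratio is ~1 for a normal symmetric wall and drops far
below 1 after a rightward (positive) HA shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helix_angle import CardiacFrame
from .tractography import TractSet


@dataclass
class TransmuralCurves:
    x: np.ndarray        # normalized depth samples, strictly increasing, [0, 1]
    ha_min: np.ndarray   # degrees
    ha_med: np.ndarray
    ha_max: np.ndarray
    counts: np.ndarray   # tract deposits contributing per sample


@dataclass
class TCIResult:
    tci: float           # may be inf (perfectly coherent: zero envelope error)
    numerator: float
    denominator: float
    length_mode: str = ""
    coherent_flag: bool = False  # True when the +inf sentinel was produced


@dataclass
class HAHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    statistic: str
    variance_ratio: float        # NaN when undefined
    ratio_defined: bool
    n_negative: int
    n_positive: int


def transmural_curves(
    tracts: TractSet,
    roi: np.ndarray,
    frame: CardiacFrame,
    spacing,
) -> TransmuralCurves:
    """Two-step nested averaging of tract HA statistics over an ROI.

    Local axes are taken from the frame at the ROI centroid: transmural
    along the radial direction, base-apex along the long axis,
    anterior-posterior along the circumference.  ROI voxels are binned on
    this local grid at one-voxel resolution; a tract deposits its
    (min, med, max) into every ROI voxel it traverses (once per voxel).
    Tracts without a classification are ignored.
    """
    roi = np.asarray(roi, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    vox = np.argwhere(roi)
    if len(vox) == 0:
        raise ValueError("ROI is empty")
    centers = (vox + 0.5) * sp

    # transmural coordinate: radial distance; normalize over the ROI wall span
    rad = frame.radial_distance(centers)
    r_lo, r_hi = rad.min(), rad.max()
    if r_hi - r_lo < 1e-9:
        raise ValueError("ROI spans a single transmural depth; need >= 3")
    step = float(min(sp))
    t_ax = (centers - frame.origin) @ frame.long_axis
    # anterior-posterior: arc-length coordinate around the centerline
    offs = centers - frame.center_at(t_ax)
    # angular coordinate in the plane orthogonal to the long axis,
    # built from two fixed in-plane basis vectors
    l = frame.long_axis
    u = np.array([1.0, 0.0, 0.0])
    if abs(u @ l) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    u = u - (u @ l) * l
    u /= np.linalg.norm(u)
    v = np.cross(l, u)
    offp = offs - (offs @ l)[:, None] * l
    theta = np.arctan2(offp @ v, offp @ u)
    r_mid = 0.5 * (r_lo + r_hi)

    tb = np.round((rad - r_lo) / step).astype(int)           # transmural bin
    ab = np.round(theta * r_mid / step).astype(int)          # anterior-posterior bin
    bb = np.round(t_ax / step).astype(int)                   # base-apex bin
    nt = tb.max() + 1
    if nt < 2:
        raise ValueError("ROI spans fewer than 2 transmural depths")
    ab -= ab.min()
    bb -= bb.min()
    na, nb = ab.max() + 1, bb.max() + 1

    # lookup from voxel index -> (tb, ab, bb); -1 marks non-ROI voxels
    binmap = np.full(roi.shape + (3,), -1, dtype=np.int64)
    binmap[vox[:, 0], vox[:, 1], vox[:, 2], 0] = tb
    binmap[vox[:, 0], vox[:, 1], vox[:, 2], 1] = ab
    binmap[vox[:, 0], vox[:, 1], vox[:, 2], 2] = bb

    sums = np.zeros((3, nt, na, nb))
    cnts = np.zeros((nt, na, nb), dtype=np.int64)
    shape = np.asarray(roi.shape)
    for s in tracts:
        cls = s.classification
        if cls is None:
            continue
        iv = np.floor(s.points / sp).astype(np.int64)
        inb = np.all((iv >= 0) & (iv < shape), axis=1)
        iv = iv[inb]
        if len(iv) == 0:
            continue
        iv = np.unique(iv, axis=0)
        b = binmap[iv[:, 0], iv[:, 1], iv[:, 2]]
        b = b[b[:, 0] >= 0]
        if len(b) == 0:
            continue
        sums[0, b[:, 0], b[:, 1], b[:, 2]] += cls.ha_min
        sums[1, b[:, 0], b[:, 1], b[:, 2]] += cls.ha_median
        sums[2, b[:, 0], b[:, 1], b[:, 2]] += cls.ha_max
        cnts[b[:, 0], b[:, 1], b[:, 2]] += 1

    # step 1: average along base-apex per (transmural, anterior-posterior) column
    with np.errstate(invalid="ignore", divide="ignore"):
        col_sum = sums.sum(axis=3)
        col_cnt = cnts.sum(axis=2)
        col_mean = np.where(col_cnt > 0, col_sum / col_cnt, np.nan)
    # step 2: average the 2D maps along the anterior-posterior direction
    valid_cols = col_cnt > 0
    curves = np.full((3, nt), np.nan)
    counts = np.zeros(nt, dtype=np.int64)
    for it in range(nt):
        sel = valid_cols[it]
        counts[it] = cnts[it].sum()
        if sel.any():
            curves[:, it] = np.nanmean(col_mean[:, it, sel], axis=1)

    # x from the transmural layer index, normalized endo -> epi (layers are
    # one voxel apart by construction)
    x = np.arange(nt) / max(nt - 1, 1)
    keep = counts > 0
    return TransmuralCurves(
        x=x[keep],
        ha_min=curves[0, keep],
        ha_med=curves[1, keep],
        ha_max=curves[2, keep],
        counts=counts[keep],
    )


def tci(curves: TransmuralCurves, length_mode: str = "") -> TCIResult:
    """Tractographic coherence index from the three transmural curves.

    Trapezoidal integrals over the valid samples on normalized depth; a
    denominator below 1e-12 of the numerator yields the +inf sentinel
    (perfect coherence).  An all-zero median with zero denominator is a
    0/0 and raises.
    """
    x = np.asarray(curves.x, dtype=float)
    if len(x) < 3:
        raise ValueError("TCI requires at least 3 valid transmural samples")
    num = float(np.trapezoid(curves.ha_med**2, x))
    den = float(
        np.trapezoid((curves.ha_max - curves.ha_med) ** 2, x)
        + np.trapezoid((curves.ha_min - curves.ha_med) ** 2, x)
    )
    if den <= 1e-12 * max(num, 1e-300):
        if num <= 1e-300:
            raise ValueError("TCI undefined: zero median curve and zero envelope error (0/0)")
        return TCIResult(np.inf, num, den, length_mode, coherent_flag=True)
    return TCIResult(num / den, num, den, length_mode)


def ha_histogram(
    tracts: TractSet,
    statistic: str = "median",
    bin_width: float = 5.0,
) -> HAHistogram:
    """HA histogram over (-90, 90] and the negative/positive variance ratio.

    The ratio is sample variance (n-1) of the strictly negative tract HA
    values over that of the strictly positive values, computed from the raw
    values (binning affects display only); HA exactly 0 is excluded from
    both sides.  Fewer than 2 values on either side leaves the ratio
    undefined (NaN, flagged).
    """
    attr = {"min": "ha_min", "max": "ha_max", "median": "ha_median", "mean": "ha_mean"}[statistic]
    vals = np.array([getattr(s.classification, attr) for s in tracts if s.classification is not None])
    nbins = int(round(180.0 / bin_width))
    edges = np.linspace(-90.0, 90.0, nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    neg = vals[vals < 0]
    pos = vals[vals > 0]
    if len(neg) >= 2 and len(pos) >= 2:
        ratio = float(np.var(neg, ddof=1) / np.var(pos, ddof=1))
        defined = True
    else:
        ratio, defined = float("nan"), False
    return HAHistogram(edges, counts, statistic, ratio, defined, len(neg), len(pos))


def zero_crossing(curves: TransmuralCurves) -> tuple[float | None, list[float]]:
    """Depth(s) where the median HA curve crosses zero.

    Linear interpolation between the bracketing samples.  Returns
    (first crossing or None, all crossings); callers should treat multiple
    crossings as a flagged condition.  Samples exactly at zero count as
    crossings at their own depth.
    """
    x = np.asarray(curves.x, dtype=float)
    y = np.asarray(curves.ha_med, dtype=float)
    crossings: list[float] = []
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 == 0.0:
            crossings.append(float(x[i]))
        elif y0 * y1 < 0:
            crossings.append(float(x[i] - y0 * (x[i + 1] - x[i]) / (y1 - y0)))
    if len(y) and y[-1] == 0.0:
        crossings.append(float(x[-1]))
    return (crossings[0] if crossings else None), crossings
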