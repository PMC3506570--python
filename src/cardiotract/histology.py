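"""Fiber orientation from 2D microscopy sections via Hessian ridge analysis.

Sections cut tangentially to the epicardial surface show myofibers and
interstitial spaces as elongated intensity ridges.  The local Hessian of
the Gaussian-smoothed image is eigendecomposed per pixel; pixels whose
principal intensity curvature is strong and whose intensity is extremal
along the principal-curvature direction are ridge points.  The ridge mask
is eroded to single-pixel-wide chains, short chains are dropped, and each
remaining segment's orientation against the horizontal axis is taken from
the principal axis of its pixel chain.  Section-level orientation is the
length-weighted circular mean on the half-circle (fiber orientation is
axial: +89 deg and -89 deg are nearly the same fiber, so angles are
doubled, averaged as unit vectors, and halved).

Angle convention: degrees counterclockwise from the horizontal (column)
axis with the vertical axis pointing up (decreasing row index), range
(-90, 90].  The mapping of microscopy angles onto the MR helix-angle sign
convention is controlled by the same global sign constant used for
tractography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.measure import label
from skimage.morphology import skeletonize

from .helix_angle import GLOBAL_HA_SIGN


@dataclass
class SectionImage:
    """One grayscale microscopy section with its transmural position."""

    pixels: np.ndarray
    pixel_size: float = 1.0       # micrometers
    transmural_level: int | None = None   # 1 (endo) .. 6 (epi), or None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("section image must be 2D grayscale")
        if min(self.pixels.shape) < 64:
            raise ValueError("section image must be at least 64x64 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("section image contains non-finite intensities")


@dataclass
class RidgeSegments:
    """Single-pixel-wide ridge chains with per-segment orientation."""

    labels: np.ndarray            # labeled skeleton image (0 = background)
    angles: np.ndarray            # per-segment angle vs horizontal, degrees
    lengths: np.ndarray           # per-segment pixel count
    empty_flag: bool = False


def _segment_angle(rows: np.ndarray, cols: np.ndarray) -> float:
    """Principal-axis orientation of a pixel chain, degrees in (-90, 90]."""
    x = cols.astype(float)
    y = -rows.astype(float)       # vertical axis up
    x = x - x.mean()
    y = y - y.mean()
    cxx, cyy, cxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    # orientation of the largest eigenvector of [[cxx, cxy], [cxy, cyy]]
    ang = 0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def hessian_orientation(
    img: SectionImage | np.ndarray,
    scale_sigma: float = 2.0,
    curvature_threshold: float | None = None,
    min_segment_length: int = 10,
) -> RidgeSegments:
    """Extract single-pixel ridge segments and their orientations.

    ``curvature_threshold`` is an absolute bound on the principal Hessian
    eigenvalue; when None it defaults to half the root-mean-square
    principal curvature over the image (adaptive, scale-free).  Both bright
    ridges (fibers) and dark valleys (interstitial spaces) are kept — the
    orientation of either carries the same fiber-direction information.
    """
    if scale_sigma < 1:
        raise ValueError("scale_sigma must be >= 1 pixel")
    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img, dtype=float)
    if np.ptp(pixels) < 1e-12 * max(1.0, abs(float(pixels.flat[0]))):
        # structureless image: nothing to extract
        return RidgeSegments(np.zeros(pixels.shape, dtype=np.int32),
                             np.array([]), np.array([], dtype=int), empty_flag=True)

    H = hessian_matrix(pixels, sigma=scale_sigma, order="rc", use_gaussian_derivatives=True)
    ev = hessian_matrix_eigvals(H)                  # (2, r, c), descending
    princ = np.where(np.abs(ev[0]) >= np.abs(ev[1]), ev[0], ev[1])

    if curvature_threshold is None:
        rms = float(np.sqrt(np.mean(princ**2)))
        curvature_threshold = 0.5 * rms
    strong = np.abs(princ) > curvature_threshold

    # extremality along the principal-curvature direction: compare the
    # smoothed intensity with its two neighbors one pixel away along the
    # eigenvector of the principal curvature
    Hrr, Hrc, Hcc = H
    # eigenvector of the principal (largest |.|) eigenvalue
    vr = princ - Hcc
    vc = Hrc.copy()
    small = np.hypot(vr, vc) < 1e-12
    vr = np.where(small, 1.0, vr)
    vc = np.where(small, 0.0, vc)
    nrm = np.hypot(vr, vc)
    vr /= nrm
    vc /= nrm
    smooth = ndimage.gaussian_filter(pixels, scale_sigma)
    rr, cc = np.meshgrid(np.arange(pixels.shape[0]), np.arange(pixels.shape[1]), indexing="ij")
    plus = ndimage.map_coordinates(smooth, [rr + vr, cc + vc], order=1, mode="nearest")
    minus = ndimage.map_coordinates(smooth, [rr - vr, cc - vc], order=1, mode="nearest")
    bright = (princ < 0) & (smooth >= plus) & (smooth >= minus)
    dark = (princ > 0) & (smooth <= plus) & (smooth <= minus)
    ridge = strong & (bright | dark)

    thin = skeletonize(ridge)
    labels = label(thin, connectivity=2)
    if labels.max() == 0:
        return RidgeSegments(labels, np.array([]), np.array([], dtype=int), empty_flag=True)

    angles, lengths, keep_ids = [], [], []
    for rid in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == rid)
        if len(rows) < min_segment_length:
            labels[labels == rid] = 0
            continue
        angles.append(_segment_angle(rows, cols))
        lengths.append(len(rows))
        keep_ids.append(rid)
    if not keep_ids:
        return RidgeSegments(labels, np.array([]), np.array([], dtype=int), empty_flag=True)
    # relabel compactly
    relabel = np.zeros(labels.max() + 1, dtype=labels.dtype)
    for new, old in enumerate(keep_ids, start=1):
        relabel[old] = new
    return RidgeSegments(relabel[labels], np.asarray(angles), np.asarray(lengths, dtype=int))


def section_mean_ha(segs: RidgeSegments, length_weighted: bool = True) -> float:
    """Length-weighted circular mean orientation of the segments, degrees.

    Axial circular mean: angles are doubled, averaged as unit vectors,
    halved, and folded to (-90, 90].  The global HA sign constant maps the
    microscopy angle onto the MR helix-angle convention.
    """
    if segs.angles.size == 0:
        raise ValueError("no ridge segments: mean orientation undefined")
    w = segs.lengths.astype(float) if length_weighted else np.ones_like(segs.angles)
    a2 = np.radians(2.0 * segs.angles)
    mean2 = np.arctan2(np.sum(w * np.sin(a2)), np.sum(w * np.cos(a2)))
    ang = np.degrees(mean2) / 2.0
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang * GLOBAL_HA_SIGN)


def transmural_profile(
    sections: list[SectionImage],
    scale_sigma: float = 2.0,
    curvature_threshold: float | None = None,
    min_segment_length: int = 10,
    length_weighted: bool = True,
) -> pd.DataFrame:
    """Mean HA per transmural level across a stack of sections.

    Returns a DataFrame (level, mean_ha_deg, n_segments, total_length_px)
    sorted endo -> epi; levels whose sections yield no segments are
    recorded with NaN mean HA.
    """
    if len(sections) < 2:
        raise ValueError("at least 2 transmural levels are required")
    rows = []
    for sec in sections:
        segs = hessian_orientation(sec, scale_sigma, curvature_threshold, min_segment_length)
        if segs.angles.size == 0:
            rows.append((sec.transmural_level, np.nan, 0, 0))
        else:
            rows.append(
                (
                    sec.transmural_level,
                    section_mean_ha(segs, length_weighted),
                    len(segs.angles),
                    int(segs.lengths.sum()),
                )
            )
    df = pd.DataFrame(rows, columns=["level", "mean_ha_deg", "n_segments", "total_length_px"])
    return df.sort_values("level", kind="stable").reset_index(drop=True)
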