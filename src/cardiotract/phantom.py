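"""Synthetic left-ventricle phantoms with known fiber architecture.

The phantom is a thick-walled annular cylinder segment — a mid-ventricular
LV wall where the geometry is locally cylindrical — with a prescribed
transmural helix-angle profile: HA varies linearly with normalized wall
depth x (0 at the endocardium, 1 at the epicardium) from ``alpha_endo`` to
``alpha_epi``.  Fibers are circumferential vectors rotated by HA about the
radial axis, optionally perturbed by random rotations; tensors are built
from the fiber triad with prescribed eigenvalues, so eigendecomposition
recovers the fiber field exactly.

Presets encode the architectures studied: a normal symmetric +60/-60 deg
profile (human), +50/-50 (sheep), and a remote-zone variant whose
epicardial HA is shifted rightward to -37.5 deg, anchored to the
subepicardial histology of remodeled hearts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .helix_angle import CardiacFrame, helix_angle
from .tensor_field import DWISet, TensorVolume

#: classic six-direction diffusion-encoding scheme (unit vectors)
SIX_DIRECTIONS = np.array(
    [[1, 1, 0], [0, 1, 1], [1, 0, 1], [1, -1, 0], [0, 1, -1], [-1, 0, 1]],
    dtype=float,
) / np.sqrt(2.0)

#: named transmural HA profiles (degrees at endo / epi surface)
PRESETS: dict[str, dict[str, float]] = {
    "normal-human": {"alpha_endo": 60.0, "alpha_epi": -60.0},
    "normal-sheep": {"alpha_endo": 50.0, "alpha_epi": -50.0},
    "remote-zone": {"alpha_endo": 60.0, "alpha_epi": -37.5},
}


@dataclass
class PhantomSpec:
    """Geometry, architecture and noise of a synthetic LV segment.

    Defaults are sheep-scale: annulus of inner radius 24 mm / outer 34 mm
    (10 mm wall), 75 mm tall, voxelized at 1.25 mm so the transmural
    profile spans 8 voxel layers on a ~64^3 grid.
    ``orientation_noise_sd`` perturbs each voxel's fiber by a random
    rotation of Normal(0, sd) degrees about a uniformly random axis.
    """

    inner_radius: float = 24.0
    outer_radius: float = 34.0
    height: float = 75.0
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)
    alpha_endo: float = 60.0
    alpha_epi: float = -60.0
    profile: str = "linear"
    eigenvalues: tuple[float, float, float] = (1.0e-3, 0.7e-3, 0.5e-3)
    orientation_noise_sd: float = 0.0
    taper_frac: float = 0.0           # optional |HA| flattening toward axial ends
    subendo_noise_sd: float | None = None  # extra incoherence for depth < 0.15
    seed: int = 0
    margin_voxels: int = 2

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.inner_radius > 0):
            raise ValueError("require outer_radius > inner_radius > 0")
        if abs(self.alpha_endo) > 90 or abs(self.alpha_epi) > 90:
            raise ValueError("|alpha_endo| and |alpha_epi| must be <= 90 degrees")
        ev = self.eigenvalues
        if not (ev[0] >= ev[1] >= ev[2] > 0):
            raise ValueError("eigenvalues must be positive and non-increasing")
        if self.profile != "linear":
            raise ValueError(f"unknown transmural profile {self.profile!r}")


@dataclass
class PhantomOutput:
    """A generated phantom: tensors plus voxelwise ground truth."""

    tensors: TensorVolume
    truth_fibers: np.ndarray   # (X, Y, Z, 3) unit fiber direction (masked voxels)
    truth_ha: np.ndarray       # (X, Y, Z) HA of truth_fibers, degrees; NaN outside
    depth: np.ndarray          # (X, Y, Z) normalized transmural depth; NaN outside
    frame: CardiacFrame
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def mask(self) -> np.ndarray:
        return self.tensors.mask


def _random_rotations(vectors: np.ndarray, sd_deg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit vector by Normal(0, sd) degrees about a random axis."""
    n = len(vectors)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    ang = np.radians(rng.normal(0.0, 1.0, size=n) * sd_deg)
    # Rodrigues rotation, vectorized
    cosa = np.cos(ang)[:, None]
    sina = np.sin(ang)[:, None]
    dot = np.sum(axes * vectors, axis=1, keepdims=True)
    return (
        vectors * cosa
        + np.cross(axes, vectors) * sina
        + axes * dot * (1.0 - cosa)
    )


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Build the annular phantom: mask, fibers, HA truth, tensors, frame.

    Deterministic: identical spec (including seed) gives bitwise-identical
    arrays.  Raises if the wall is thinner than two voxels, in which case
    the transmural profile cannot be resolved.
    """
    sp = np.asarray(spec.spacing, dtype=float)
    wall = spec.outer_radius - spec.inner_radius
    if wall < 2.0 * max(sp[:2]):
        raise ValueError("wall thickness below two voxels: transmural profile unresolvable")

    m = spec.margin_voxels
    nxy = int(np.ceil(2.0 * spec.outer_radius / sp[0])) + 2 * m
    nz = int(np.ceil(spec.height / sp[2])) + 2 * m
    shape = (nxy, nxy, nz)

    center = np.array([nxy / 2.0 * sp[0], nxy / 2.0 * sp[1], (nz / 2.0) * sp[2]])
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    x = (ii + 0.5) * sp[0] - center[0]
    y = (jj + 0.5) * sp[1] - center[1]
    z = (kk + 0.5) * sp[2] - center[2]
    r = np.hypot(x, y)
    mask = (r >= spec.inner_radius) & (r <= spec.outer_radius) & (np.abs(z) <= spec.height / 2.0)

    depth = np.full(shape, np.nan)
    depth[mask] = (r[mask] - spec.inner_radius) / wall

    # analytic profile, optionally tapered toward the axial ends
    ha_profile = spec.alpha_endo + depth[mask] * (spec.alpha_epi - spec.alpha_endo)
    if spec.taper_frac > 0:
        axial = np.abs(z[mask]) / (spec.height / 2.0)
        ha_profile = ha_profile * (1.0 - spec.taper_frac * axial**2)

    # local triad: radial, circumferential (z x r), longitudinal (+z)
    rm = r[mask]
    rhat = np.stack([x[mask] / rm, y[mask] / rm, np.zeros_like(rm)], axis=1)
    chat = np.stack([-rhat[:, 1], rhat[:, 0], np.zeros_like(rm)], axis=1)
    lhat = np.zeros_like(rhat)
    lhat[:, 2] = 1.0

    a = np.radians(ha_profile)
    fibers = np.cos(a)[:, None] * chat + np.sin(a)[:, None] * lhat

    rng = np.random.default_rng(spec.seed)
    sd = np.full(len(fibers), float(spec.orientation_noise_sd))
    if spec.subendo_noise_sd is not None:
        sd = np.where(depth[mask] < 0.15, float(spec.subendo_noise_sd), sd)
    if np.any(sd > 0):
        fibers = _random_rotations(fibers, sd, rng)
        fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)

    # sheet/normal axes by Gram-Schmidt: n along radial, s in-wall
    nvec = rhat - np.sum(rhat * fibers, axis=1, keepdims=True) * fibers
    nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
    svec = np.cross(fibers, nvec)

    l1, l2, l3 = spec.eigenvalues
    D = (
        l1 * fibers[:, :, None] * fibers[:, None, :]
        + l2 * svec[:, :, None] * svec[:, None, :]
        + l3 * nvec[:, :, None] * nvec[:, None, :]
    )
    mats = np.zeros(shape + (3, 3))
    mats[mask] = D
    tv = TensorVolume.from_matrices(mats, tuple(sp), mask)

    truth_fibers = np.zeros(shape + (3,))
    truth_fibers[mask] = fibers

    axis = np.array([0.0, 0.0, 1.0])
    zs = np.arange(nz) * sp[2] + 0.5 * sp[2] - center[2]
    cents = np.tile(center[None, :], (nz, 1))
    cents[:, 2] = zs + center[2]
    frame = CardiacFrame(axis, center, zs, cents)

    truth_ha = np.full(shape, np.nan)
    c, l, _ = frame.triads(voxel_centers(mask, sp))
    truth_ha[mask] = helix_angle(fibers, c, l)

    return PhantomOutput(tv, truth_fibers, truth_ha, depth, frame, spec)


def voxel_centers(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    return (idx + 0.5) * np.asarray(spacing, dtype=float)


def sector_roi(ph: PhantomOutput, ang_center_deg: float = 0.0,
               ang_width_deg: float = 90.0, z_extent_mm: float = 24.0) -> np.ndarray:
    """Transmural ROI: an angular sector of the wall, axially centered.

    Emulates the lateral-wall region of interest at the mid-ventricular
    level: the ROI spans the full wall thickness, ``ang_width_deg`` of
    circumference around ``ang_center_deg`` (degrees from +x), and
    ``z_extent_mm`` axially about the phantom midplane.
    """
    mask = ph.mask
    sp = np.asarray(ph.tensors.spacing)
    shape = mask.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ctr = ph.frame.origin
    x = (ii + 0.5) * sp[0] - ctr[0]
    y = (jj + 0.5) * sp[1] - ctr[1]
    z = (kk + 0.5) * sp[2] - ctr[2]
    ang = np.degrees(np.arctan2(y, x))
    dang = (ang - ang_center_deg + 180.0) % 360.0 - 180.0
    return mask & (np.abs(dang) <= ang_width_deg / 2.0) & (np.abs(z) <= z_extent_mm / 2.0)


def simulate_dwi(
    ph: PhantomOutput,
    bval: float = 2000.0,
    bvecs: np.ndarray | None = None,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_b0: int = 1,
    rician: bool = True,
) -> DWISet:
    """Forward-simulate diffusion-weighted signals from phantom tensors.

    S_i = S0 exp(-b g_i^T D g_i) per masked voxel (S0 outside the mask).
    Noise is Rician by default (magnitude MR), Gaussian otherwise;
    reproducible from ``seed``.
    """
    if bval <= 0:
        raise ValueError("bval must be > 0")
    g = SIX_DIRECTIONS if bvecs is None else np.asarray(bvecs, dtype=float)
    if g.shape[0] < 6:
        raise ValueError("at least 6 diffusion directions are required")
    g = g / np.linalg.norm(g, axis=1, keepdims=True)

    mask = ph.mask
    mats = ph.tensors.as_matrices()[mask]             # (n, 3, 3)
    adc = np.einsum("vi,nij,vj->nv", g, mats, g)      # (n, ndir)
    sig = s0 * np.exp(-bval * adc)

    shape = mask.shape
    nvol = n_b0 + len(g)
    vols = np.full(shape + (nvol,), s0, dtype=float)
    dwvols = np.full(shape + (len(g),), s0, dtype=float)
    dwvols[mask] = sig
    vols[..., n_b0:] = dwvols

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rician:
            n1 = rng.normal(0.0, noise_sd, vols.shape)
            n2 = rng.normal(0.0, noise_sd, vols.shape)
            vols = np.hypot(vols + n1, n2)
        else:
            vols = vols + rng.normal(0.0, noise_sd, vols.shape)

    bvals = np.concatenate([np.zeros(n_b0), np.full(len(g), bval)])
    allvecs = np.vstack([np.tile([[1.0, 0.0, 0.0]], (n_b0, 1)), g])
    return DWISet(vols, bvals, allvecs, ph.tensors.spacing)


def generate_stripe_image(
    angle: float,
    period: float = 12.0,
    size: tuple[int, int] = (256, 256),
    contrast: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sinusoidal stripe image whose ridges make ``angle`` with horizontal.

    The angle convention matches the histology module: measured
    counterclockwise from the horizontal (column) axis with the vertical
    axis pointing up (i.e. toward decreasing row index).  Intensities lie
    in [0, 1] before noise.  ``angle=0`` gives rows constant along the
    horizontal; ``contrast=0`` gives a flat image.
    """
    if not (0 < period < min(size)):
        raise ValueError("period must lie in (0, min(size))")
    rows, cols = np.meshgrid(np.arange(size[0]), np.arange(size[1]), indexing="ij")
    th = np.radians(angle)
    # stripe direction u = (cos th, sin th) in (x=col, y=-row); phase along normal
    s = -cols * np.sin(th) - rows * np.cos(th)
    img = 0.5 + 0.5 * contrast * np.cos(2.0 * np.pi * s / period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable form of a PhantomSpec (for configs and provenance)."""
    d = asdict(spec)
    d["spacing"] = list(d["spacing"])
    d["eigenvalues"] = list(d["eigenvalues"])
    return d
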