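"""Diffusion tensor estimation and eigendecomposition.

A diffusion tensor volume stores, per voxel, the symmetric 3x3 tensor D
(mm^2/s) as six components in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).  The primary eigenvector e1 of D is taken
as the local myofiber direction; eigenvalues are sorted lam1 >= lam2 >= lam3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: index pairs of the six stored components within the full 3x3 tensor,
#: lower-triangular order: Dxx, Dxy, Dyy, Dxz, Dyz, Dzz
LOWER_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


class DegenerateDesignError(ValueError):
    """Raised when the diffusion gradient scheme cannot determine a tensor."""


@dataclass
class DWISet:
    """A diffusion-weighted acquisition: baseline plus encoded volumes.

    Parameters
    ----------
    volumes : (X, Y, Z, V) float array
        Signal intensities; at least one baseline (b = 0) volume.
    bvals : (V,) array
        b-value per volume, s/mm^2.
    bvecs : (V, 3) array
        Unit gradient direction per volume (arbitrary for b = 0 volumes).
    spacing : (3,) tuple
        Voxel size per axis, mm.
    """

    volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, volume)")
        if self.volumes.shape[3] != len(self.bvals) or self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvals/bvecs length must match the number of volumes")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 baseline volume is required")
        dw = self.bvals > 0
        if dw.sum() < 6:
            raise DegenerateDesignError("at least 6 diffusion-encoded volumes are required")
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-encoding bvecs must have unit norm (within 1e-6)")


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors over a masked grid.

    ``tensors`` has shape (X, Y, Z, 6) in lower-triangular component order
    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); ``flagged`` marks voxels whose fit was
    invalid (non-positive signal) or whose tensor is not positive definite.
    """

    tensors: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.ndim != 4 or self.tensors.shape[3] != 6:
            raise ValueError("tensors must have shape (x, y, z, 6)")
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape must match the tensor grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.flagged is None:
            self.flagged = np.zeros(self.mask.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand the six components to full (X, Y, Z, 3, 3) matrices."""
        m = np.empty(self.shape + (3, 3), dtype=float)
        for k, (i, j) in enumerate(LOWER_TRI):
            m[..., i, j] = self.tensors[..., k]
            m[..., j, i] = self.tensors[..., k]
        return m

    @classmethod
    def from_matrices(
        cls,
        matrices: np.ndarray,
        spacing: tuple[float, float, float],
        mask: np.ndarray,
        flagged: np.ndarray | None = None,
    ) -> "TensorVolume":
        comps = np.stack([matrices[..., i, j] for (i, j) in LOWER_TRI], axis=-1)
        return cls(comps, spacing, mask, flagged)


@dataclass
class EigenField:
    """Sorted eigensystem of a tensor volume.

    ``eigenvalues`` (X, Y, Z, 3) non-increasing; ``eigenvectors``
    (X, Y, Z, 3, 3) with ``eigenvectors[..., :, k]`` the unit eigenvector of
    ``eigenvalues[..., k]``.  Eigenvector sign is arbitrary (fibers are
    axial); downstream consumers must treat e and -e as equivalent.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    @property
    def primary(self) -> np.ndarray:
        """Primary eigenvector field e1, shape (X, Y, Z, 3)."""
        return self.eigenvectors[..., :, 0]


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map the six tensor components to -ln(S/S0) attenuation.

    For direction g and b-value b the model is
    ln(S/S0) = -b * g^T D g = -b * (gx^2 Dxx + 2 gx gy Dxy + gy^2 Dyy + ...).
    """
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)[:, None]
    cols = []
    for (i, j) in LOWER_TRI:
        w = 1.0 if i == j else 2.0
        cols.append(w * g[:, i] * g[:, j])
    return -b * np.stack(cols, axis=1)


def fit_tensor(dwi: DWISet, mask: np.ndarray) -> TensorVolume:
    """Fit diffusion tensors by unweighted log-linear least squares.

    Multiple b=0 volumes are averaged before the log transform.  Voxels with
    any non-positive signal are flagged invalid and not fit; voxels outside
    the mask are left as zero tensors.

    Raises
    ------
    DegenerateDesignError
        If the gradient scheme has rank < 6.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.volumes.shape[:3]:
        raise ValueError("mask shape does not match DWI volumes")

    dw = dwi.bvals > 0
    A = design_matrix(dwi.bvals[dw], dwi.bvecs[dw])
    if np.linalg.matrix_rank(A) < 6:
        raise DegenerateDesignError(
            "gradient scheme is rank-deficient: fewer than 6 independent directions"
        )

    s0 = dwi.volumes[..., ~dw].mean(axis=-1)
    s = dwi.volumes[..., dw]

    valid = mask & (s0 > 0) & np.all(s > 0, axis=-1)
    flagged = mask & ~valid
    n_flagged = int(flagged.sum())

    tensors = np.zeros(mask.shape + (6,), dtype=float)
    if valid.any():
        y = np.log(s[valid] / s0[valid][:, None])  # (n, ndir)
        pinv = np.linalg.pinv(A)
        tensors[valid] = (pinv @ y.T).T

    tv = TensorVolume(tensors, dwi.spacing, mask, flagged)
    if valid.any():
        # non-SPD fits are kept but flagged so that tracking can skip them
        evals = np.linalg.eigvalsh(tv.as_matrices()[valid])
        bad = np.zeros(mask.shape, dtype=bool)
        bad[valid] = evals[:, 0] <= 0
        tv.flagged |= bad
    tv.n_invalid_signal = n_flagged  # type: ignore[attr-defined]
    return tv


def eigendecompose(tv: TensorVolume) -> EigenField:
    """Eigendecompose a tensor volume into sorted orthonormal eigensystems.

    Eigenvalues are sorted non-increasing per voxel (lam1 >= lam2 >= lam3);
    ties are broken by the symmetric solver's deterministic output.

    Raises
    ------
    ValueError
        If a masked voxel contains non-finite tensor components (the error
        names the first offending voxel index).
    """
    bad = ~np.all(np.isfinite(tv.tensors), axis=-1) & tv.mask
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite tensor components at voxel {idx}")

    mats = tv.as_matrices()
    w, v = np.linalg.eigh(mats)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    return EigenField(w, v, tv.spacing, tv.mask)
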