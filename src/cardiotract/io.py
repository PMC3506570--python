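"""File formats: NIfTI tensor/mask volumes, FSL bvals/bvecs, VTK tracts.

Tensor volumes are 4D NIfTI with 6 components per voxel in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); files written here
carry a header comment extension naming that order, which the reader
checks when present.  Tract sets are written as VTK legacy ASCII polydata
(one polyline per streamline) with the per-point scalar ``HA_deg`` and
per-cell scalars ``HA_min``/``HA_med``/``HA_max``/``HA_mean`` and
``termination``, so they open directly in standard viewers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import nibabel as nib

from .helix_angle import HAClassification
from .tensor_field import DWISet, TensorVolume
from .tractography import Streamline, TractSet

TENSOR_ORDER_TAG = "cardiotract tensor order: Dxx Dxy Dyy Dxz Dyz Dzz"
_TERM_CODES = {"active": 0, "angle": 1, "mask_exit": 2, "length_cap": 3, "invalid_voxel": 4}


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _spacing_from(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    if any(s <= 0 for s in z):
        raise ValueError(f"{img.get_filename()}: non-positive voxel spacing {z}")
    return tuple(float(s) for s in z)


def write_tensor_nifti(tv: TensorVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(tv.tensors.astype(np.float64), _affine(tv.spacing))
    img.header.extensions.append(nib.nifti1.Nifti1Extension("comment", TENSOR_ORDER_TAG.encode()))
    nib.save(img, str(path))


def read_tensor_nifti(path: str | Path, mask: np.ndarray | None = None) -> TensorVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(f"{path}: tensor NIfTI must be 4D with 6 components, got {data.shape}")
    for ext in img.header.extensions:
        content = ext.get_content()
        text = content.decode() if isinstance(content, bytes) else str(content)
        if "tensor order" in text and text.strip() != TENSOR_ORDER_TAG:
            raise ValueError(f"{path}: unexpected tensor component order tag {text!r}")
    if mask is None:
        mask = np.any(data != 0, axis=-1)
    return TensorVolume(data, _spacing_from(img), mask)


def write_mask_nifti(mask: np.ndarray, spacing, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be a 3D volume, got shape {data.shape}")
    return data != 0, _spacing_from(img)


def read_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style text gradients: one row of b-values, three rows of bvecs.

    Non-unit diffusion bvecs are renormalized when within 1% of unit norm;
    larger deviations are an error naming the file.
    """
    bvals = np.loadtxt(str(bvals_path)).ravel()
    bvecs = np.loadtxt(str(bvecs_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(f"{bvecs_path}: expected 3x{len(bvals)} bvecs, got {bvecs.shape}")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 0.01):
        raise ValueError(f"{bvecs_path}: bvec norms deviate from unit by more than 1%")
    bvecs[dw] /= norms[:, None]
    return bvals, bvecs


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bvals_path, bvecs_path) -> None:
    np.savetxt(str(bvals_path), np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), np.asarray(bvecs).T, fmt="%.10g")


def read_dwi(nifti_path, bvals_path, bvecs_path) -> DWISet:
    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: DWI must be 4D, got shape {data.shape}")
    bvals, bvecs = read_bvals_bvecs(bvals_path, bvecs_path)
    if data.shape[3] != len(bvals):
        raise ValueError(
            f"{nifti_path}: {data.shape[3]} volumes but {len(bvals)} b-values"
        )
    return DWISet(data, bvals, bvecs, _spacing_from(img))


def write_dwi(dwi: DWISet, nifti_path, bvals_path, bvecs_path) -> None:
    nib.save(nib.Nifti1Image(dwi.volumes, _affine(dwi.spacing)), str(nifti_path))
    write_bvals_bvecs(dwi.bvals, dwi.bvecs, bvals_path, bvecs_path)


def write_tracts_vtk(tracts: TractSet, path: str | Path) -> None:
    """VTK legacy ASCII polydata: polylines + HA point/cell scalars."""
    lines = ["# vtk DataFile Version 3.0", "cardiotract fiber tracts", "ASCII", "DATASET POLYDATA"]
    npts = sum(len(s.points) for s in tracts)
    lines.append(f"POINTS {npts} float")
    for s in tracts:
        for p in s.points:
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    ncell = len(tracts.streamlines)
    lines.append(f"LINES {ncell} {ncell + npts}")
    off = 0
    for s in tracts:
        n = len(s.points)
        lines.append(" ".join([str(n)] + [str(off + i) for i in range(n)]))
        off += n

    lines.append(f"POINT_DATA {npts}")
    lines.append("SCALARS HA_deg float 1")
    lines.append("LOOKUP_TABLE default")
    for s in tracts:
        cls = s.classification
        n = len(s.points)
        if cls is not None and len(cls.discrete) == n:
            vals = cls.discrete
        elif cls is not None:
            # undefined-HA vertices were dropped from discrete; pad with NaN-free median
            vals = np.full(n, cls.ha_median)
        else:
            vals = np.zeros(n)
        lines.extend(f"{v:.4f}" for v in vals)

    lines.append(f"CELL_DATA {ncell}")
    for name, attr in [("HA_min", "ha_min"), ("HA_med", "ha_median"),
                       ("HA_max", "ha_max"), ("HA_mean", "ha_mean")]:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        for s in tracts:
            v = getattr(s.classification, attr) if s.classification is not None else 0.0
            lines.append(f"{v:.4f}")
    lines.append("SCALARS termination int 1")
    lines.append("LOOKUP_TABLE default")
    for s in tracts:
        lines.append(str(_TERM_CODES.get(s.termination_fwd, 0)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tracts_vtk(path: str | Path) -> TractSet:
    """Read back tracts written by :func:`write_tracts_vtk`."""
    lines_in = Path(path).read_text().splitlines()
    pts = None
    polylines = []
    scalars: dict[str, np.ndarray] = {}
    section_n = 0  # current attribute tuple count (POINT_DATA / CELL_DATA)
    i = 0
    while i < len(lines_in):
        line = lines_in[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            flat: list[float] = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(t) for t in lines_in[i].split())
                i += 1
            pts = np.array(flat).reshape(n, 3)
            continue
        if line.startswith("LINES"):
            ncell = int(line.split()[1])
            i += 1
            for _ in range(ncell):
                parts = [int(t) for t in lines_in[i].split()]
                polylines.append(parts[1 : 1 + parts[0]])
                i += 1
            continue
        if line.startswith(("POINT_DATA", "CELL_DATA")):
            section_n = int(line.split()[1])
            i += 1
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals: list[float] = []
            while len(vals) < section_n:
                vals.extend(float(t) for t in lines_in[i].split())
                i += 1
            scalars[name] = np.array(vals)
            continue
        i += 1

    if pts is None:
        raise ValueError(f"{path}: no POINTS section found")
    term_rev = {v: k for k, v in _TERM_CODES.items()}
    streams = []
    ha = scalars.get("HA_deg")
    for ci, ids in enumerate(polylines):
        cls = None
        if "HA_med" in scalars:
            disc = ha[ids] if ha is not None else np.array([])
            cls = HAClassification(
                discrete=disc,
                ha_min=float(scalars["HA_min"][ci]),
                ha_max=float(scalars["HA_max"][ci]),
                ha_median=float(scalars["HA_med"][ci]),
                ha_mean=float(scalars["HA_mean"][ci]),
            )
        term = term_rev.get(int(scalars["termination"][ci]), "active") if "termination" in scalars else "active"
        streams.append(Streamline(pts[ids], term, term, seed_index=ci, classification=cls))
    return TractSet(streams)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_metrics(metrics: dict, path: str | Path, config: dict | None = None, seed: int | None = None) -> None:
    """Metrics JSON with a provenance block (config hash, seed, version)."""
    from . import __version__

    out = dict(metrics)
    out["provenance"] = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
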