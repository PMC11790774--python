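"""Reading and writing the standard formats the pipeline touches.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinates are obtained through the NIfTI
  affine and are RAS+ millimetres;
* diffusion gradient directions are stored FSL-style, i.e. expressed in the
  image-axis frame, with ``bvecs`` as three rows of space-separated components;
* endo/epicardial contours live in a CSV with columns
  ``slice,surface,x_mm,y_mm`` (surface is ``endo`` or ``epi``), vertices
  ordered along each closed polygon, coordinates in world millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from shapely.geometry import Polygon


class FormatError(ValueError):
    """Mutually inconsistent or malformed input files."""


class TopologyError(ValueError):
    """Contours that violate the endo-inside-epi annulus topology."""


B0_THRESHOLD = 10.0  # s/mm²; measurements below this count as unweighted


@dataclass
class GradientTable:
    """Per-measurement b-values (s/mm²) and unit gradient directions.

    A zero direction vector is allowed (and conventional) on b=0 rows.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (len(self.bvals), 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} inconsistent with {len(self.bvals)} b-values"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = norms > 0
        off = nonzero & (np.abs(norms - 1.0) > 1e-6)
        if np.any(off):
            warnings.warn(
                f"{int(off.sum())} non-unit gradient direction(s) renormalized",
                stacklevel=2,
            )
        self.bvecs = self.bvecs.copy()
        self.bvecs[nonzero] /= norms[nonzero, None]

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals < B0_THRESHOLD)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals >= B0_THRESHOLD)

    def design_matrix(self) -> np.ndarray:
        """Log-linear tensor design matrix, one row per measurement.

        Columns multiply ``[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`` so that
        ``X @ theta = ln S`` under the Stejskal–Tanner model
        ``ln S = ln S0 − b gᵀ D g``.
        """
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -b * gy * gy,
                -b * gz * gz,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )


@dataclass
class DWIStack:
    """4-D diffusion-weighted signal volume with spatial metadata.

    ``data`` is ordered (x, y, z, measurement); the affine maps 0-based voxel
    indices to RAS+ world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray
    b0_indices: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DWI stack must be 4-D, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise FormatError("voxel size must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape


def save_dwi(dwi: DWIStack, gtab: GradientTable, path_nifti, path_bvals, path_bvecs) -> None:
    """Write a stack as NIfTI-1 plus FSL-style bvals/bvecs text files."""
    if dwi.n_volumes != len(gtab):
        raise FormatError(
            f"{dwi.n_volumes} volumes but {len(gtab)} gradient-table rows"
        )
    img = nib.Nifti1Image(dwi.data, dwi.affine)
    img.header.set_zooms(tuple(dwi.voxel_size) + (1.0,))
    nib.save(img, str(path_nifti))
    np.savetxt(path_bvals, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(path_bvecs, gtab.bvecs.T, fmt="%.17g")


def save_volume(vol: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D map (float) or label/mask volume (integer) as NIfTI-1."""
    arr = np.asarray(vol)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def load_dwi(path_nifti, path_bvals, path_bvecs) -> tuple[DWIStack, GradientTable]:
    """Load and cross-validate a DWI volume with its gradient table.

    Raises :class:`FormatError` when the number of volumes disagrees with the
    gradient-table rows rather than silently truncating.  Slightly non-unit
    direction vectors are renormalized with a warning.
    """
    for p in (path_nifti, path_bvals, path_bvecs):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(path_bvals).ravel()
    bvecs = np.loadtxt(path_bvecs)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square case: FSL files are 3 rows x n columns
        bvecs = bvecs.T
    if data.shape[3] != len(bvals) or len(bvals) != len(bvecs):
        raise FormatError(
            f"volume count {data.shape[3]}, bvals {len(bvals)}, bvecs {len(bvecs)} disagree"
        )
    gtab = GradientTable(bvals=bvals, bvecs=bvecs)
    stack = DWIStack(data=data, affine=np.asarray(img.affine), b0_indices=gtab.b0_indices)
    return stack, gtab


# ---------------------------------------------------------------------------
# contours


def _validate_contour_pair(endo: np.ndarray, epi: np.ndarray, slice_idx) -> None:
    p_endo = Polygon(endo)
    p_epi = Polygon(epi)
    if not p_endo.is_valid or not p_epi.is_valid:
        raise TopologyError(f"self-intersecting contour on slice {slice_idx}")
    if not p_epi.contains(p_endo):
        raise TopologyError(
            f"endocardial contour not strictly inside epicardial contour on slice {slice_idx}"
        )


def load_contours(path) -> dict[int, dict[str, np.ndarray]]:
    """Load per-slice endo/epi closed polygons from a contour CSV.

    Returns a mapping ``slice index -> {"endo": (n,2), "epi": (m,2)}`` with
    vertices in world mm.  Every slice must carry both surfaces, each polygon
    must be simple (non-self-intersecting), and endo must lie strictly inside
    epi; violations raise :class:`TopologyError`.
    """
    df = pd.read_csv(path)
    required = {"slice", "surface", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise FormatError(f"contour CSV must have columns {sorted(required)}")
    out: dict[int, dict[str, np.ndarray]] = {}
    for sl, group in df.groupby("slice"):
        surfaces = {}
        for tag, sub in group.groupby("surface"):
            if tag not in ("endo", "epi"):
                raise FormatError(f"unknown surface tag {tag!r}")
            surfaces[tag] = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        if set(surfaces) != {"endo", "epi"}:
            raise FormatError(f"slice {sl} missing an endo or epi contour")
        _validate_contour_pair(surfaces["endo"], surfaces["epi"], sl)
        out[int(sl)] = surfaces
    return out


def save_contours(contours: dict[int, dict[str, np.ndarray]], path) -> None:
    rows = []
    for sl in sorted(contours):
        for tag in ("endo", "epi"):
            for x, y in contours[sl][tag]:
                rows.append({"slice": sl, "surface": tag, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)
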