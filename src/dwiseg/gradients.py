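"""Gradient tables, DWI series and b0 normalization.

Diffusion-weighted MRI data come as a 4D volume (one 3D image per
measurement) plus a gradient table: per-measurement b-values (s/mm²) and
unit gradient directions.  Gradient tables are read and written in the FSL
dialect (``.bval``: one whitespace-separated row of m values; ``.bvec``:
three rows of m values, one per spatial component).

All diffusion-weighted intensities are normalized by the non-weighted
(b=0) signal before any further processing; when several b=0 volumes are
present their voxel-wise mean is used as the divisor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWISeries",
    "read_gradient_table",
    "write_gradient_table",
    "identify_b0s",
    "b0_normalize",
    "load_dwi",
    "save_dwi",
]

#: b-values at or below this (s/mm²) count as non-diffusion-weighted.
DEFAULT_B0_THRESHOLD = 50.0

#: Unit-norm tolerance for diffusion-weighted direction vectors.
UNIT_NORM_TOL = 1e-3


class GradientTableError(ValueError):
    """Malformed or inconsistent bval/bvec input."""


@dataclass(frozen=True)
class GradientTable:
    """Per-measurement b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (m,) array
        Diffusion weightings in s/mm², all non-negative.
    bvecs : (m, 3) array
        Gradient directions.  Rows for diffusion-weighted measurements
        must be unit vectors (within ``UNIT_NORM_TOL``); b=0 rows may be
        zero.  Directions are treated as antipodally symmetric throughout
        (the diffusion signal cannot distinguish q from −q).
    b0_threshold : float
        b-value cutoff separating b=0 from weighted measurements.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (m, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise GradientTableError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if bvals.shape[0] < 1:
            raise GradientTableError("empty gradient table")
        if not np.all(np.isfinite(bvals)) or not np.all(np.isfinite(bvecs)):
            raise GradientTableError("non-finite values in gradient table")
        if np.any(bvals < 0):
            raise GradientTableError("negative b-value")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > self.b0_threshold
        bad = weighted & (np.abs(norms - 1.0) > UNIT_NORM_TOL)
        if np.any(bad):
            raise GradientTableError(
                f"non-unit direction(s) at indices {np.flatnonzero(bad).tolist()}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def m(self) -> int:
        """Number of measurements."""
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def dwi_indices(self) -> np.ndarray:
        """Indices of diffusion-weighted (non-b0) measurements."""
        return np.flatnonzero(~self.b0_mask)

    def subset(self, indices: Sequence[int]) -> "GradientTable":
        idx = np.asarray(indices, dtype=int)
        return GradientTable(self.bvals[idx], self.bvecs[idx], self.b0_threshold)


@dataclass
class DWISeries:
    """A 4D diffusion-weighted image with its gradient table and geometry.

    ``data`` has shape (x, y, z, m) with m matching the gradient table;
    ``affine`` maps voxel indices to world mm, and ``voxel_size`` is the
    per-axis spacing in mm.
    """

    data: np.ndarray
    gtab: GradientTable
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.gtab.m:
            raise ValueError(
                f"data has {self.data.shape[3]} volumes but gradient table has "
                f"{self.gtab.m} entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities in DWI data")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {vs}")
        self.voxel_size = vs
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _parse_rows(source, n_rows_expected: int | None = None) -> np.ndarray:
    """Parse whitespace-separated numeric rows from a path, string or array."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        return np.atleast_2d(np.asarray(source, dtype=float))
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GradientTableError(f"non-numeric token in {line!r}") from exc
    if not rows:
        raise GradientTableError("empty gradient table source")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GradientTableError(f"ragged rows with lengths {sorted(lengths)}")
    arr = np.asarray(rows, dtype=float)
    if n_rows_expected is not None and arr.shape[0] != n_rows_expected:
        raise GradientTableError(
            f"expected {n_rows_expected} row(s), got {arr.shape[0]}"
        )
    return arr


def read_gradient_table(
    bval_source, bvec_source, b0_threshold: float = DEFAULT_B0_THRESHOLD
) -> GradientTable:
    """Read an FSL-style bval/bvec pair.

    Sources may be file paths, raw text, or array-likes.  Directions whose
    norm exceeds the b0-vector tolerance are re-normalized to unit length;
    rows with (near-)zero norm are kept as zero vectors (legal only for
    b=0 entries).
    """
    bvals = _parse_rows(bval_source, n_rows_expected=1).ravel()
    bvecs = _parse_rows(bvec_source)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # FSL layout is three rows of m values; m == 3 is ambiguous, keep
        # the FSL reading (rows are components).
        bvecs = bvecs.T
    if bvecs.shape[1] != 3:
        raise GradientTableError(f"bvecs must have 3 components, got {bvecs.shape}")
    if bvals.shape[0] != bvecs.shape[0]:
        raise GradientTableError(
            f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    renorm = norms > UNIT_NORM_TOL
    bvecs = bvecs.copy()
    bvecs[renorm] /= norms[renorm, None]
    return GradientTable(bvals, bvecs, b0_threshold)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    """Write a gradient table as FSL bval/bvec text files."""
    Path(bval_path).write_text(
        " ".join(f"{b:.6g}" for b in gtab.bvals) + "\n"
    )
    lines = [
        " ".join(f"{v:.9g}" for v in gtab.bvecs[:, axis]) for axis in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def identify_b0s(
    gtab: GradientTable, b0_threshold: float = DEFAULT_B0_THRESHOLD
) -> np.ndarray:
    """Indices of non-diffusion-weighted measurements (bval ≤ threshold)."""
    return np.flatnonzero(gtab.bvals <= b0_threshold)


def b0_normalize(
    dwi: DWISeries,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
    epsilon: float = 1e-6,
    clip_max: float = 2.0,
) -> DWISeries:
    """Divide diffusion-weighted volumes by the mean b=0 volume.

    Returns a series containing only the weighted measurements.  The
    divisor is floored at ``epsilon`` and the quotient clipped to
    ``[0, clip_max]``: physical attenuation cannot exceed 1, so larger
    values are noise and are bounded to keep the downstream SH fit stable.
    """
    b0_idx = identify_b0s(dwi.gtab, b0_threshold)
    if b0_idx.size == 0:
        raise ValueError("no b=0 measurement to normalize by")
    dw_idx = np.setdiff1d(np.arange(dwi.gtab.m), b0_idx)
    b0_mean = dwi.data[..., b0_idx].mean(axis=-1)
    divisor = np.maximum(b0_mean, epsilon)[..., None]
    normalized = np.clip(dwi.data[..., dw_idx] / divisor, 0.0, clip_max)
    gtab = GradientTable(
        dwi.gtab.bvals[dw_idx], dwi.gtab.bvecs[dw_idx], b0_threshold
    )
    return DWISeries(normalized, gtab, dwi.voxel_size, dwi.affine)


def load_dwi(image_path, bval_path, bvec_path, **kwargs) -> DWISeries:
    """Load a NIfTI DWI volume with its FSL gradient table."""
    img = nib.load(str(image_path))
    gtab = read_gradient_table(bval_path, bvec_path, **kwargs)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(data, gtab, voxel_size, np.asarray(img.affine))


def save_dwi(dwi: DWISeries, image_path, bval_path=None, bvec_path=None) -> None:
    """Write a DWI series as NIfTI (+ optional bval/bvec text files)."""
    img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), dwi.affine)
    img.header.set_zooms(dwi.voxel_size + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None and bvec_path is not None:
        write_gradient_table(dwi.gtab, bval_path, bvec_path)
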