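"""Even real spherical-harmonics representation of the diffusion signal.

The b0-normalized diffusion signal is antipodally symmetric, so only the
even-degree real spherical harmonics are needed.  At order 2 the basis has
(2+1)(2+2)/2 = 6 functions, which gives a fixed 6-channel representation
of a scan regardless of how many gradient directions were measured — this
is what makes models trained on one gradient table applicable to another.

Basis convention (``basis_name = "real_symmetric"``): for even degree l
and order −l ≤ m ≤ l,

    Y_{l,m} = sqrt(2) (−1)^m Im(Y_l^{|m|})   m < 0
    Y_{l,0} = Y_l^0                           m = 0
    Y_{l,m} = sqrt(2) (−1)^m Re(Y_l^m)        m > 0

with Y_l^m the orthonormal complex harmonics, coefficients ordered by
ascending l then ascending m (l=0; l=2, m=−2..2; ...).  The basis is real,
orthonormal on the sphere, and even in the direction vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "SHCoefficientVolume",
    "n_coefficients",
    "sh_design_matrix",
    "fit_sh",
    "project_volume",
]

BASIS_NAME = "real_symmetric"


def n_coefficients(order: int) -> int:
    """Number of even real SH basis functions up to ``order``."""
    _check_order(order)
    return (order + 1) * (order + 2) // 2


def _check_order(order: int) -> None:
    if order < 0 or order % 2 != 0:
        raise ValueError(f"SH order must be even and non-negative, got {order}")


def _degrees_orders(order: int) -> tuple[np.ndarray, np.ndarray]:
    ls, ms = [], []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


@dataclass
class SHCoefficientVolume:
    """4D volume of real SH coefficient maps (x, y, z, n_coef)."""

    coeffs: np.ndarray
    order: int
    basis_name: str = BASIS_NAME
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs)
        if self.coeffs.ndim != 4:
            raise ValueError("coefficient volume must be 4D")
        expected = n_coefficients(self.order)
        if self.coeffs.shape[3] != expected:
            raise ValueError(
                f"order {self.order} requires {expected} channels, "
                f"got {self.coeffs.shape[3]}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite SH coefficients")

    @property
    def n_coef(self) -> int:
        return self.coeffs.shape[3]

    def save(self, image_path) -> None:
        """Write as NIfTI with a JSON sidecar recording the fit settings."""
        img = nib.Nifti1Image(np.asarray(self.coeffs, dtype=np.float32), self.affine)
        img.header.set_zooms(self.voxel_size + (1.0,))
        nib.save(img, str(image_path))
        sidecar = {
            "order": self.order,
            "basis_name": self.basis_name,
            **{k: v for k, v in self.meta.items()},
        }
        path = Path(str(image_path))
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def sh_design_matrix(directions: np.ndarray, order: int) -> np.ndarray:
    """Evaluate the even real SH basis at each direction.

    Returns the (m, n_coef) matrix whose row i holds the basis functions
    at direction i.  Rows are even in the direction: the row for −v equals
    the row for v.
    """
    _check_order(order)
    vecs = np.atleast_2d(np.asarray(directions, dtype=float))
    if vecs.shape[1] != 3:
        raise ValueError(f"directions must be (m, 3), got {vecs.shape}")
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm direction")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        vecs = vecs / norms[:, None]
    theta = np.arccos(np.clip(vecs[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(vecs[:, 1], vecs[:, 0])  # azimuth
    ls, ms = _degrees_orders(order)
    B = np.empty((vecs.shape[0], ls.size))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
        elif m == 0:
            B[:, j] = y.real
        else:
            B[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
    return B


def _laplace_beltrami_diag(order: int) -> np.ndarray:
    ls, _ = _degrees_orders(order)
    return (ls * (ls + 1.0)) ** 2


def fit_sh(
    signals: np.ndarray,
    directions: np.ndarray,
    order: int = 2,
    reg_lambda: float = 0.0,
) -> np.ndarray:
    """Least-squares SH fit of signals measured on the given directions.

    Solves min_c ‖B c − s‖² + reg_lambda ‖L c‖² per voxel, with B the
    design matrix and L the diagonal Laplace–Beltrami weights l²(l+1)².
    ``signals`` may be a single (m,) vector or any (..., m) stack; the
    output replaces the last axis with n_coef coefficients.
    """
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be non-negative")
    B = sh_design_matrix(directions, order)
    m, n = B.shape
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != m:
        raise ValueError(
            f"{s.shape[-1]} signals per voxel but {m} directions"
        )
    if m < n and reg_lambda == 0.0:
        raise ValueError(
            f"under-determined fit: {m} directions for {n} coefficients "
            "(set reg_lambda > 0 to regularize)"
        )
    lhs = B.T @ B + reg_lambda * np.diag(_laplace_beltrami_diag(order))
    flat = s.reshape(-1, m)
    coeffs = np.linalg.solve(lhs, B.T @ flat.T).T
    return coeffs.reshape(s.shape[:-1] + (n,))


def project_volume(
    dwi,
    subset=None,
    order: int = 2,
    reg_lambda: float = 0.0,
) -> SHCoefficientVolume:
    """Project a b0-normalized DWI series onto the SH basis voxel-wise.

    ``subset`` restricts the fit to the given measurement indices (e.g. a
    q-space augmentation subset); the output always has n_coef channels
    regardless of subset size.
    """
    if subset is None:
        idx = np.arange(dwi.gtab.m)
    else:
        idx = np.asarray(getattr(subset, "indices", subset), dtype=int)
        if idx.size == 0 or np.any(idx < 0) or np.any(idx >= dwi.gtab.m):
            raise ValueError("subset indices out of range")
        if np.any(dwi.gtab.b0_mask[idx]):
            raise ValueError("subset contains b=0 measurements")
    coeffs = fit_sh(
        dwi.data[..., idx].astype(float),
        dwi.gtab.bvecs[idx],
        order=order,
        reg_lambda=reg_lambda,
    )
    return SHCoefficientVolume(
        coeffs,
        order=order,
        voxel_size=dwi.voxel_size,
        affine=dwi.affine,
        meta={"subset_indices": [int(i) for i in idx], "reg_lambda": reg_lambda},
    )
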