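"""Ensemble-disagreement uncertainty via unfolded Wasserstein distance.

The n subset predictions of an ensemble agree when the scan carries
enough information for a stable segmentation; when they disagree the
segmentation is suspect.  Disagreement is measured with the earth
mover's distance (EMD) between each member's probability map and the
ensemble mean, treating each (downsampled, unit-sum-normalized) map as
a mass distribution.  Exact EMD in 3D is impractical, so the maps are
unfolded into one dimension along a serpentine (boustrophedon) grid
traversal — consecutive elements of the unfolded sequence are always
grid-adjacent — and the 1D distance between the cumulative sums is
used: EMD(p, q) = Σ_t |P(t) − Q(t)|, which is the exact 1D Wasserstein
distance along the unfolded path.  The statistic

    u = (1/n) Σ_k EMD(y_k, ȳ)

is computed per tract; u above a threshold (default 0.30) flags the
tract's segmentation as likely inaccurate.  Distances are in units of
one unfolded step on the downsampled grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "UncertaintyReport",
    "downsample",
    "unit_sum_normalize",
    "unfold",
    "unfold_coordinates",
    "emd_unfolded",
    "uncertainty_report",
    "compute_u",
    "flag_inaccurate",
]

DEFAULT_THRESHOLD = 0.30
DEFAULT_DOWNSAMPLE = 4
UNFOLD_ORDER = "serpentine-zyx"


class EmptyMassError(ValueError):
    """A segmentation map with no mass cannot be normalized."""


@dataclass
class UncertaintyReport:
    """Per-tract disagreement statistics for one ensemble prediction."""

    per_tract_emd: dict  # label -> list of n EMD(y_k, ȳ) values (NaN if undefined)
    u: dict  # label -> mean EMD (NaN when undefined)
    flag: dict  # label -> bool, True = likely inaccurate
    threshold: float = DEFAULT_THRESHOLD
    downsample_factor: int = DEFAULT_DOWNSAMPLE
    unfold_order: str = UNFOLD_ORDER

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": lab,
                "u": self.u[lab],
                "flag": bool(self.flag[lab]),
                "n": len(self.per_tract_emd[lab]),
                "threshold": self.threshold,
                "downsample_factor": self.downsample_factor,
                "unfold_order": self.unfold_order,
            }
            for lab in sorted(self.u)
        ]
        return pd.DataFrame(rows)

    def save(self, json_path, csv_path=None) -> None:
        payload = {
            "threshold": self.threshold,
            "downsample_factor": self.downsample_factor,
            "unfold_order": self.unfold_order,
            "per_tract": {
                str(lab): {
                    "emd": [None if np.isnan(v) else float(v)
                            for v in self.per_tract_emd[lab]],
                    "u": None if np.isnan(self.u[lab]) else float(self.u[lab]),
                    "flag": bool(self.flag[lab]),
                }
                for lab in sorted(self.u)
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def downsample(vol: np.ndarray, factor: int = DEFAULT_DOWNSAMPLE) -> np.ndarray:
    """Shrink each axis by ``factor`` (ceil) via cubic interpolation.

    Cubic interpolation can overshoot, so values are clipped back to
    [0, 1] to keep the result a valid probability map.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("downsample factor must be a positive integer")
    vol = np.asarray(vol, dtype=np.float64)
    if vol.size == 0:
        raise ValueError("empty volume")
    if factor == 1:
        return vol.copy()
    factor = int(factor)
    # odd-reflection padding extends the volume linearly across its
    # edges, so the cubic spline stays exact for (locally) linear data
    # right up to the boundary; the padded coarse voxels are cropped off
    pad_mode = {"mode": "reflect", "reflect_type": "odd"} \
        if min(vol.shape) >= 2 else {"mode": "edge"}
    padded = np.pad(vol, factor, **pad_mode)
    out_shape = tuple(int(np.ceil(s / factor)) + 2 for s in vol.shape)
    zoom = [o / s for o, s in zip(out_shape, padded.shape)]
    out = ndimage.zoom(padded, zoom, order=3, mode="nearest", grid_mode=True)
    out = out[tuple(slice(1, -1) for _ in vol.shape)]
    return np.clip(out, 0.0, 1.0)


def unit_sum_normalize(vol: np.ndarray) -> np.ndarray:
    """Scale a non-negative volume to total mass 1."""
    vol = np.asarray(vol, dtype=np.float64)
    if np.any(vol < 0):
        raise ValueError("negative values cannot be normalized to a mass")
    total = vol.sum()
    if total <= 0:
        raise EmptyMassError("volume has zero total mass")
    return vol / total


def unfold(vol: np.ndarray) -> np.ndarray:
    """Serpentine traversal of a grid into a 1D sequence.

    Slices are visited in ascending z; within slice z rows in ascending
    y when z is even, descending otherwise; within each row x ascends
    when (y+z) is even, else descends.  Every pair of consecutive output
    elements therefore comes from grid-adjacent voxels, which is what
    makes one step of the unfolded sequence a meaningful transport unit.
    1D input is returned in its own order.
    """
    vol = np.asarray(vol)
    if vol.size == 0:
        raise ValueError("empty volume")
    if vol.ndim == 1:
        return vol.copy()
    if vol.ndim == 2:
        vol = vol[..., None]
    if vol.ndim != 3:
        raise ValueError("unfold expects a 1D–3D array")
    nx, ny, nz = vol.shape
    out = np.empty(vol.size, dtype=vol.dtype)
    pos = 0
    for z in range(nz):
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for y in ys:
            row = vol[:, y, z]
            if (y + z) % 2 == 1:
                row = row[::-1]
            out[pos:pos + nx] = row
            pos += nx
    return out


def unfold_coordinates(shape) -> np.ndarray:
    """Grid coordinates (x, y, z) visited by :func:`unfold`, in order."""
    shape3 = tuple(shape) + (1,) * (3 - len(tuple(shape)))
    return np.stack([unfold(g) for g in np.indices(shape3)], axis=1)


def emd_unfolded(p: np.ndarray, q: np.ndarray, mode: str = "abs") -> float:
    """EMD between two unit-mass volumes along the serpentine unfolding.

    With ``mode="abs"`` (default) returns Σ_t |P(t) − Q(t)| with P, Q
    the cumulative sums of the unfolded inputs — the exact 1D
    Wasserstein distance with unit ground metric along the unfolded
    path.  ``mode="l2"`` returns the root-sum-of-squares of the same
    differences, an alternative reading of the pairing distance.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {q.shape}")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("inputs must be unit-sum mass distributions")
    diff = np.cumsum(unfold(p)) - np.cumsum(unfold(q))
    if mode == "abs":
        return float(np.abs(diff).sum())
    if mode == "l2":
        return float(np.sqrt((diff**2).sum()))
    raise ValueError(f"unknown mode {mode!r}")


def compute_u(
    pred,
    label: int,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    mode: str = "abs",
) -> tuple[list[float], float]:
    """Per-member EMD(y_k, ȳ) and their mean u for one label channel.

    ``pred`` is an EnsemblePrediction; ``label`` indexes its channel
    axis.  Members (or a mean) with zero mass yield NaN entries; u is
    the mean over the defined EMDs, NaN if none are defined.
    """
    mean_map = downsample(pred.mean[..., label], downsample_factor)
    try:
        mean_mass = unit_sum_normalize(mean_map)
    except EmptyMassError:
        return [float("nan")] * pred.n, float("nan")
    emds = []
    for member in pred.members:
        member_map = downsample(member[..., label], downsample_factor)
        try:
            member_mass = unit_sum_normalize(member_map)
        except EmptyMassError:
            emds.append(float("nan"))
            continue
        emds.append(emd_unfolded(member_mass, mean_mass, mode=mode))
    defined = [e for e in emds if not np.isnan(e)]
    u = float(np.mean(defined)) if defined else float("nan")
    return emds, u


def flag_inaccurate(u: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True when disagreement exceeds the cutoff (or is undefined)."""
    if np.isnan(u):
        return True
    if u < 0:
        raise ValueError("u must be non-negative")
    return bool(u > threshold)


def uncertainty_report(
    pred,
    labels=None,
    threshold: float = DEFAULT_THRESHOLD,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    mode: str = "abs",
) -> UncertaintyReport:
    """Full per-tract report for an ensemble prediction."""
    n_labels = pred.mean.shape[-1]
    labels = range(n_labels) if labels is None else labels
    per_tract, u_map, flags = {}, {}, {}
    for lab in labels:
        emds, u = compute_u(pred, lab, downsample_factor, mode)
        per_tract[lab] = emds
        u_map[lab] = u
        flags[lab] = flag_inaccurate(u, threshold)
    return UncertaintyReport(
        per_tract_emd=per_tract, u=u_map, flag=flags,
        threshold=threshold, downsample_factor=downsample_factor,
    )
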