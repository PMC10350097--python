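"""Multi-tensor DWI phantoms with known tract labels.

The simulator emulates the kind of single-shell, DTI-style scan the
segmentation model is meant for: 20–90 gradient directions on one shell
at b ≈ 750–1200 s/mm² plus a few b=0 volumes.  Tracts are tubes around
smooth centerlines (they may cross); within a tube the signal follows a
cylindrically symmetric diffusion tensor whose principal axis is the
local centerline tangent, the background is isotropic, and voxels shared
by several tubes average the compartment signals with equal fractions.
Magnitude (Rician) noise is added at a configurable SNR relative to the
b=0 intensity.

This gives order-2 SH inputs realistic angular structure (mean signal +
a rank-2 anisotropy term) while keeping every quantity — occupancy,
tangents, diffusivities — available in closed form for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .gradients import DWISeries, GradientTable

__all__ = [
    "TractSpec",
    "PhantomSpec",
    "hemisphere_directions",
    "rasterize_tracts",
    "simulate_dwi",
    "random_crossing_spec",
]


@dataclass(frozen=True)
class TractSpec:
    """A tube: integer label ≥ 1, centerline control points (voxel
    coordinates, ≥ 2 points), and radius in mm."""

    label: int
    points: tuple
    radius: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("centerline needs at least 2 points of 3 coords")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.label < 1:
            raise ValueError("tract labels start at 1 (0 is background)")
        object.__setattr__(self, "points", tuple(map(tuple, pts)))


@dataclass
class PhantomSpec:
    """Full description of a synthetic scan; same seed → same phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tracts: list[TractSpec] = field(default_factory=list)
    b_value: float = 1000.0
    n_directions: int = 30
    n_b0: int = 3
    s0: float = 100.0
    diffusivities: tuple[float, float] = (1.7e-3, 0.3e-3)  # axial, radial mm²/s
    background_adc: float = 1.0e-3
    snr: float | None = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        ax, rad = self.diffusivities
        if not (ax >= rad > 0):
            raise ValueError("need axial diffusivity ≥ radial diffusivity > 0")
        labels = [t.label for t in self.tracts]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tract labels")
        if self.n_directions < 1 or self.n_b0 < 0:
            raise ValueError("need at least one gradient direction")

    @property
    def labels(self) -> list[int]:
        return [t.label for t in self.tracts]

    def to_yaml(self, path) -> None:
        d = {
            "grid_shape": [int(s) for s in self.grid_shape],
            "voxel_size": [float(v) for v in self.voxel_size],
            "tracts": [
                {"label": int(t.label),
                 "points": [[float(c) for c in p] for p in t.points],
                 "radius": float(t.radius)}
                for t in self.tracts
            ],
            "b_value": float(self.b_value),
            "n_directions": int(self.n_directions),
            "n_b0": int(self.n_b0),
            "s0": float(self.s0),
            "diffusivities": [float(v) for v in self.diffusivities],
            "background_adc": float(self.background_adc),
            "snr": None if self.snr is None else float(self.snr),
            "seed": int(self.seed),
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["tracts"] = [
            TractSpec(t["label"], tuple(map(tuple, t["points"])), t["radius"])
            for t in d["tracts"]
        ]
        for key in ("grid_shape", "voxel_size", "diffusivities"):
            d[key] = tuple(d[key])
        return cls(**d)


def hemisphere_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper half-sphere (Fibonacci
    spiral); adequate single-shell coverage for any n ≥ 6."""
    i = np.arange(n)
    z = (i + 0.5) / n  # strictly positive: stay on one hemisphere
    r = np.sqrt(1.0 - z * z)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


def _densify(points: np.ndarray, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Sample a polyline at ~step spacing; return samples and unit tangents."""
    pts = np.asarray(points, dtype=float)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.all(seglen < 1e-12):
        raise ValueError("degenerate centerline (zero length)")
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    total = t[-1]
    n_samp = max(int(np.ceil(total / step)) + 1, 2)
    u = np.linspace(0.0, total, n_samp)
    samples = np.c_[[np.interp(u, t, pts[:, k]) for k in range(3)]].T
    tang = np.gradient(samples, u, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    return samples, tang


def rasterize_tracts(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize the tubes.

    Returns ``occupancy`` of shape grid + (n_tracts,), boolean (a voxel
    may carry several labels where tubes cross), and ``tangents`` of
    shape grid + (n_tracts, 3): per tract, the unit tangent of the
    nearest centerline point (zero outside the tube).
    """
    shape = tuple(spec.grid_shape)
    vs = np.asarray(spec.voxel_size)
    grid = np.indices(shape).reshape(3, -1).T * vs  # voxel centers, mm
    occupancy = np.zeros(shape + (len(spec.tracts),), dtype=bool)
    tangents = np.zeros(shape + (len(spec.tracts), 3))
    for t_i, tract in enumerate(spec.tracts):
        samples, tang = _densify(np.asarray(tract.points) * vs)
        tree = cKDTree(samples)
        dist, nearest = tree.query(grid, workers=-1)
        inside = dist <= tract.radius
        occupancy[..., t_i] = inside.reshape(shape)
        tfield = np.zeros((grid.shape[0], 3))
        tfield[inside] = tang[nearest[inside]]
        tangents[..., t_i, :] = tfield.reshape(shape + (3,))
    return occupancy, tangents


def simulate_dwi(spec: PhantomSpec) -> tuple[DWISeries, np.ndarray]:
    """Simulate the scan; returns the DWI series and the label volume.

    The label volume has shape grid + (n_tracts,) with boolean occupancy
    per tract (overlap allowed at crossings).  Noiseless signal per voxel:
    s0 · mean over occupying compartments of exp(−b gᵀDg), with D the
    cylindrical tensor along the local tangent for tract compartments and
    the isotropic background ADC otherwise; b=0 volumes equal s0.  When
    ``snr`` is finite, Rician noise of σ = s0/snr is applied.
    """
    occupancy, tangents = rasterize_tracts(spec)
    dirs = hemisphere_directions(spec.n_directions)
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )
    bvecs = np.concatenate([np.zeros((spec.n_b0, 3)), dirs])
    gtab = GradientTable(bvals, bvecs)

    shape = tuple(spec.grid_shape)
    ax, rad = spec.diffusivities
    b = spec.b_value
    # background everywhere, then overwrite tract voxels with the
    # compartment average
    signal = np.full(
        shape + (spec.n_directions,),
        np.exp(-b * spec.background_adc),
        dtype=np.float64,
    )
    any_tract = occupancy.any(axis=-1)
    n_comp = occupancy.sum(axis=-1)
    acc = np.zeros(shape + (spec.n_directions,))
    for t_i in range(len(spec.tracts)):
        mask = occupancy[..., t_i]
        if not mask.any():
            continue
        tang = tangents[mask][:, t_i, :]  # (nv, 3)
        proj = tang @ dirs.T  # cos(angle to gradient)
        acc[mask] += np.exp(-b * (rad + (ax - rad) * proj**2))
    signal[any_tract] = acc[any_tract] / n_comp[any_tract, None]

    data = np.concatenate(
        [np.ones(shape + (spec.n_b0,)), signal], axis=-1
    ) * spec.s0

    if spec.snr is not None and np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        noise_r = rng.normal(0.0, sigma, data.shape)
        noise_i = rng.normal(0.0, sigma, data.shape)
        data = np.sqrt((data + noise_r) ** 2 + noise_i**2)

    dwi = DWISeries(data.astype(np.float32), gtab, spec.voxel_size)
    return dwi, occupancy


def random_crossing_spec(
    seed: int = 0,
    grid: int = 32,
    n_tracts: int = 2,
    snr: float | None = 20.0,
    n_directions: int = 30,
    radius_range: tuple[float, float] = (3.0, 4.5),
) -> PhantomSpec:
    """A randomized two-to-four-tract crossing geometry on a cubic grid.

    Tract 1 runs roughly along x, tract 2 along y (they cross near the
    center), further tracts along z / diagonal.  The random seed jitters
    offsets, curvature and radii so distinct seeds give distinct
    geometries while staying inside the grid.
    """
    rng = np.random.default_rng(seed)
    c = grid / 2.0
    span = np.array([-0.45 * grid, 0.45 * grid])
    axes = [0, 1, 2, 0]
    tracts = []
    for t_i in range(n_tracts):
        axis = axes[t_i]
        offset = rng.uniform(-0.12 * grid, 0.12 * grid, size=3)
        bow = rng.uniform(-0.08 * grid, 0.08 * grid, size=3)
        radius = rng.uniform(*radius_range)
        ts = np.linspace(-1.0, 1.0, 7)
        pts = np.tile(c + offset, (ts.size, 1))
        pts[:, axis] = c + span[0] + (span[1] - span[0]) * (ts + 1) / 2
        perp = (axis + 1) % 3
        pts[:, perp] += bow[perp] * (1 - ts**2)  # gentle quadratic bow
        if t_i == 3:  # fourth tract: oblique
            pts[:, (axis + 2) % 3] += np.linspace(-0.2 * grid, 0.2 * grid, ts.size)
        pts = np.clip(pts, 2.0, grid - 3.0)
        tracts.append(TractSpec(label=t_i + 1, points=tuple(map(tuple, pts)),
                                radius=radius))
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        tracts=tracts,
        n_directions=n_directions,
        snr=snr,
        seed=int(rng.integers(2**31)),
    )
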