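"""Random, well-spread q-space measurement subsets.

Training uses a fresh small subset of the gradient directions at every
iteration (size drawn uniformly from 6–12 by default) as data
augmentation; inference averages predictions over n such subsets.
Subsets are chosen by randomized farthest-point sampling: the first
direction is drawn uniformly at random among the non-b0 measurements and
each subsequent one maximizes its minimum angular distance to those
already chosen (ties broken at random).  Random initialization supplies
the stochasticity, greedy growth the angular spread.

Angular distance treats q and −q as equivalent (the diffusion signal is
antipodally symmetric), so distances live in [0, π/2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .gradients import GradientTable

__all__ = [
    "SubsetSpec",
    "angular_distance",
    "select_spread_subset",
    "make_training_sampler",
    "make_test_subsets",
]


@dataclass(frozen=True)
class SubsetSpec:
    """An ordered index set into a gradient table, with its RNG seed."""

    indices: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be distinct")

    @property
    def size(self) -> int:
        return len(self.indices)

    def to_json(self) -> str:
        return json.dumps(
            {"indices": list(self.indices), "size": self.size, "seed": self.seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "SubsetSpec":
        d = json.loads(text)
        return cls(indices=tuple(d["indices"]), seed=d["seed"])


def angular_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions modulo antipodal symmetry, in [0, π/2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero vector has no direction")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos)
    return float(min(theta, np.pi - theta))


def _pairwise_angles(vecs: np.ndarray) -> np.ndarray:
    """All-pairs antipodal angular distance matrix for unit vectors."""
    cos = np.clip(np.abs(vecs @ vecs.T), 0.0, 1.0)
    return np.arccos(cos)


def _greedy_farthest(angles: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[int]:
    n = angles.shape[0]
    chosen = [int(rng.integers(n))]
    min_dist = angles[chosen[0]].copy()
    min_dist[chosen[0]] = -np.inf
    for _ in range(1, k):
        best = np.flatnonzero(min_dist == min_dist.max())
        nxt = int(best[rng.integers(best.size)])
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, angles[nxt])
        min_dist[nxt] = -np.inf
    return chosen


def _min_pairwise(angles: np.ndarray, sel) -> float:
    sub = angles[np.ix_(sel, sel)]
    iu = np.triu_indices(len(sel), 1)
    return float(sub[iu].min()) if iu[0].size else np.inf


def _swap_refine(angles: np.ndarray, sel: list[int]) -> tuple[list[int], float]:
    """Single-point swap hill climbing on the minimum pairwise angle."""
    sel = list(sel)
    n = angles.shape[0]
    score = _min_pairwise(angles, sel)
    improved = True
    while improved and len(sel) < n and len(sel) > 1:
        improved = False
        for i in range(len(sel)):
            rest = sel[:i] + sel[i + 1:]
            base = _min_pairwise(angles, rest)
            # score of replacing sel[i] by any outside candidate j
            cand_scores = np.minimum(base, angles[:, rest].min(axis=1))
            cand_scores[sel] = -np.inf
            j = int(cand_scores.argmax())
            if cand_scores[j] > score + 1e-12:
                sel[i] = j
                score = float(cand_scores[j])
                improved = True
    return sel, score


def select_spread_subset(
    gtab: GradientTable, k: int, rng_seed: int, n_restarts: int = 8
) -> SubsetSpec:
    """Randomized farthest-point selection of k diffusion-weighted indices.

    Each restart seeds greedy farthest-point growth at a random
    direction and hill-climbs with single-point swaps on the minimum
    pairwise angle; the best-spread restart wins.  Random starts keep
    the selection stochastic across seeds while the refinement keeps the
    minimum pairwise angle near the combinatorial optimum.
    """
    candidates = gtab.dwi_indices
    if k < 1 or k > candidates.size:
        raise ValueError(
            f"cannot select {k} of {candidates.size} diffusion-weighted measurements"
        )
    rng = np.random.default_rng(rng_seed)
    vecs = gtab.bvecs[candidates]
    angles = _pairwise_angles(vecs)
    best_sel, best_score = None, -np.inf
    for _ in range(n_restarts):
        sel = _greedy_farthest(angles, k, rng)
        sel, score = _swap_refine(angles, sel)
        if score > best_score:
            best_sel, best_score = sel, score
    return SubsetSpec(
        indices=tuple(int(candidates[i]) for i in best_sel), seed=int(rng_seed)
    )


def make_training_sampler(
    gtab: GradientTable,
    size_min: int = 6,
    size_max: int = 12,
    rng_seed: int = 0,
) -> Iterator[SubsetSpec]:
    """Endless reproducible stream of training subsets.

    Each draw picks a size uniformly in [size_min, size_max] and then runs
    :func:`select_spread_subset` with a seed derived from the stream seed.
    """
    n_avail = gtab.dwi_indices.size
    if not (1 <= size_min <= size_max <= n_avail):
        raise ValueError(
            f"invalid size bounds [{size_min}, {size_max}] for {n_avail} "
            "diffusion-weighted measurements"
        )

    def stream() -> Iterator[SubsetSpec]:
        rng = np.random.default_rng(rng_seed)
        while True:
            k = int(rng.integers(size_min, size_max + 1))
            sub_seed = int(rng.integers(2**31))
            yield select_spread_subset(gtab, k, sub_seed)

    return stream()


def make_test_subsets(
    gtab: GradientTable,
    k: int,
    n: int = 10,
    rng_seed: int = 0,
    disjoint: bool = False,
) -> list[SubsetSpec]:
    """n inference subsets of fixed size k, optionally pairwise disjoint.

    Disjoint subsets (e.g. two size-6 subsets of a 30-direction scan) let
    one measure how reproducible the segmentation is across independent
    measurement subsets.
    """
    avail = list(gtab.dwi_indices)
    if disjoint and n * k > len(avail):
        raise ValueError(
            f"{n} disjoint subsets of size {k} need {n * k} measurements, "
            f"only {len(avail)} available"
        )
    if k > len(avail):
        raise ValueError(f"subset size {k} exceeds {len(avail)} measurements")
    rng = np.random.default_rng(rng_seed)
    out: list[SubsetSpec] = []
    used: set[int] = set()
    for i in range(n):
        # the first subset uses rng_seed itself, so n=1 coincides with a
        # plain select_spread_subset call; later subsets use derived seeds
        sub_seed = int(rng_seed) if i == 0 else int(rng.integers(2**31))
        if disjoint:
            keep = np.array([i for i in avail if i not in used], dtype=int)
            sub_gtab = GradientTable(
                gtab.bvals[keep], gtab.bvecs[keep], gtab.b0_threshold
            )
            spec = select_spread_subset(sub_gtab, k, sub_seed)
            # spec indexes rows of sub_gtab; map back to the full table
            indices = tuple(int(keep[j]) for j in spec.indices)
            spec = SubsetSpec(indices=indices, seed=spec.seed)
            used.update(indices)
        else:
            spec = select_spread_subset(gtab, k, sub_seed)
        out.append(spec)
    return out
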