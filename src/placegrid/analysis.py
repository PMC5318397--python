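"""Diagnostics for trained latent representations.

Covers dead-unit counting, per-position winner direction-invariance maps,
direction-summed linear response maps, Delaunay/Voronoi-style lattice
summaries of response peaks, and the largest-to-second-largest ratio used as
a boundary signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from placegrid.arena import BagDataset
from placegrid.autoencoder import DEAD_UNIT_THRESHOLD, AEWeights, encode_linear

logger = logging.getLogger(__name__)

BORDER_EPSILON = 1e-6


@dataclass
class ResponseTensor:
    """Linear latent responses arranged on the (x, y, heading, unit) grid."""

    values: np.ndarray  # (Px, Py, L, Q), nonnegative

    @property
    def n_units(self) -> int:
        return self.values.shape[3]

    @property
    def n_directions(self) -> int:
        return self.values.shape[2]

    def summed_maps(self) -> np.ndarray:
        """Direction-summed response map per unit, shape (Px, Py, Q)."""
        return self.values.sum(axis=2)


@dataclass
class LatticeSummary:
    """Peak geometry of the responsive units' direction-summed maps."""

    peaks: np.ndarray  # (n_responsive, 2) arena coordinates
    edges: np.ndarray  # (n_edges, 2) peak indices of the triangulation
    interior_degree: dict[int, int]  # interior peak index -> Delaunay degree
    polygon_counts: dict[str, int]
    mean_nn_distance: float
    nn_distance_cv: float


_DEGREE_CLASSES = {4: "quadrilateral", 5: "pentagon", 6: "hexagon", 7: "heptagon"}


def response_tensor(
    weights: AEWeights,
    dataset: BagDataset,
    sparsity=None,
) -> ResponseTensor:
    """Linear latent response of every unit for every (point, heading) row.

    Rows dropped from training are still evaluated (their bag is all-zero,
    so a zero-bias network responds zero there).
    """
    cfg = dataset.config
    H = encode_linear(dataset.X, weights, sparsity)
    n_side = cfg.grid_cells + 1
    L, Q = cfg.n_directions, H.shape[1]
    # rows are point-major with x fastest within a row of constant y
    vals = H.reshape(n_side, n_side, L, Q).transpose(1, 0, 2, 3)
    return ResponseTensor(values=np.ascontiguousarray(vals))


def count_dead_units(tensor: ResponseTensor, threshold: float = DEAD_UNIT_THRESHOLD) -> int:
    """Units whose maximum response over all positions and headings is below
    the threshold."""
    peak = tensor.values.max(axis=(0, 1, 2))
    return int(np.sum(peak <= threshold))


def winner_invariance_map(
    tensor: ResponseTensor, threshold: float = DEAD_UNIT_THRESHOLD
) -> np.ndarray:
    """Per position: the win count of the most direction-invariant unit.

    For each heading the winner is the argmax unit (no winner when every
    response is at or below threshold); the map holds the maximum number of
    headings won by any single unit, from 0 (no response at all) to L
    (one unit wins every heading).
    """
    v = tensor.values
    Px, Py, L, Q = v.shape
    winners = np.argmax(v, axis=3)
    has_winner = v.max(axis=3) > threshold
    out = np.zeros((Px, Py), dtype=np.int64)
    for q in range(Q):
        wins = ((winners == q) & has_winner).sum(axis=2)
        np.maximum(out, wins, out=out)
    return out


def unit_peaks(
    tensor: ResponseTensor, threshold: float = DEAD_UNIT_THRESHOLD
) -> np.ndarray:
    """Arena coordinates of each responsive unit's direction-summed argmax.

    Ties resolve to the lowest flat (row-major y, x) index; no sub-grid
    interpolation.
    """
    maps = tensor.summed_maps()
    Px, Py, Q = maps.shape
    alive = maps.max(axis=(0, 1)) > threshold
    peaks = []
    for q in np.flatnonzero(alive):
        flat = int(np.argmax(maps[:, :, q].T))  # y-major flat index
        iy, ix = divmod(flat, Px)
        peaks.append((ix / (Px - 1), iy / (Py - 1)))
    return np.asarray(peaks, dtype=np.float64).reshape(-1, 2)


def lattice_summary(
    tensor: ResponseTensor | None = None,
    peaks: np.ndarray | None = None,
    threshold: float = DEAD_UNIT_THRESHOLD,
) -> LatticeSummary:
    """Delaunay triangulation of response peaks with a vertex-degree census.

    Interior vertices (not on the convex hull) are classified by their
    triangulation degree: 6 neighbours correspond to a hexagonal cell, 5 to a
    pentagon, 7 to a heptagon, 4 to a quadrilateral.
    """
    if peaks is None:
        if tensor is None:
            raise ValueError("need a response tensor or explicit peaks")
        peaks = unit_peaks(tensor, threshold)
    peaks = np.asarray(peaks, dtype=np.float64)
    if len(peaks) < 3:
        raise ValueError(f"need at least 3 responsive peaks, got {len(peaks)}")
    try:
        tri = Delaunay(peaks)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError(f"degenerate peak configuration: {exc}") from exc
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            edges.add(tuple(sorted((int(simplex[a]), int(simplex[b])))))
    edges = np.array(sorted(edges), dtype=np.int64)
    degree = np.zeros(len(peaks), dtype=np.int64)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    hull = set(int(i) for i in tri.convex_hull.ravel())
    interior = {i: int(degree[i]) for i in range(len(peaks)) if i not in hull}
    counts = {name: 0 for name in _DEGREE_CLASSES.values()}
    counts["other"] = 0
    for deg in interior.values():
        counts[_DEGREE_CLASSES.get(deg, "other")] = counts.get(
            _DEGREE_CLASSES.get(deg, "other"), 0
        ) + 1
    # nearest-neighbour spacing statistics over all peaks
    diff = peaks[:, None, :] - peaks[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    return LatticeSummary(
        peaks=peaks,
        edges=edges,
        interior_degree=interior,
        polygon_counts=counts,
        mean_nn_distance=float(nn.mean()),
        nn_distance_cv=float(nn.std() / nn.mean()) if nn.mean() > 0 else float("nan"),
    )


def second_magnitude_map(tensor: ResponseTensor) -> np.ndarray:
    """Second-largest direction-summed unit activity at each position.

    High values trace the boundaries between neighbouring units' winning
    domains (the dual tessellation of the peak lattice).
    """
    maps = tensor.summed_maps()
    if maps.shape[2] < 2:
        raise ValueError("need at least 2 units for a second-magnitude map")
    part = np.partition(maps, maps.shape[2] - 2, axis=2)
    return part[:, :, -2]


def first_magnitude_map(tensor: ResponseTensor) -> np.ndarray:
    """Largest direction-summed unit activity at each position."""
    return tensor.summed_maps().max(axis=2)


def border_statistic(ordered: np.ndarray, epsilon: float = BORDER_EPSILON) -> float:
    """Ratio of the largest to the second-largest activity.

    Heads toward the boundary leave the second-largest response tiny (no
    field beyond the wall), making the ratio spike.  Zero leading activity
    returns 0; the ratio is capped at ``1 / epsilon``.
    """
    ordered = np.asarray(ordered, dtype=np.float64)
    if ordered.ndim != 1 or ordered.size < 2:
        raise ValueError("need a 1-D descending vector of length >= 2")
    if np.any(np.diff(ordered) > 1e-12):
        raise ValueError("vector must be sorted in descending order")
    a1, a2 = ordered[0], ordered[1]
    if a1 <= 0:
        return 0.0
    ratio = a1 / (a2 + epsilon)
    return float(min(ratio, 1.0 / epsilon)) if epsilon > 0 else float(ratio)
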