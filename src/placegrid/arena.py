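"""Square arena with landmark boxes and head-direction-conditioned bag inputs.

The simulated animal sits on a lattice of grid points inside the unit square.
The arena is surrounded by non-overlapping axis-aligned boxes (remote visual
cues).  For each grid point and each discrete heading, a binary visibility
vector over boxes is recorded: a box is visible if a ray cast inside the
field of view hits it first (occlusion-aware).  Per-heading visibility
vectors are concatenated into a single sparse "bag" input, optionally masked
to a window of headings and sector-normalized.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: angular spacing of occlusion-test rays, degrees
RAY_STEP_DEG = 0.25

#: minimum ray-travel distance: hits closer than this are ignored
_T_EPS = 1e-9

try:  # pragma: no cover - exercised implicitly when numba is present
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and sampling parameters of the arena simulator.

    The arena is the unit square ``[0, 1]^2`` discretized into ``grid_cells``
    cells per side, i.e. ``(grid_cells + 1)^2`` inclusive lattice points.
    ``n_directions`` headings are spaced ``direction_spacing`` degrees apart
    and each heading sees a ``fov``-degree field of view centered on it.
    """

    grid_cells: int = 36
    n_boxes: int = 150
    n_directions: int = 18
    direction_spacing: float = 20.0
    fov: float = 28.0
    seed: int = 0
    #: uniform range for box half extents (per axis), arena-side units
    box_half_extent: tuple[float, float] = (0.01, 0.05)
    #: gap between arena boundary and nearest box face / outer reach of band
    band: tuple[float, float] = (0.02, 0.45)

    def __post_init__(self) -> None:
        if self.grid_cells < 1:
            raise ValueError("grid_cells must be >= 1")
        if self.n_boxes < 0:
            raise ValueError("n_boxes must be >= 0")
        if abs(self.n_directions * self.direction_spacing - 360.0) > 1e-9:
            raise ValueError(
                "n_directions * direction_spacing must equal 360 degrees"
            )
        if not (0 < self.fov <= 360):
            raise ValueError("fov must lie in (0, 360]")
        if self.box_half_extent[0] <= 0 or self.box_half_extent[1] < self.box_half_extent[0]:
            raise ValueError("box_half_extent must be an increasing positive range")

    # -- derived constants ---------------------------------------------------

    @property
    def n_grid_points(self) -> int:
        return (self.grid_cells + 1) ** 2

    @property
    def n_rows(self) -> int:
        """Rows of the full bag dataset: grid points x headings."""
        return self.n_grid_points * self.n_directions

    @property
    def input_dim(self) -> int:
        """Length of the concatenated bag vector: boxes x headings."""
        return self.n_boxes * self.n_directions

    @property
    def directions_deg(self) -> np.ndarray:
        return np.arange(self.n_directions) * self.direction_spacing

    def field_of_view_deg(self, v: int) -> float:
        """Total angular extent seen through a ``v``-sector mask window."""
        validate_mask_width(v, self.n_directions)
        return min(self.fov + (v - 1) * self.direction_spacing, 360.0)

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream fanned out from the master seed."""
        return np.random.default_rng([zlib.crc32(stream.encode()), self.seed])


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangular landmark outside the arena."""

    center: tuple[float, float]
    half_extent: tuple[float, float]

    @property
    def lo(self) -> tuple[float, float]:
        return (self.center[0] - self.half_extent[0], self.center[1] - self.half_extent[1])

    @property
    def hi(self) -> tuple[float, float]:
        return (self.center[0] + self.half_extent[0], self.center[1] + self.half_extent[1])

    def overlaps(self, other: "Box") -> bool:
        """Strict interior overlap; touching edges do not count."""
        return (
            abs(self.center[0] - other.center[0]) < self.half_extent[0] + other.half_extent[0]
            and abs(self.center[1] - other.center[1]) < self.half_extent[1] + other.half_extent[1]
        )


@dataclass(frozen=True)
class SectorMask:
    """Window of unmasked viewing sectors around a heading index."""

    direction_index: int
    v: int
    n_directions: int = 18

    def __post_init__(self) -> None:
        validate_mask_width(self.v, self.n_directions)

    @property
    def sectors(self) -> np.ndarray:
        return sector_window(self.direction_index, self.v, self.n_directions)

    @property
    def indicator(self) -> np.ndarray:
        ind = np.zeros(self.n_directions, dtype=bool)
        ind[self.sectors] = True
        return ind


@dataclass
class BagDataset:
    """Matrix of concatenated visibility vectors, one row per (point, heading).

    ``X`` always holds all ``(grid_cells+1)^2 * n_directions`` rows in
    (point-major, heading-minor) order; rows whose bag is entirely empty are
    flagged in ``dropped`` (and excluded from training) when normalization is
    on.
    """

    X: np.ndarray
    positions: np.ndarray  # (I, 2) arena coordinates per row
    direction_idx: np.ndarray  # (I,) heading index per row
    dropped: np.ndarray  # (I,) bool
    config: ArenaConfig
    v: int = 1
    normalized: bool = False

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_dropped(self) -> int:
        return int(self.dropped.sum())

    @property
    def active_rows(self) -> np.ndarray:
        return self.X[~self.dropped]

    def loss_mask(self) -> np.ndarray:
        """Boolean (I, J) matrix flagging the unmasked sector blocks per row."""
        L, d = self.config.n_directions, self.config.n_boxes
        mask = np.zeros((self.n_rows, L), dtype=bool)
        for l in range(L):
            rows = self.direction_idx == l
            mask[np.ix_(rows, sector_window(l, self.v, L))] = True
        return np.repeat(mask, d, axis=1)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_x": self.positions[:, 0],
                "position_y": self.positions[:, 1],
                "direction_deg": self.direction_idx * self.config.direction_spacing,
                "dropped": self.dropped,
            }
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(out / "bag_dataset.npz", X=self.X)
        self.metadata().to_csv(out / "rows.csv", index=False)


# ---------------------------------------------------------------------------
# box placement
# ---------------------------------------------------------------------------


def place_boxes(config: ArenaConfig, max_attempts_per_box: int = 2000) -> list[Box]:
    """Pseudo-randomly place non-overlapping boxes in a band around the arena.

    Centers are drawn uniformly over the band's bounding square; candidates
    intersecting the (gap-expanded) arena or any already placed box are
    rejected.  Deterministic for a fixed config seed.
    """
    rng = config.rng("boxes")
    gap, outer = config.band
    lo_bound, hi_bound = -outer, 1.0 + outer
    boxes: list[Box] = []
    attempts = 0
    budget = max_attempts_per_box * max(config.n_boxes, 1)
    while len(boxes) < config.n_boxes:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {config.n_boxes} boxes in {budget} attempts; "
                "the band is too small for this many non-overlapping boxes"
            )
        attempts += 1
        hx, hy = rng.uniform(*config.box_half_extent, size=2)
        cx = rng.uniform(lo_bound + hx, hi_bound - hx)
        cy = rng.uniform(lo_bound + hy, hi_bound - hy)
        cand = Box((cx, cy), (hx, hy))
        # reject anything reaching into the arena plus safety gap
        if cx + hx > -gap and cx - hx < 1.0 + gap and cy + hy > -gap and cy - hy < 1.0 + gap:
            continue
        if any(cand.overlaps(b) for b in boxes):
            continue
        boxes.append(cand)
    logger.info("placed %d boxes in %d attempts", len(boxes), attempts)
    return boxes


def boxes_to_arrays(boxes: Sequence[Box]) -> tuple[np.ndarray, np.ndarray]:
    """AABB corner arrays (lo, hi), each of shape (n_boxes, 2)."""
    if len(boxes) == 0:
        return np.zeros((0, 2)), np.zeros((0, 2))
    lo = np.array([b.lo for b in boxes], dtype=np.float64)
    hi = np.array([b.hi for b in boxes], dtype=np.float64)
    return lo, hi


def boxes_to_frame(boxes: Sequence[Box]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.center[0], b.center[1], b.half_extent[0], b.half_extent[1]) for b in boxes],
        columns=["cx", "cy", "hx", "hy"],
    )


def boxes_from_frame(df: pd.DataFrame) -> list[Box]:
    return [Box((r.cx, r.cy), (r.hx, r.hy)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def _first_hit_numpy(origin: np.ndarray, angles: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Index of the first box hit by each ray, -1 for misses (slab method)."""
    if lo.shape[0] == 0:
        return np.full(angles.shape[0], -1, dtype=np.int64)
    d = np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    d = np.where(np.abs(d) < 1e-12, 1e-12, d)
    inv = 1.0 / d
    t1 = (lo[None, :, :] - origin[None, None, :]) * inv[:, None, :]
    t2 = (hi[None, :, :] - origin[None, None, :]) * inv[:, None, :]
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    tnear = np.maximum(tmin[..., 0], tmin[..., 1])
    tfar = np.minimum(tmax[..., 0], tmax[..., 1])
    hit = (tnear <= tfar) & (tfar > 0) & (tnear > _T_EPS)
    tnear = np.where(hit, tnear, np.inf)
    idx = np.argmin(tnear, axis=1).astype(np.int64)
    idx[~np.isfinite(tnear[np.arange(len(idx)), idx])] = -1
    return idx


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _slab_t(ox, oy, dx, dy, blo, bhi):  # pragma: no cover - jit
        if abs(dx) < 1e-12:
            dx = 1e-12
        if abs(dy) < 1e-12:
            dy = 1e-12
        tx1 = (blo[0] - ox) / dx
        tx2 = (bhi[0] - ox) / dx
        ty1 = (blo[1] - oy) / dy
        ty2 = (bhi[1] - oy) / dy
        tnear = max(min(tx1, tx2), min(ty1, ty2))
        tfar = min(max(tx1, tx2), max(ty1, ty2))
        if tnear <= tfar and tfar > 0 and tnear > _T_EPS:
            return tnear
        return np.inf

    @numba.njit(cache=True)
    def _first_hit_table_nb(origins, n_rays, lo, hi):  # pragma: no cover - jit
        P = origins.shape[0]
        B = lo.shape[0]
        step = 2.0 * np.pi / n_rays
        cs = np.cos(np.arange(n_rays) * step)
        sn = np.sin(np.arange(n_rays) * step)
        out = np.full((P, n_rays), -1, dtype=np.int64)
        best = np.empty(n_rays, dtype=np.float64)
        for p in range(P):
            ox, oy = origins[p, 0], origins[p, 1]
            best[:] = np.inf
            for b in range(B):
                # angular interval subtended by the box (origin is outside,
                # so the span is < pi and bracketed by corner angles)
                a0 = np.arctan2(lo[b, 1] - oy, lo[b, 0] - ox)
                amin = 0.0
                amax = 0.0
                for ci in range(1, 4):
                    cxx = lo[b, 0] if ci % 2 == 0 else hi[b, 0]
                    cyy = lo[b, 1] if ci < 2 else hi[b, 1]
                    a = np.arctan2(cyy - oy, cxx - ox) - a0
                    while a > np.pi:
                        a -= 2.0 * np.pi
                    while a < -np.pi:
                        a += 2.0 * np.pi
                    if a < amin:
                        amin = a
                    if a > amax:
                        amax = a
                ka = int(np.ceil((a0 + amin) / step - 1e-9))
                kb = int(np.floor((a0 + amax) / step + 1e-9))
                for k in range(ka, kb + 1):
                    kk = k % n_rays
                    t = _slab_t(ox, oy, cs[kk], sn[kk], lo[b], hi[b])
                    if t < best[kk]:
                        best[kk] = t
                        out[p, kk] = b
        return out


def _first_hit_table(origins: np.ndarray, n_rays: int, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """First-hit box index for rays on a uniform angular grid, per origin."""
    if _HAVE_NUMBA and lo.shape[0] > 0:
        return _first_hit_table_nb(
            np.ascontiguousarray(origins, dtype=np.float64),
            n_rays,
            np.ascontiguousarray(lo),
            np.ascontiguousarray(hi),
        )
    angles = np.arange(n_rays) * (2.0 * np.pi / n_rays)
    return np.stack([_first_hit_numpy(o, angles, lo, hi) for o in origins])


def _fov_offsets_deg(fov: float, step: float = RAY_STEP_DEG) -> np.ndarray:
    """Ray offsets spanning the closed interval [-fov/2, fov/2]."""
    half = fov / 2.0
    n = int(np.floor(half / step + 1e-9))
    return np.arange(-n, n + 1) * step


def compute_visibility(
    position: Sequence[float],
    direction_deg: float,
    boxes: Sequence[Box],
    config: ArenaConfig,
) -> np.ndarray:
    """Binary visibility of each box inside the fov centered on ``direction``.

    A box is visible iff at least one of the rays cast across the field of
    view (spaced ``RAY_STEP_DEG`` apart, endpoints included) hits it before
    any other box.
    """
    lo, hi = boxes_to_arrays(boxes)
    angles = np.deg2rad(direction_deg + _fov_offsets_deg(config.fov))
    hits = _first_hit_numpy(np.asarray(position, dtype=np.float64), angles, lo, hi)
    vis = np.zeros(len(boxes), dtype=np.uint8)
    vis[hits[hits >= 0]] = 1
    return vis


def grid_points(config: ArenaConfig) -> np.ndarray:
    """Inclusive (M+1)x(M+1) lattice over the unit square, x-major rows."""
    return lattice_points(config.grid_cells)


def lattice_points(resolution: int) -> np.ndarray:
    """Inclusive lattice of ``(resolution+1)^2`` points over the unit square."""
    axis = np.arange(resolution + 1) / resolution
    gx, gy = np.meshgrid(axis, axis, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


def fine_grid_points(resolution: int = 150) -> np.ndarray:
    """Sample points of the fine prediction grid (defaults to 151x151)."""
    return lattice_points(resolution)


def visibility_table(
    config: ArenaConfig, boxes: Sequence[Box], points: np.ndarray | None = None
) -> np.ndarray:
    """Visibility of every box from every lattice point in every heading.

    Returns a uint8 array of shape (n_points, n_directions, n_boxes).  Rays
    are shared across overlapping sectors: first hits are computed once per
    point on the global ``RAY_STEP_DEG`` grid and each sector gathers its
    window of rays.
    """
    if points is None:
        points = grid_points(config)
    P, L, d = len(points), config.n_directions, config.n_boxes
    out = np.zeros((P, L, d), dtype=np.uint8)
    if d == 0:
        return out
    step = RAY_STEP_DEG
    if abs(config.direction_spacing / step - round(config.direction_spacing / step)) > 1e-9:
        raise ValueError("direction_spacing must be a multiple of the ray step")
    n_rays = int(round(360.0 / step))
    lo, hi = boxes_to_arrays(boxes)
    hits = _first_hit_table(points, n_rays, lo, hi)
    offsets = np.round(_fov_offsets_deg(config.fov) / step).astype(np.int64)
    rows = np.arange(P)
    for l in range(L):
        center = int(round(l * config.direction_spacing / step))
        h = hits[:, (center + offsets) % n_rays]
        valid = h >= 0
        out[np.repeat(rows, valid.sum(axis=1)), l, h[valid]] = 1
    return out


# ---------------------------------------------------------------------------
# masks, normalization, dataset assembly
# ---------------------------------------------------------------------------


def validate_mask_width(v: int, n_directions: int) -> None:
    """Valid widths are the odd numbers 1..L-1 plus the full circle L."""
    if v == n_directions:
        return
    if not (1 <= v < n_directions and v % 2 == 1):
        raise ValueError(
            f"mask width v={v} invalid: must be odd in [1, {n_directions - 1}] "
            f"or the full {n_directions}"
        )


def sector_window(direction_index: int, v: int, n_directions: int) -> np.ndarray:
    """Unmasked sector indices: the heading plus symmetric neighbors, wrapped."""
    validate_mask_width(v, n_directions)
    if v == n_directions:
        return np.arange(n_directions)
    half = (v - 1) // 2
    return (direction_index + np.arange(-half, half + 1)) % n_directions


def apply_mask(vis_point: np.ndarray, mask: SectorMask) -> np.ndarray:
    """Concatenated input for one (point, heading): unmasked sector blocks
    hold that sector's visibility vector, masked blocks are all-zero.

    ``vis_point`` is the (L, d) visibility slab of a single grid point.
    """
    L, d = vis_point.shape
    row = np.zeros((L, d), dtype=vis_point.dtype)
    sectors = mask.sectors
    row[sectors] = vis_point[sectors]
    return row.reshape(L * d)


def normalize_sectors(row: np.ndarray, d: int) -> tuple[np.ndarray, bool]:
    """Rescale each d-block to unit L2 norm; all-zero blocks stay zero.

    Returns the normalized row and a drop flag that is True iff the whole
    row is zero.
    """
    if row.shape[-1] % d != 0:
        raise ValueError("row length must be divisible by the block size d")
    blocks = row.reshape(-1, d).astype(np.float64)
    norms = np.linalg.norm(blocks, axis=1)
    nz = norms > 0
    blocks[nz] /= norms[nz, None]
    return blocks.reshape(row.shape), not nz.any()


def build_bag_dataset(
    config: ArenaConfig,
    boxes: Sequence[Box] | None = None,
    v: int = 1,
    normalize: bool = False,
    points: np.ndarray | None = None,
    vis: np.ndarray | None = None,
    dtype: np.dtype = np.float32,
) -> BagDataset:
    """Assemble the full (point x heading) bag dataset.

    One row per (lattice point, heading), ordered point-major.  Each row is
    the concatenation of L d-blocks; with mask width ``v`` the blocks of the
    window around the heading are populated from that point's visibility and
    the rest are zero.  With ``normalize`` on, each populated block is
    rescaled to unit norm and entirely-zero rows are flagged as dropped.

    Values are binary or unit-norm fractions, so single precision (the
    default) is ample and halves the memory traffic of the full-size matrix.
    """
    if boxes is None:
        boxes = place_boxes(config)
    if points is None:
        points = grid_points(config)
    if vis is None:
        vis = visibility_table(config, boxes, points)
    P, L, d = vis.shape
    J = L * d
    X = np.zeros((P, L, L, d), dtype=dtype)
    idx = np.arange(L)
    half = 0 if v == L else (v - 1) // 2
    offsets = range(-half, half + 1) if v < L else range(L)
    for o in offsets:
        s = (idx + o) % L if v < L else idx * 0 + o
        X[:, idx, s, :] = vis[:, s, :]
    X = X.reshape(P * L, J)
    positions = np.repeat(points, L, axis=0)
    direction_idx = np.tile(np.arange(L), P)
    dropped = np.zeros(P * L, dtype=bool)
    if normalize:
        blocks = X.reshape(-1, d)
        norms = np.linalg.norm(blocks, axis=1)
        nz = norms > 0
        blocks[nz] /= norms[nz, None]
        X = blocks.reshape(P * L, J)
        dropped = ~np.any(X != 0, axis=1)
    logger.info(
        "bag dataset: %d rows x %d cols (v=%d, normalize=%s, dropped=%d)",
        X.shape[0], J, v, normalize, int(dropped.sum()),
    )
    return BagDataset(
        X=X,
        positions=positions,
        direction_idx=direction_idx,
        dropped=dropped,
        config=config,
        v=v,
        normalized=normalize,
    )


def warmup_kernels() -> None:
    """Trigger JIT compilation of the ray-casting kernel on a tiny scene."""
    if _HAVE_NUMBA:
        _first_hit_table(np.array([[0.5, 0.5]]), 8, np.array([[2.0, 2.0]]), np.array([[3.0, 3.0]]))
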