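"""Magnitude-ordered straight-path prediction and beyond-arena continuation.

Latent activities are collected on a fine inclusive lattice, sorted by
magnitude (discarding unit identity), and sampled along straight paths one
fine-grid step at a time.  A linear predictor (Moore-Penrose pseudoinverse or
partial least squares) maps each n-step ordered history window to the next
step; feeding predictions back autoregressively continues the representation
beyond the explored arena, where the leading component traces a periodic,
approximately hexagonal field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from placegrid.arena import ArenaConfig, build_bag_dataset, lattice_points
from placegrid.autoencoder import AEWeights, encode_linear

logger = logging.getLogger(__name__)


def magnitude_order(a: np.ndarray) -> np.ndarray:
    """Sort a vector nonincreasing, discarding unit identity."""
    a = np.asarray(a)
    return -np.sort(-a, axis=-1)


@dataclass
class ActivityField:
    """Magnitude-unordered latent activities on the fine lattice.

    ``values[p, l]`` is the latent vector at fine-grid point ``p`` (point
    index over the inclusive ``(resolution+1)^2`` lattice, y-major with x
    fastest) for heading index ``l``.
    """

    values: np.ndarray  # (P, L, Q)
    resolution: int
    config: ArenaConfig

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def spacing(self) -> float:
        return 1.0 / self.resolution

    def point_index(self, xy: np.ndarray) -> np.ndarray:
        """Nearest fine-grid point per row of ``xy`` (lowest index on ties)."""
        n = self.resolution + 1
        # round half down resolves equidistant points to the lower index
        idx = np.ceil(np.asarray(xy) * self.resolution - 0.5).astype(np.int64)
        idx = np.clip(idx, 0, self.resolution)
        return idx[..., 1] * n + idx[..., 0]


def fine_grid_activities(
    weights: AEWeights,
    config: ArenaConfig,
    boxes,
    resolution: int = 150,
    v: int = 1,
    normalize: bool = True,
) -> ActivityField:
    """Latent activity at every fine lattice point for every heading.

    The fine dataset is built exactly like the training data (same mask
    width and normalization) at the higher spatial resolution.
    """
    points = lattice_points(resolution)
    ds = build_bag_dataset(config, boxes, v=v, normalize=normalize, points=points)
    H = encode_linear(ds.X, weights)
    L = config.n_directions
    values = H.reshape(len(points), L, -1)
    return ActivityField(values=values, resolution=resolution, config=config)


@dataclass
class PathWindowSet:
    """Training windows for one heading's straight-path predictor.

    ``R`` stacks the flattened n-step magnitude-ordered history windows
    (newest step last); ``R_next`` holds the (n+1)-st step.  Every window's
    n+1 consecutive positions lie inside the arena.
    """

    R: np.ndarray  # (t, n*m)
    R_next: np.ndarray  # (t, m)
    direction_deg: float
    n_steps: int
    starts: np.ndarray  # (t, 2) window start positions

    @property
    def n_windows(self) -> int:
        return self.R.shape[0]

    @property
    def m(self) -> int:
        return self.R_next.shape[1]


def build_path_windows(
    field: ActivityField, direction_deg: float, n: int
) -> PathWindowSet:
    """All maximal straight-path windows for one heading.

    Paths start at every fine-grid point, advance one grid spacing per step
    along the heading, and contribute a window for every offset at which all
    ``n + 1`` positions stay inside the unit square.  Each step's sample is
    the magnitude-ordered activity of the nearest fine-grid point.
    """
    if n < 1:
        raise ValueError("window length n must be >= 1")
    cfg = field.config
    dir_idx = int(round(direction_deg / cfg.direction_spacing)) % cfg.n_directions
    if abs(dir_idx * cfg.direction_spacing - direction_deg % 360.0) > 1e-9:
        raise ValueError(
            f"direction {direction_deg} is not one of the {cfg.n_directions} headings"
        )
    step = field.spacing * np.array(
        [np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))]
    )
    pts = lattice_points(field.resolution)
    m = field.values.shape[2]
    # a start is admissible iff its final position is still inside the arena
    final = pts + n * step
    tol = 1e-9
    ok = (
        (final[:, 0] >= -tol)
        & (final[:, 0] <= 1 + tol)
        & (final[:, 1] >= -tol)
        & (final[:, 1] <= 1 + tol)
    )
    starts = pts[ok]
    if len(starts) == 0:
        warnings.warn(
            f"no admissible {n + 1}-step window for direction {direction_deg}",
            stacklevel=2,
        )
        return PathWindowSet(
            R=np.zeros((0, n * m)),
            R_next=np.zeros((0, m)),
            direction_deg=direction_deg,
            n_steps=n,
            starts=np.zeros((0, 2)),
        )
    ordered = magnitude_order(field.values[:, dir_idx, :])
    samples = np.empty((len(starts), n + 1, m))
    for j in range(n + 1):
        samples[:, j, :] = ordered[field.point_index(starts + j * step)]
    return PathWindowSet(
        R=samples[:, :n, :].reshape(len(starts), n * m),
        R_next=samples[:, n, :],
        direction_deg=direction_deg,
        n_steps=n,
        starts=starts,
    )


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


@dataclass
class PseudoinversePredictor:
    """Least-squares linear map from a stacked history window to the next step."""

    M: np.ndarray  # (m, n*m)
    direction_deg: float = 0.0

    def predict(self, window: np.ndarray) -> np.ndarray:
        window = np.asarray(window, dtype=np.float64)
        if window.shape[-1] != self.M.shape[1]:
            raise ValueError(
                f"window length {window.shape[-1]} != {self.M.shape[1]}"
            )
        return window @ self.M.T


@dataclass
class PLSPredictor:
    """Partial-least-squares regression from history window to next step."""

    model: PLSRegression
    n_components: int
    direction_deg: float = 0.0

    def predict(self, window: np.ndarray) -> np.ndarray:
        arr = np.asarray(window, dtype=np.float64)
        single = arr.ndim == 1
        out = self.model.predict(np.atleast_2d(arr))
        out = out.reshape(1 if single else arr.shape[0], -1)
        return out[0] if single else out


def fit_pseudoinverse(windows: PathWindowSet) -> PseudoinversePredictor:
    """Minimum-norm least-squares fit of the next step on the history window."""
    t, nm = windows.R.shape
    if t <= nm:
        logger.warning(
            "history matrix has %d windows for %d coefficients; "
            "solution is the minimum-norm one", t, nm,
        )
    M = np.linalg.pinv(windows.R) @ windows.R_next
    return PseudoinversePredictor(M=M.T, direction_deg=windows.direction_deg)


def fit_pls(windows: PathWindowSet, n_components: int = 15) -> PLSPredictor:
    """Two-block PLS regression of the next step on the history window."""
    bound = min(windows.n_windows, windows.R.shape[1])
    if not (1 <= n_components <= bound):
        raise ValueError(
            f"n_components={n_components} out of range [1, {bound}] "
            f"(min of {windows.n_windows} windows and {windows.R.shape[1]} columns)"
        )
    model = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(windows.R, windows.R_next)
    return PLSPredictor(
        model=model, n_components=n_components, direction_deg=windows.direction_deg
    )


def predict_next(predictor, window: np.ndarray) -> np.ndarray:
    """One-step prediction from a stacked n*m history window."""
    return predictor.predict(np.asarray(window))


@dataclass
class Rollout:
    """Autoregressive continuation of one seed window."""

    steps: np.ndarray  # (steps, m) predicted ordered activity vectors
    fade: np.ndarray  # (steps,) euclidean norm per predicted step
    truncated: bool = False


def continue_prediction(
    predictor,
    seed_window: np.ndarray,
    steps: int,
    resort: bool = False,
) -> Rollout:
    """Roll the predictor forward, feeding each prediction back in.

    The oldest step of the window is dropped and the newest prediction
    appended each iteration.  Predictions are fed back raw by default
    (``resort`` re-sorts them into descending order first); per-step norms
    are recorded as the fade metric.  A non-finite prediction truncates the
    rollout with a warning.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    window = np.asarray(seed_window, dtype=np.float64).copy()
    nm = window.shape[-1]
    m = predictor.M.shape[0] if isinstance(predictor, PseudoinversePredictor) else (
        predictor.model.y_loadings_.shape[0]
    )
    if nm % m != 0:
        raise ValueError("seed window length is not a multiple of the step size")
    out = np.zeros((steps, m))
    fade = np.zeros(steps)
    for i in range(steps):
        with np.errstate(over="ignore", invalid="ignore"):
            nxt = np.asarray(predictor.predict(window), dtype=np.float64).reshape(m)
        if not np.isfinite(nxt).all():
            warnings.warn(f"rollout became non-finite at step {i}; truncating", stacklevel=2)
            return Rollout(steps=out[:i], fade=fade[:i], truncated=True)
        if resort:
            nxt = magnitude_order(nxt)
        out[i] = nxt
        with np.errstate(over="ignore"):
            fade[i] = float(np.linalg.norm(nxt))
        window = np.concatenate([window[m:], nxt])
    return Rollout(steps=out, fade=fade)


# ---------------------------------------------------------------------------
# prediction fields beyond the arena
# ---------------------------------------------------------------------------


@dataclass
class PredictionField:
    """Leading ordered component along parallel predicted paths.

    Rows index start points along the arena edge, columns index prediction
    steps; together they tile a parallelogram oriented along the heading.
    """

    leading: np.ndarray  # (n_starts, steps)
    start_points: np.ndarray  # (n_starts, 2)
    direction_deg: float
    step_length: float

    def positions(self) -> np.ndarray:
        """Arena-frame coordinates of every field sample, (n_starts, steps, 2)."""
        d = np.array(
            [np.cos(np.deg2rad(self.direction_deg)), np.sin(np.deg2rad(self.direction_deg))]
        )
        ks = np.arange(1, self.leading.shape[1] + 1)
        return self.start_points[:, None, :] + self.step_length * ks[None, :, None] * d


def edge_seed_windows(field: ActivityField, direction_deg: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Seed windows whose last step ends on the far edge of the arena.

    For each admissible start point on the lattice line that makes the final
    window step land on the arena boundary (the edge the heading exits
    through), returns the stacked n-step history and the endpoint positions.
    """
    windows = build_path_windows(field, direction_deg, n - 1)
    if windows.n_windows == 0:
        return np.zeros((0, n * windows.m)), np.zeros((0, 2))
    step = field.spacing * np.array(
        [np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))]
    )
    ends = windows.starts + (n - 1) * step
    # keep those whose next step would leave the arena: they end at the edge
    nxt = ends + step
    tol = 1e-9
    leaving = ~(
        (nxt[:, 0] >= -tol) & (nxt[:, 0] <= 1 + tol)
        & (nxt[:, 1] >= -tol) & (nxt[:, 1] <= 1 + tol)
    )
    hist = np.concatenate([windows.R, windows.R_next], axis=1)
    return hist[leaving], ends[leaving]


def render_prediction_field(
    predictor,
    field: ActivityField,
    direction_deg: float,
    n: int,
    steps: int = 200,
    resort: bool = False,
) -> PredictionField:
    """Continue prediction beyond the arena from every edge start point."""
    seeds, ends = edge_seed_windows(field, direction_deg, n)
    if len(seeds) == 0:
        raise ValueError(f"no admissible seed windows for direction {direction_deg}")
    leading = np.zeros((len(seeds), steps))
    for i, seed in enumerate(seeds):
        roll = continue_prediction(predictor, seed, steps, resort=resort)
        leading[i, : len(roll.steps)] = roll.steps[:, 0]
    return PredictionField(
        leading=leading,
        start_points=ends,
        direction_deg=direction_deg,
        step_length=field.spacing,
    )


def field_peaks(field: PredictionField, min_value: float = 0.0) -> np.ndarray:
    """Arena-frame positions of local maxima of the leading component.

    A sample is a peak when it strictly exceeds its predecessor along the
    travel axis, is at least as large as every other 4-neighbour in the
    (start, step) parallelogram grid, and exceeds ``min_value``.
    """
    z = field.leading
    core = z[1:-1, 1:-1]
    is_peak = (
        (core >= z[:-2, 1:-1]) & (core >= z[2:, 1:-1])
        & (core > z[1:-1, :-2]) & (core >= z[1:-1, 2:])
        & (core > min_value)
    )
    rows, cols = np.nonzero(is_peak)
    pos = field.positions()
    return pos[rows + 1, cols + 1]
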