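"""Self-organizing map on a toroidal hexagonal grid.

Online Kohonen training: each iteration visits every data entry in a fresh
seeded permutation, finds the entry's best-matching unit (BMU) by Euclidean
distance in feature space, and moves every codebook within the current
neighborhood radius toward the entry. The learning rate decays linearly
(defaults 0.025 → 0.01 over 1500 iterations); the bubble neighborhood radius
decays linearly from one-third of the grid diagonal to 1.

Grid geometry is the subtle part: nodes sit on an odd-row-offset hexagonal
lattice embedded on a torus, so inter-node distances are the minimum over the
nine wrap-around images of the plain Euclidean distance. Grid height must be
even for the hexagonal row parity to close around the torus.

The training inner loop is JIT-compiled with numba when available and falls
back to pure numpy otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not args or not callable(args[0]) else args[0]


@dataclass(frozen=True)
class TrainConfig:
    """SOM training schedule."""

    iterations: int = 1500
    learning_rate_start: float = 0.025
    learning_rate_end: float = 0.01
    radius_start: float | None = None  # default: grid diagonal / 3
    radius_end: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be ≥ 1")
        if not self.learning_rate_start >= self.learning_rate_end > 0:
            raise ValidationError("need learning_rate_start ≥ learning_rate_end > 0")


def hex_coordinates(width: int, height: int) -> np.ndarray:
    """Cartesian positions of grid nodes (row-major), odd rows shifted +1/2.

    Unit horizontal spacing; rows √3/2 apart — the standard pointy-top
    hexagonal packing.
    """
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    x = cols + 0.5 * (rows % 2)
    y = rows * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()])


def toroidal_hex_distances(width: int, height: int) -> np.ndarray:
    """Pairwise node distances on the hexagonal torus.

    Minimum over the 9 wrap images of the Euclidean distance between node
    positions. Requires even ``height`` so row parity is consistent across
    the vertical wrap.
    """
    if height % 2 != 0:
        raise ValidationError("toroidal hexagonal grid needs an even height")
    pos = hex_coordinates(width, height)
    dy_unit = np.sqrt(3.0) / 2.0
    best = np.full((len(pos), len(pos)), np.inf)
    for dx in (-width, 0, width):
        for dr in (-height, 0, height):
            shifted = pos + np.array([dx, dr * dy_unit])
            diff = shifted[:, None, :] - pos[None, :, :]
            np.minimum(best, np.sqrt((diff**2).sum(axis=2)), out=best)
    return best


@dataclass
class SOMGrid:
    """A trained map: codebooks plus grid geometry and the training log."""

    width: int
    height: int
    codebooks: np.ndarray  # (width*height, n_features)
    node_distances: np.ndarray = field(repr=False)
    training_log: np.ndarray = field(repr=False)  # mean BMU distance / iteration

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    def bmu(self, data: np.ndarray) -> np.ndarray:
        """Best-matching unit index for each row of ``data``."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        d2 = ((data[:, None, :] - self.codebooks[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@njit(cache=True)
def _train_loop(codebooks, data, orders, node_dist, lrs, radii):  # pragma: no cover
    n_iter, n_entries = orders.shape
    n_nodes, n_feat = codebooks.shape
    log = np.empty(n_iter)
    for t in range(n_iter):
        lr = lrs[t]
        radius = radii[t]
        total = 0.0
        for e in range(n_entries):
            x = data[orders[t, e]]
            best = 0
            best_d = 1e300
            for n in range(n_nodes):
                d = 0.0
                for f in range(n_feat):
                    diff = codebooks[n, f] - x[f]
                    d += diff * diff
                if d < best_d:
                    best_d = d
                    best = n
            total += np.sqrt(best_d)
            for n in range(n_nodes):
                if node_dist[best, n] <= radius:
                    for f in range(n_feat):
                        codebooks[n, f] += lr * (x[f] - codebooks[n, f])
        log[t] = total / n_entries
    return log


def _train_loop_numpy(codebooks, data, orders, node_dist, lrs, radii):
    n_iter, n_entries = orders.shape
    log = np.empty(n_iter)
    for t in range(n_iter):
        lr, radius = lrs[t], radii[t]
        neigh = node_dist <= radius
        total = 0.0
        for e in range(n_entries):
            x = data[orders[t, e]]
            d2 = ((codebooks - x) ** 2).sum(axis=1)
            best = int(d2.argmin())
            total += np.sqrt(d2[best])
            mask = neigh[best]
            codebooks[mask] += lr * (x - codebooks[mask])
        log[t] = total / n_entries
    return log


def train_som(
    data: np.ndarray,
    config: TrainConfig = TrainConfig(),
    width: int = 20,
    height: int = 20,
) -> SOMGrid:
    """Train a toroidal hexagonal SOM on ``data`` (entries × features).

    Codebooks are initialized uniformly at random within each feature's data
    range. Deterministic given ``config.seed``.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or len(data) < 1:
        raise ValidationError("training data must be a non-empty 2-D array")
    if not np.isfinite(data).all():
        raise ValidationError("training data must be finite")
    rng = np.random.default_rng(config.seed)
    n_nodes = width * height
    lo, hi = data.min(axis=0), data.max(axis=0)
    codebooks = rng.uniform(lo, hi, size=(n_nodes, data.shape[1]))

    node_dist = toroidal_hex_distances(width, height)
    diag = np.hypot(width, height * np.sqrt(3.0) / 2.0)
    r0 = config.radius_start if config.radius_start is not None else diag / 3.0
    T = config.iterations
    frac = np.arange(T) / max(T - 1, 1)
    lrs = config.learning_rate_start + frac * (
        config.learning_rate_end - config.learning_rate_start
    )
    radii = r0 + frac * (config.radius_end - r0)
    orders = np.empty((T, len(data)), dtype=np.int64)
    for t in range(T):
        orders[t] = rng.permutation(len(data))

    loop = _train_loop if _HAVE_NUMBA else _train_loop_numpy
    log = loop(codebooks, data, orders, node_dist, lrs, radii)
    return SOMGrid(width, height, codebooks, node_dist, np.asarray(log))


def quantization_error(grid: SOMGrid, data: np.ndarray) -> float:
    """Mean Euclidean distance from each entry to its BMU codebook."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d2 = ((data[:, None, :] - grid.codebooks[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())
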