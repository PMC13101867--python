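"""Non-metric multidimensional scaling (NMDS).

Kruskal stress-1 minimization by alternating SMACOF-style majorization steps
(the Guttman transform) with monotone regression of embedding distances
against the rank order of the input dissimilarities (pool-adjacent-violators
via :func:`sklearn.isotonic.isotonic_regression`). Implemented directly so
ordination stays seed-deterministic; the best of a few random restarts is
kept.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .errors import ValidationError


@dataclass(frozen=True)
class Ordination:
    embedding: np.ndarray  # (n_points, dims)
    stress: float  # Kruskal stress-1
    stress_path: np.ndarray  # per-iteration stress of the winning restart


def _check_distances(distances: np.ndarray) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValidationError("distances must be non-negative")
    return d


def _stress1(d_embed: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_embed**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_embed - disparities) ** 2).sum() / denom))


def _pcoa_init(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical-MDS (principal coordinates) configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    if coords.shape[1] < dims:  # pragma: no cover - defensive
        coords = np.pad(coords, ((0, 0), (0, dims - coords.shape[1])))
    return coords


def ordinate(
    distances: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> Ordination:
    """NMDS embedding of a symmetric dissimilarity matrix.

    The first restart starts from the classical-MDS configuration (guarding
    against the degenerate cluster-collapse solutions a random start can get
    trapped in); further restarts are random. Each restart alternates (a)
    isotonic regression of embedding distances on the dissimilarity rank
    order to get disparities and (b) a Guttman transform toward those
    disparities, until the stress improvement falls below ``tol``. The
    restart with the lowest final stress wins.
    """
    D = _check_distances(distances)
    n = D.shape[0]
    if n < 2:
        raise ValidationError("need at least two points to ordinate")
    dvec = squareform(D, checks=False)
    if dvec.max() == 0.0:  # all points identical
        return Ordination(np.zeros((n, dims)), 0.0, np.zeros(1))
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)

    best: Ordination | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            X = _pcoa_init(D, dims)
        else:
            X = rng.normal(size=(n, dims)) * dvec.mean()
        path = []
        prev = np.inf
        for _ in range(max_iter):
            d_embed = pdist(X)
            fitted = isotonic_regression(d_embed[order], increasing=True)
            disparities = np.empty_like(fitted)
            disparities[order] = fitted
            stress = _stress1(d_embed, disparities)
            path.append(stress)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform toward the disparities
            W = squareform(disparities, checks=False)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(squareform(d_embed) > 0, W / squareform(d_embed), 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
        cand = Ordination(X, path[-1], np.asarray(path))
        # A later restart must beat the incumbent by a material margin:
        # near-zero stress ties are broken in favor of the metric-informed
        # (classical-MDS-initialized) solution, which guards against
        # degenerate collapsed configurations that reach the same stress.
        if best is None or cand.stress < best.stress - 1e-4:
            best = cand
    assert best is not None
    return best
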