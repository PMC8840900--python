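"""Matérn spatial correlation (smoothness ν = 1) and the knot mesh.

The spatial domain is summarized by ``x`` knots; every sample inherits the
random-field values of its nearest knot (Euclidean distance in a projected
planar coordinate system, km).  Correlation between knots decays with
transformed distance ``d`` as ``(κd)·K₁(κd)`` where ``K₁`` is the modified
Bessel function of the second kind and ``κ`` sets the decorrelation scale
(range ≈ sqrt(8)/κ for ν = 1).  Geometric anisotropy is a unit-determinant
linear transform of the coordinates built from a rotation angle and a
log-aspect ratio; both zero gives isotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import kv

__all__ = [
    "KnotMesh",
    "anisotropy_matrix",
    "build_knot_mesh",
    "map_to_knots",
    "matern_nu1",
    "matern_correlation",
]


def anisotropy_matrix(aniso: np.ndarray | None) -> np.ndarray:
    """Unit-determinant 2x2 coordinate transform from (rotation, log-aspect).

    ``aniso = (theta, log_aspect)``; the transform is
    ``Rot(theta) @ diag(e^{la/2}, e^{-la/2}) @ Rot(theta).T`` so the
    determinant is exactly 1 and ``aniso = (0, 0)`` is the identity.
    """
    if aniso is None:
        return np.eye(2)
    theta, la = float(aniso[0]), float(aniso[1])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    stretch = np.diag([np.exp(la / 2.0), np.exp(-la / 2.0)])
    return rot @ stretch @ rot.T


def matern_nu1(kappa_d: np.ndarray) -> np.ndarray:
    """Matérn ν=1 correlation as a function of κ·d; 1 at zero distance."""
    kd = np.asarray(kappa_d, dtype=float)
    out = np.ones_like(kd)
    pos = kd > 0
    out[pos] = kd[pos] * kv(1, kd[pos])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Matérn correlation; check distances and kappa")
    return out


@dataclass
class KnotMesh:
    """Spatial knots plus the sample → nearest-knot assignment."""

    knot_coords: np.ndarray  # (x, 2), planar km
    assignment: np.ndarray  # (n_samples,) int indices into knot_coords

    def __post_init__(self) -> None:
        self.knot_coords = np.asarray(self.knot_coords, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        self._dist_cache: dict = {}

    @property
    def n_knots(self) -> int:
        return self.knot_coords.shape[0]

    def distances(self, aniso: np.ndarray | None = None) -> np.ndarray:
        """Pairwise knot distances, optionally after the anisotropy transform."""
        key = None if aniso is None else (float(aniso[0]), float(aniso[1]))
        hit = self._dist_cache.get(key)
        if hit is not None:
            return hit
        coords = self.knot_coords
        if key is not None and key != (0.0, 0.0):
            coords = coords @ anisotropy_matrix(aniso).T
        d = cdist(coords, coords)
        self._dist_cache[key] = d
        return d


def build_knot_mesh(sample_coords: np.ndarray, x: int, seed: int = 0) -> KnotMesh:
    """Place ``x`` knots over the sample locations and assign each sample.

    If ``x`` equals the number of unique locations the knots are exactly those
    locations; otherwise knots are k-means cluster centers of the unique
    locations (seeded, deterministic).  Assignment is by nearest knot with
    ties broken toward the lowest knot index.
    """
    coords = np.asarray(sample_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("sample_coords must be an (n, 2) array of planar km coordinates")
    uniq = np.unique(coords, axis=0)
    if x > uniq.shape[0]:
        raise ValueError(
            f"requested {x} knots but only {uniq.shape[0]} unique sample locations"
        )
    if x == uniq.shape[0]:
        knots = uniq
    elif x == 1:
        knots = uniq.mean(axis=0, keepdims=True)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=x, random_state=int(seed), n_init=10)
        km.fit(uniq)
        knots = km.cluster_centers_
    assignment = _nearest(coords, knots)
    return KnotMesh(knot_coords=knots, assignment=assignment)


def _nearest(points: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # argmin returns the first (lowest) index on exact ties
    return np.argmin(cdist(points, knots), axis=1)


def map_to_knots(sample_coords: np.ndarray, mesh: KnotMesh) -> np.ndarray:
    """Nearest-knot index for each row of ``sample_coords`` (ties → lowest index)."""
    pts = np.atleast_2d(np.asarray(sample_coords, dtype=float))
    return _nearest(pts, mesh.knot_coords)


def matern_correlation(
    mesh: KnotMesh, log_kappa: float, aniso: np.ndarray | None = None
) -> np.ndarray:
    """Knot-level Matérn ν=1 correlation matrix R (symmetric, unit diagonal)."""
    kappa = np.exp(float(log_kappa))
    d = mesh.distances(aniso)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite knot distances")
    R = matern_nu1(kappa * d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)
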