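"""Delay-coordinate embedding of scalar time series.

A scalar observable ``z_t`` of a deterministic dynamical system is lifted to
state-space vectors ``(z_t, z_{t+τ}, ..., z_{t+(d-1)τ})``.  The lag ``τ`` is
chosen at the first local minimum of the delayed mutual information and the
dimension ``d`` by the false-nearest-neighbor criterion.

All indices are 0-based internally; the classical 1-based formulas are
translated once here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "RawSeries",
    "EmbeddingParams",
    "Manifold",
    "select_lag",
    "select_dim",
    "delay_embed",
    "truncate_pair",
]


@dataclass(frozen=True)
class RawSeries:
    """A named, uniformly sampled scalar time series."""

    name: str
    values: np.ndarray
    sample_step: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("series must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"series {self.name!r} contains non-finite values")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension d and delay lag τ (in samples)."""

    dim: int
    lag: int

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.lag < 1:
            raise ValueError("embedding lag must be >= 1")

    @property
    def window(self) -> int:
        """Span (d-1)·τ of one embedding vector, in samples."""
        return (self.dim - 1) * self.lag


class Manifold:
    """A delay-embedded vector sequence with its diameter.

    ``points`` has shape (T0, d) with T0 = T - (d-1)·τ when embedded alone;
    in a paired analysis both manifolds are cut to the common T0 first.
    """

    def __init__(self, points: np.ndarray, params: EmbeddingParams,
                 source_name: str = "") -> None:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[0] < 1:
            raise ValueError("manifold needs at least one point")
        self.points = pts
        self.params = params
        self.source_name = source_name

    def __len__(self) -> int:
        return self.points.shape[0]

    @cached_property
    def diameter(self) -> float:
        """Max pairwise Euclidean distance, evaluated in row chunks.

        Chunking only bounds memory; each entry is the same cdist value as in
        the full T0×T0 computation, so the maximum is bit-identical.
        """
        return max_pairwise_distance(self.points)

    def truncated(self, n: int) -> "Manifold":
        """First ``n`` points (used for the common-T0 paired truncation)."""
        if n > len(self):
            raise ValueError("cannot truncate to more points than available")
        return Manifold(self.points[:n], self.params, self.source_name)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Manifold({self.source_name!r}, T0={len(self)}, "
                f"d={self.params.dim}, tau={self.params.lag})")


def max_pairwise_distance(points: np.ndarray, chunk: int = 512) -> float:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    best = 0.0
    for i in range(0, pts.shape[0], chunk):
        d = cdist(pts[i:i + chunk], pts)
        m = float(d.max())
        if m > best:
            best = m
    return best


def _mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int,
                        lo: float, hi: float) -> float:
    """Histogram mutual information with equal-width bins on [lo, hi]."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins, range=[[lo, hi], [lo, hi]])
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def mi_curve(series: RawSeries, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """Delayed mutual information MI(L) for L = 0..max_lag."""
    v = series.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("degenerate series: constant values, MI undefined")
    return np.array([
        _mutual_information(v[:v.size - L] if L else v, v[L:], n_bins, lo, hi)
        for L in range(max_lag + 1)
    ])


def select_lag(series: RawSeries, max_lag: int, n_bins: int = 16) -> int:
    """First local minimum of the delayed mutual information.

    Returns the smallest L in [1, max_lag] with MI(L) < MI(L-1) and
    MI(L) <= MI(L+1).  If no local minimum exists the argmin over the range
    is returned with a warning.
    """
    T = len(series)
    if max_lag >= T / 2:
        raise ValueError(f"max_lag={max_lag} must be below T/2={T / 2}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    # one extra lag so the right-hand condition is checkable at L = max_lag
    upper = min(max_lag + 1, T - 2)
    mi = mi_curve(series, upper, n_bins)
    for L in range(1, max_lag + 1):
        if L + 1 <= upper and mi[L] < mi[L - 1] and mi[L] <= mi[L + 1]:
            return L
    lag = int(np.argmin(mi[1:max_lag + 1])) + 1
    warnings.warn(
        "no local minimum of delayed mutual information in "
        f"[1, {max_lag}]; falling back to argmin lag={lag}",
        stacklevel=2,
    )
    return lag


def fnn_fraction(values: np.ndarray, dim: int, lag: int,
                 rtol: float = 10.0) -> float:
    """False-nearest-neighbor fraction at dimension ``dim``.

    A point's nearest neighbor at dimension d is false when the extra
    coordinate gained at d+1 grows the distance by more than ``rtol`` times
    the d-dimensional distance.  Points whose (d+1)-coordinate does not exist
    or whose neighbor distance is exactly zero are skipped.
    """
    T = values.size
    n = T - dim * lag  # points for which the (d+1)-th coordinate exists
    if n < 2:
        raise ValueError("series too short for FNN at this dimension/lag")
    pts = np.column_stack([values[i * lag:i * lag + n] for i in range(dim)])
    _, idx = cKDTree(pts).query(pts, k=2)
    nbr = idx[:, 1]
    r_d = np.linalg.norm(pts - pts[nbr], axis=1)
    ok = r_d > 0
    if not np.any(ok):
        return 0.0
    extra = np.abs(values[dim * lag:dim * lag + n]
                   - values[nbr + dim * lag])
    return float(np.mean(extra[ok] / r_d[ok] > rtol))


def select_dim(series: RawSeries, lag: int, max_dim: int = 10,
               rtol: float = 10.0, fnn_threshold: float = 0.01) -> int:
    """Smallest dimension whose FNN fraction falls below ``fnn_threshold``."""
    T = len(series)
    if (max_dim - 1) * lag >= T:
        raise ValueError(
            f"series of length {T} too short for max_dim={max_dim}, lag={lag}")
    for d in range(1, max_dim + 1):
        if T - d * lag < 2:
            break
        if fnn_fraction(series.values, d, lag, rtol) < fnn_threshold:
            return d
    warnings.warn(
        f"FNN fraction never fell below {fnn_threshold}; "
        f"returning max_dim={max_dim}", stacklevel=2)
    return max_dim


def delay_embed(series: RawSeries, params: EmbeddingParams) -> Manifold:
    """Embed ``z`` as points (z_t, z_{t+τ}, ..., z_{t+(d-1)τ})."""
    T = len(series)
    window = params.window
    if window >= T:
        raise ValueError(
            f"series of length {T} too short for dim={params.dim}, "
            f"lag={params.lag}; need length > {window}")
    T0 = T - window
    pts = np.column_stack([
        series.values[i * params.lag:i * params.lag + T0]
        for i in range(params.dim)
    ])
    return Manifold(pts, params, series.name)


def truncate_pair(a: Manifold, b: Manifold) -> tuple[Manifold, Manifold]:
    """Cut both manifolds to the common T0 = min(len(a), len(b))."""
    t0 = min(len(a), len(b))
    return a.truncated(t0), b.truncated(t0)
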