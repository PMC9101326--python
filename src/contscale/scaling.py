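"""The continuity-scaling curve and its slope — the causal-strength index.

For an ordered pair (cause ↪ effect) of reconstructed manifolds, causation is
quantified by how the average radius ⟨δ⟩ needed on the cause manifold shrinks
as the radius ε of a neighborhood on the effect manifold shrinks.  The slope
of ⟨δ⟩ against ln ε over the steepest part of the curve is the causal index:
near zero means no directional coupling, and it grows with coupling strength.

Procedure, for effect manifold {u_t} and cause manifold {v_t} of common
length T0 (0-based indices):

1. ε-grid: N_ε log-equally-spaced radii from e·D to D, with D the effect
   manifold diameter.
2. For each usable time t and each ε_j, collect the neighbor index set
   I_t(ε_j) = {τ : |u_{t+1} - u_τ| < ε_j, |t+1-τ| > E} (E a Theiler
   exclusion), and estimate δ_t(ε_j) as the mean of the cause-side partner
   distances |v_t - v_{τ-1}| (arithmetic by default; a harmonic variant is
   available).
3. Plateau-fill undefined cells from the next larger ε; drop times undefined
   even at ε = D.
4. Average over t, form increments S_j of ⟨δ⟩ against ln ε, keep the
   ⌊(N_ε+1)/2⌋ largest, and fit ⟨δ⟩ = s·ln ε + b by least squares over the
   grid points those increments touch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import Manifold, RawSeries, delay_embed, truncate_pair

__all__ = [
    "EpsilonGrid",
    "NeighborIndex",
    "DeltaTable",
    "ScalingCurve",
    "build_epsilon_grid",
    "neighbor_index",
    "delta_estimate",
    "delta_table",
    "fit_slope",
    "continuity_slope",
]

logger = logging.getLogger(__name__)

_UNDEFINED = np.nan  # sentinel for cells with insufficient neighbors


@dataclass(frozen=True)
class EpsilonGrid:
    """Geometric radius grid ε_1 = e·D … ε_{N_ε} = D, equally spaced in ln ε."""

    e: float
    n_eps: int
    values: np.ndarray

    @property
    def ln_values(self) -> np.ndarray:
        return np.log(self.values)


def build_epsilon_grid(diameter: float, e: float = 0.001,
                       n_eps: int = 33) -> EpsilonGrid:
    if not 0 < e < 1:
        raise ValueError("e must lie strictly between 0 and 1")
    if n_eps < 3:
        raise ValueError("n_eps must be >= 3")
    if not diameter > 0:
        raise ValueError("degenerate manifold: diameter must be positive")
    values = diameter * np.exp(np.linspace(np.log(e), 0.0, n_eps))
    # pin the endpoints exactly
    values[0] = e * diameter
    values[-1] = diameter
    return EpsilonGrid(e=e, n_eps=n_eps, values=values)


@dataclass(frozen=True)
class NeighborIndex:
    """Time indices τ whose u_τ falls in the ε-ball around u_{t+1}.

    The refined variant additionally requires the predecessor u_{τ-1} to lie
    within ε of u_t (the numerical analogue of the predecessor condition
    arising from the one-step time difference between u_{t+1} and v_t).
    """

    t: int
    eps: float
    taus: np.ndarray
    refined: bool = False


def neighbor_index(effect_manifold: Manifold, t: int, eps: float,
                   theiler_E: int = 0, refined: bool = False) -> NeighborIndex:
    """All τ with |u_{t+1} - u_τ| < eps (strict) and |t+1-τ| > E.  0-based."""
    pts = effect_manifold.points
    T0 = pts.shape[0]
    if not 0 <= t + 1 < T0:
        raise ValueError(f"t+1={t + 1} outside manifold range [0, {T0})")
    if eps <= 0:
        raise ValueError("eps must be positive")
    d = np.linalg.norm(pts - pts[t + 1], axis=1)
    sel = (d < eps) & (np.abs(np.arange(T0) - (t + 1)) > theiler_E)
    if refined:
        sel[0] = False
        dprev = np.linalg.norm(pts[:-1] - pts[t], axis=1)
        sel[1:] &= dprev < eps
    return NeighborIndex(t=t, eps=eps, taus=np.nonzero(sel)[0],
                         refined=refined)


def delta_estimate(index: NeighborIndex, cause_manifold: Manifold, t: int,
                   mean_mode: str = "arithmetic",
                   partner_shift: str = "previous") -> float:
    """Estimate δ_t(ε) from the cause-side partner distances.

    Partners are v_{τ-1} (``previous``, the default: the correspondence is
    between u_{t+1} and v_t, one step apart) or v_τ (``same``).  Arithmetic
    mode averages the distances; harmonic mode inverts the mean reciprocal
    distance, so zero distances would make the reciprocal infinite and are
    dropped with a log message.  Returns NaN when no valid partner remains.
    """
    if index.t != t:
        raise ValueError("neighbor index was built for a different t")
    _check_modes(mean_mode, partner_shift)
    pts = cause_manifold.points
    taus = index.taus
    if partner_shift == "previous":
        taus = taus[taus >= 1]
        partners = taus - 1
    else:
        partners = taus
    if partners.size == 0:
        return _UNDEFINED
    dists = np.linalg.norm(pts[partners] - pts[t], axis=1)
    if mean_mode == "harmonic":
        nz = dists > 0
        n_zero = int(dists.size - nz.sum())
        if n_zero:
            logger.info("delta_estimate: dropped %d zero-distance partners "
                        "at t=%d", n_zero, t)
        dists = dists[nz]
        if dists.size == 0:
            return _UNDEFINED
        return float(dists.size / np.sum(1.0 / dists))
    return float(np.mean(dists))


def _check_modes(mean_mode: str, partner_shift: str) -> None:
    if mean_mode not in ("harmonic", "arithmetic"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    if partner_shift not in ("previous", "same"):
        raise ValueError(f"unknown partner_shift {partner_shift!r}")


@dataclass
class DeltaTable:
    """δ_t(ε_j) over usable times t (rows) and the ε-grid (columns).

    ``t_index`` holds the retained 0-based t values, ``fill_mask`` marks
    plateau-filled cells, ``dropped_t`` the times undefined even at ε = D.
    """

    values: np.ndarray
    t_index: np.ndarray
    fill_mask: np.ndarray
    dropped_t: np.ndarray
    n_zero_dropped: int = 0


def _pair_distances(points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Full T0×T0 Euclidean distance matrix, built in row chunks.

    Rows are computed independently, so the chunked result is bit-identical
    to a single cdist call.
    """
    n = points.shape[0]
    out = np.empty((n, n), dtype=float)
    for i in range(0, n, chunk):
        out[i:i + chunk] = cdist(points[i:i + chunk], points)
    return out


def _raw_delta_matrix(d_eff: np.ndarray, d_cau: np.ndarray,
                      eps_values: np.ndarray, theiler_E: int,
                      refined: bool, mean_mode: str, partner_shift: str,
                      min_neighbors: int) -> tuple[np.ndarray, int]:
    """δ_t(ε_j) for t = 0..T0-2 from precomputed distance matrices.

    Per time t the candidate τ are sorted by their effect-side distance key;
    membership in every ε-ball is then a prefix, and the per-ε sums come from
    cumulative sums over that order.  NaN marks undefined cells.
    """
    T0 = d_eff.shape[0]
    n_eps = eps_values.size
    delta = np.full((T0 - 1, n_eps), np.nan)
    idx = np.arange(T0)
    n_zero_dropped = 0
    for t in range(T0 - 1):
        key = d_eff[t + 1].copy()
        valid = np.abs(idx - (t + 1)) > theiler_E
        if partner_shift == "previous" or refined:
            valid[0] = False
        if refined:
            # neighbor must satisfy both ball conditions; the max of the two
            # distances is the radius at which it first qualifies
            key[1:] = np.maximum(key[1:], d_eff[t, :-1])
            key[0] = np.inf
        if partner_shift == "previous":
            cau = np.empty(T0)
            cau[0] = np.inf
            cau[1:] = d_cau[t, :-1]
        else:
            cau = d_cau[t]
        if mean_mode == "harmonic":
            zero = valid & (cau == 0.0)
            nz = int(zero.sum())
            if nz:
                n_zero_dropped += nz
                valid &= ~zero
        key = key[valid]
        cau = cau[valid]
        if key.size == 0:
            continue
        order = np.argsort(key, kind="stable")
        key = key[order]
        weights = 1.0 / cau[order] if mean_mode == "harmonic" else cau[order]
        csum = np.cumsum(weights)
        counts = np.searchsorted(key, eps_values, side="left")
        ok = counts >= max(min_neighbors, 1)
        m = counts[ok]
        if mean_mode == "harmonic":
            delta[t, ok] = m / csum[m - 1]
        else:
            delta[t, ok] = csum[m - 1] / m
    return delta, n_zero_dropped


def _fill_and_drop(delta: np.ndarray) -> DeltaTable:
    """Plateau fill from larger ε, then drop rows undefined at ε = D."""
    n_eps = delta.shape[1]
    fill_mask = np.zeros(delta.shape, dtype=bool)
    for j in range(n_eps - 2, -1, -1):
        nan = np.isnan(delta[:, j])
        delta[nan, j] = delta[nan, j + 1]
        fill_mask[nan, j] = True
    keep = ~np.isnan(delta[:, -1])
    dropped = np.nonzero(~keep)[0]
    if not np.any(keep):
        raise ValueError("no usable time points: every row is undefined")
    return DeltaTable(values=delta[keep], t_index=np.nonzero(keep)[0],
                      fill_mask=fill_mask[keep], dropped_t=dropped)


def delta_table(effect: Manifold, cause: Manifold, grid: EpsilonGrid,
                theiler_E: int = 0, refined: bool = False,
                mean_mode: str = "arithmetic",
                partner_shift: str = "previous",
                min_neighbors: int = 1,
                min_t0: int = 50) -> DeltaTable:
    """Compute the δ table for cause ↪ effect on a common-T0 manifold pair."""
    _check_modes(mean_mode, partner_shift)
    if len(effect) != len(cause):
        raise ValueError("manifolds must share a common T0; truncate first")
    if len(effect) < min_t0:
        raise ValueError(f"common T0={len(effect)} below minimum {min_t0}")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    d_eff = _pair_distances(effect.points)
    d_cau = _pair_distances(cause.points)
    raw, n_zero = _raw_delta_matrix(d_eff, d_cau, grid.values, theiler_E,
                                    refined, mean_mode, partner_shift,
                                    min_neighbors)
    table = _fill_and_drop(raw)
    table.n_zero_dropped = n_zero
    if n_zero:
        logger.info("delta_table: dropped %d zero-distance partners", n_zero)
    if table.dropped_t.size:
        logger.info("delta_table: dropped %d undefined time rows",
                    table.dropped_t.size)
    return table


@dataclass
class ScalingCurve:
    """The (ln ε_j, ⟨δ⟩_j) pairs with the fitted slope over the support H."""

    ln_eps: np.ndarray
    mean_delta: np.ndarray
    increments: np.ndarray
    support: np.ndarray       # 0-based grid indices in H
    slope: float
    intercept: float
    n_dropped: int = 0
    n_filled: int = 0
    n_zero_dropped: int = 0
    effect_name: str = ""
    cause_name: str = ""

    @property
    def direction(self) -> str:
        return f"{self.cause_name} -> {self.effect_name}"


def fit_slope(table: DeltaTable, grid: EpsilonGrid) -> ScalingCurve:
    """Sorted-increment least-squares slope of ⟨δ⟩ against ln ε.

    The ⌊(N_ε+1)/2⌋ largest increments S_j (stable descending sort, smaller
    j first on ties) select the support H = ∪{j, j+1}; ordinary least squares
    over H gives (slope, intercept).
    """
    ln_eps = grid.ln_values
    mean_delta = table.values.mean(axis=0)
    increments = np.diff(mean_delta) / np.diff(ln_eps)
    k = (grid.n_eps + 1) // 2
    top = np.argsort(-increments, kind="stable")[:k]
    support = np.unique(np.concatenate([top, top + 1]))
    if support.size < 3:
        raise ValueError("need at least 3 support points for the slope fit")
    x = ln_eps[support]
    y = mean_delta[support]
    xm = x - x.mean()
    ym = y - y.mean()
    # centered form: a constant curve yields an exactly zero slope
    slope = float(np.dot(xm, ym) / np.dot(xm, xm))
    intercept = float(y.mean() - slope * x.mean())
    return ScalingCurve(
        ln_eps=ln_eps, mean_delta=mean_delta, increments=increments,
        support=support, slope=slope, intercept=intercept,
        n_dropped=int(table.dropped_t.size),
        n_filled=int(table.fill_mask.sum()),
        n_zero_dropped=int(table.n_zero_dropped),
    )


def _curve_from_dists(d_eff: np.ndarray, d_cau: np.ndarray, grid: EpsilonGrid,
                      theiler_E: int, refined: bool, mean_mode: str,
                      partner_shift: str, min_neighbors: int) -> ScalingCurve:
    """Slope pipeline on precomputed distance matrices (surrogates reuse it)."""
    raw, n_zero = _raw_delta_matrix(d_eff, d_cau, grid.values, theiler_E,
                                    refined, mean_mode, partner_shift,
                                    min_neighbors)
    table = _fill_and_drop(raw)
    table.n_zero_dropped = n_zero
    return fit_slope(table, grid)


def default_theiler(effect: Manifold, cause: Manifold) -> int:
    """One embedding window: max over both manifolds of (d-1)·τ."""
    return max(effect.params.window, cause.params.window)


def continuity_slope(effect_series: RawSeries, cause_series: RawSeries,
                     config=None) -> ScalingCurve:
    """End-to-end slope for the direction cause ↪ effect from raw series.

    Embeds both series (parameters from ``config`` or auto-selected),
    truncates to the common T0, builds the ε-grid from the effect manifold
    diameter and runs the δ-table → slope-fit pipeline.  Deterministic for
    fixed inputs and configuration.
    """
    from .config import RunConfig

    cfg = config if config is not None else RunConfig()
    if len(effect_series) != len(cause_series):
        raise ValueError("effect and cause series must have equal length")
    eff_m = delay_embed(effect_series, cfg.embedding_for(effect_series))
    cau_m = delay_embed(cause_series, cfg.embedding_for(cause_series))
    eff_m, cau_m = truncate_pair(eff_m, cau_m)
    theiler = (cfg.theiler if cfg.theiler is not None
               else default_theiler(eff_m, cau_m))
    grid = build_epsilon_grid(eff_m.diameter, cfg.e, cfg.n_eps)
    table = delta_table(eff_m, cau_m, grid, theiler, cfg.refined,
                        cfg.mean_mode, cfg.partner_shift, cfg.min_neighbors,
                        cfg.min_t0)
    curve = fit_slope(table, grid)
    curve.effect_name = effect_series.name
    curve.cause_name = cause_series.name
    return curve
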