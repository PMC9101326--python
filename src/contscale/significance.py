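"""Segment-shuffle surrogate test for the significance of a scaling slope.

The embedded effect and cause sequences (length T0) are each cut into N_G
consecutive segments of equal length ⌊T0/N_G⌋ — any remainder forms a final,
shorter segment — and the segments are independently permuted.  Shuffling
destroys the dynamical continuity that carries the causal signal while
preserving the marginal geometry, so slopes recomputed on shuffled pairs form
a null ensemble.  Pooling the original slope s_0 with the Q surrogate slopes,
the one-sided Gaussian-tail p-value is p = 1 - Φ((s_0 - μ̂)/σ̂); p < α
indicates causation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .config import RunConfig
from .embedding import RawSeries, delay_embed, truncate_pair
from .scaling import (ScalingCurve, _curve_from_dists, _pair_distances,
                      build_epsilon_grid, default_theiler)

__all__ = [
    "SurrogateEnsemble",
    "CausalTestResult",
    "segment_shuffle",
    "segment_permutation",
    "p_value_from_slopes",
    "test_direction",
]


@dataclass
class SurrogateEnsemble:
    """Original slope (index q=0) pooled with Q surrogate slopes."""

    original_slope: float
    surrogate_slopes: np.ndarray
    n_segments: int
    seed: int | None = None
    # per-repetition segment orders, for audit: (effect_order, cause_order)
    segment_orders: list = field(default_factory=list)

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([[self.original_slope], self.surrogate_slopes])


@dataclass
class CausalTestResult:
    """Outcome of one directional test: cause ↪ effect."""

    cause: str
    effect: str
    slope: float
    p_value: float
    alpha: float
    ensemble: SurrogateEnsemble
    curve: ScalingCurve
    config: RunConfig

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    @property
    def direction(self) -> str:
        return f"{self.cause} -> {self.effect}"


def _segment_bounds(n: int, n_segments: int) -> list[tuple[int, int]]:
    """Consecutive segments of length ⌊n/n_segments⌋; remainder is a final,
    shorter segment."""
    if not 1 <= n_segments <= n:
        raise ValueError(f"n_segments={n_segments} must lie in [1, {n}]")
    size = n // n_segments
    bounds = [(i * size, (i + 1) * size) for i in range(n_segments)]
    if n_segments * size < n:
        bounds.append((n_segments * size, n))
    return bounds


def segment_permutation(n: int, n_segments: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Index permutation obtained by shuffling consecutive segments.

    Returns (indices, segment_order): ``indices`` maps shuffled position to
    original position; ``segment_order`` is the drawn permutation of segments.
    """
    bounds = _segment_bounds(n, n_segments)
    order = rng.permutation(len(bounds))
    idx = np.concatenate([np.arange(*bounds[k]) for k in order])
    return idx, order


def segment_shuffle(points: np.ndarray, n_segments: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Segment-shuffled copy of an ordered (vector) sequence."""
    pts = np.asarray(points)
    idx, _ = segment_permutation(pts.shape[0], n_segments, rng)
    return pts[idx]


def p_value_from_slopes(ensemble: SurrogateEnsemble) -> float:
    """One-sided Gaussian-tail p-value of the original slope.

    All Q+1 slopes (the original included) are pooled; μ̂ is their mean and
    σ̂ their sample (n-1 denominator) standard deviation.
    """
    pooled = ensemble.pooled
    if pooled.size < 2:
        raise ValueError("need at least one surrogate slope")
    if not np.all(np.isfinite(pooled)):
        raise ValueError("ensemble contains non-finite slopes")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=1))
    s0 = ensemble.original_slope
    if sigma == 0.0:
        warnings.warn("degenerate surrogate ensemble: zero pooled standard "
                      "deviation", stacklevel=2)
        if s0 == mu:
            return 0.5
        return 0.0 if s0 > mu else 1.0
    return float(norm.sf((s0 - mu) / sigma))


def test_direction(effect_series: RawSeries, cause_series: RawSeries,
                   config: RunConfig | None = None,
                   rng: np.random.Generator | int | None = None) -> CausalTestResult:
    """Slope + surrogate significance for the direction cause ↪ effect.

    Each of the Q repetitions shuffles the embedded effect and cause
    sequences with independent segment permutations and recomputes the slope
    under the same grid-construction rules.  The permuted sequences have the
    same point set, so the surrogate ε-grid coincides with the original one;
    distance matrices are therefore reused by row/column permutation, which
    reproduces the recomputed distances exactly.
    """
    cfg = config if config is not None else RunConfig()
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = cfg.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)

    eff_m = delay_embed(effect_series, cfg.embedding_for(effect_series))
    cau_m = delay_embed(cause_series, cfg.embedding_for(cause_series))
    eff_m, cau_m = truncate_pair(eff_m, cau_m)
    theiler = (cfg.theiler if cfg.theiler is not None
               else default_theiler(eff_m, cau_m))
    grid = build_epsilon_grid(eff_m.diameter, cfg.e, cfg.n_eps)

    d_eff = _pair_distances(eff_m.points)
    d_cau = _pair_distances(cau_m.points)

    def slope_of(de: np.ndarray, dc: np.ndarray) -> ScalingCurve:
        return _curve_from_dists(de, dc, grid, theiler, cfg.refined,
                                 cfg.mean_mode, cfg.partner_shift,
                                 cfg.min_neighbors)

    curve = slope_of(d_eff, d_cau)
    curve.effect_name = effect_series.name
    curve.cause_name = cause_series.name

    t0 = len(eff_m)
    surr = np.empty(cfg.surrogates)
    orders: list = []
    for q in range(cfg.surrogates):
        pe, oe = segment_permutation(t0, cfg.n_segments, rng)
        pc, oc = segment_permutation(t0, cfg.n_segments, rng)
        orders.append((oe, oc))
        surr[q] = slope_of(d_eff[np.ix_(pe, pe)], d_cau[np.ix_(pc, pc)]).slope

    ensemble = SurrogateEnsemble(
        original_slope=curve.slope, surrogate_slopes=surr,
        n_segments=cfg.n_segments, seed=seed, segment_orders=orders)
    p = p_value_from_slopes(ensemble) if cfg.surrogates >= 1 else float("nan")
    return CausalTestResult(
        cause=cause_series.name, effect=effect_series.name,
        slope=curve.slope, p_value=p, alpha=cfg.alpha,
        ensemble=ensemble, curve=curve, config=cfg)
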