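"""Benchmark dynamical systems for exercising the causality pipeline.

Three generators cover the standard test beds:

* a two-species discrete logistic model with directional couplings,
  ``x1' = x1(3.8 - 3.8 x1 - μ12 x2)``, ``x2' = x2(3.7 - 3.7 x2 - μ21 x1)``;
* n-species logistic networks with an arbitrary coupling matrix, with
  ``ring5`` (x_i ↪ x_{i+1 mod 5}) and ``tree5`` (x_j ↪ x_{j+1}, x_{j+3},
  j = 1, 2) presets;
* a pair of Lorenz flows with linear coupling into the x-equation,
  integrated by fixed-step RK4 and observed through y at sampling interval ω.

Everything is exactly reproducible from (spec, seed), and trajectories that
leave the admissible region abort with an error rather than returning NaNs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import RawSeries

__all__ = [
    "LogisticPairSpec",
    "LogisticNetworkSpec",
    "LorenzPairSpec",
    "simulate_logistic_pair",
    "simulate_logistic_network",
    "simulate_lorenz_pair",
    "add_observation_noise",
    "ring5_coupling",
    "tree5_coupling",
]

_DIVERGENCE_BOUND = 10.0


@dataclass(frozen=True)
class LogisticPairSpec:
    """Two coupled logistic species; μ12 is the effect of x2 on x1."""

    mu12: float = 0.0
    mu21: float = 0.0
    r1: float = 3.8
    r2: float = 3.7
    length: int = 5000
    transient: int = 1000
    initial: tuple[float, float] | None = None  # default: uniform(0,1) draws
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu12 < 0 or self.mu21 < 0:
            raise ValueError("couplings must be nonnegative")
        if self.length < 2 or self.transient < 0:
            raise ValueError("invalid length/transient")
        if self.initial is not None and not all(
                0 <= v < 1 for v in self.initial):
            raise ValueError("initial state must lie in [0,1)^2")


_IC_ATTEMPTS = 100  # random-initial-condition redraws before giving up


def simulate_logistic_pair(spec: LogisticPairSpec) -> tuple[RawSeries, RawSeries]:
    """Iterate the coupled two-species map.

    With random initial conditions, a draw whose transient leaves the
    admissible region (possible for strong couplings: the basin of the
    coexistence attractor does not cover all of (0,1)²) is discarded and
    redrawn from the same generator; an explicitly supplied initial state is
    never redrawn.  Divergence after the transient always raises.
    """
    rng = np.random.default_rng(spec.seed)
    attempts = 1 if spec.initial is not None else _IC_ATTEMPTS
    last_error = None
    for _ in range(attempts):
        if spec.initial is not None:
            x1, x2 = spec.initial
        else:
            x1, x2 = rng.uniform(0.0, 1.0, size=2)
        try:
            return _iterate_logistic_pair(spec, x1, x2)
        except RuntimeError as exc:
            last_error = exc
            if "after transient" in str(exc) or spec.initial is not None:
                raise
    raise RuntimeError(
        f"no admissible initial condition found in {attempts} draws: "
        f"{last_error}")


def _iterate_logistic_pair(spec, x1, x2):
    n = spec.transient + spec.length
    out1 = np.empty(spec.length)
    out2 = np.empty(spec.length)
    for t in range(n):
        if abs(x1) > _DIVERGENCE_BOUND or abs(x2) > _DIVERGENCE_BOUND:
            when = "after transient" if t >= spec.transient else "in transient"
            raise RuntimeError(
                "trajectory diverged (inadmissible coupling) "
                f"{when} at step {t}: |x| > {_DIVERGENCE_BOUND}")
        if t >= spec.transient:
            out1[t - spec.transient] = x1
            out2[t - spec.transient] = x2
        x1, x2 = (x1 * (spec.r1 - spec.r1 * x1 - spec.mu12 * x2),
                  x2 * (spec.r2 - spec.r2 * x2 - spec.mu21 * x1))
    return (RawSeries("x1", out1), RawSeries("x2", out2))


def ring5_coupling(weight: float = 0.35) -> np.ndarray:
    """Coupling matrix for x_i ↪ x_{i+1 mod 5}: entry (i+1, i) = weight."""
    mu = np.zeros((5, 5))
    for i in range(5):
        mu[(i + 1) % 5, i] = weight
    return mu


def tree5_coupling(weight: float = 0.35) -> np.ndarray:
    """x_j ↪ x_{j+1}, x_{j+3} for j = 1, 2 (1-based): links 1→2,1→4,2→3,2→5."""
    mu = np.zeros((5, 5))
    for j in (0, 1):  # 0-based sources
        mu[j + 1, j] = weight
        mu[j + 3, j] = weight
    return mu


@dataclass(frozen=True)
class LogisticNetworkSpec:
    """n coupled logistic species; coupling[i, j] = μ_ij, influence of j on i."""

    coupling: np.ndarray
    growth: np.ndarray | None = None  # default: seeded uniform in [3.6, 3.8]
    length: int = 2000
    transient: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.coupling, dtype=float)
        if mu.ndim != 2 or mu.shape[0] != mu.shape[1]:
            raise ValueError("coupling must be a square matrix")
        if np.any(np.diag(mu) != 0):
            raise ValueError("diagonal couplings must be zero")
        if np.any(mu < 0):
            raise ValueError("couplings must be nonnegative")
        object.__setattr__(self, "coupling", mu)
        if self.growth is not None:
            g = np.asarray(self.growth, dtype=float)
            if g.shape != (mu.shape[0],):
                raise ValueError("growth must have one rate per node")
            object.__setattr__(self, "growth", g)

    @classmethod
    def preset(cls, name: str, weight: float = 0.35,
               **kwargs) -> "LogisticNetworkSpec":
        builders = {"ring5": ring5_coupling, "tree5": tree5_coupling}
        if name not in builders:
            raise ValueError(f"unknown preset {name!r}; "
                             f"choose from {sorted(builders)}")
        return cls(coupling=builders[name](weight), **kwargs)

    def links(self) -> list[tuple[int, int]]:
        """Ordered causal links (source, target) with nonzero coupling."""
        tgt, src = np.nonzero(self.coupling)
        return list(zip(src.tolist(), tgt.tolist()))

    def adjacency(self) -> np.ndarray:
        """Truth matrix A[i, j] = 1 when i causes j."""
        return (self.coupling.T > 0).astype(int)


def simulate_logistic_network(spec: LogisticNetworkSpec) -> list[RawSeries]:
    """Iterate the coupled n-species map (random ICs redrawn as in the
    two-species simulator when a transient proves inadmissible)."""
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.coupling.shape[0]
    r = (spec.growth if spec.growth is not None
         else rng.uniform(3.6, 3.8, size=n_nodes))
    last_error = None
    for _ in range(_IC_ATTEMPTS):
        x = rng.uniform(0.0, 1.0, size=n_nodes)
        out = np.empty((spec.length, n_nodes))
        diverged = None
        for t in range(spec.transient + spec.length):
            if np.any(np.abs(x) > _DIVERGENCE_BOUND):
                diverged = t
                break
            if t >= spec.transient:
                out[t - spec.transient] = x
            x = x * (r - r * x - spec.coupling @ x)
        if diverged is None:
            return [RawSeries(f"x{i + 1}", out[:, i])
                    for i in range(n_nodes)]
        if diverged >= spec.transient:
            raise RuntimeError("trajectory diverged (inadmissible coupling) "
                               f"after transient at step {diverged}")
        last_error = diverged
    raise RuntimeError(
        f"no admissible initial condition found in {_IC_ATTEMPTS} draws "
        f"(last divergence in transient at step {last_error})")


@dataclass(frozen=True)
class LorenzPairSpec:
    """Two Lorenz subsystems, linearly coupled through the x-equation.

    ẋ_i = σ_i (y_i - x_i) + μ_ij x_j,  ẏ_i = x_i (ρ_i - z_i) - y_i,
    ż_i = x_i y_i - β_i z_i, with (i, j) = (1, 2) and (2, 1); μ21 couples
    subsystem 1 into subsystem 2.  Observables are y_1, y_2 sampled every ω
    time units after the transient and a shift ν.
    """

    sigma: tuple[float, float] = (10.0, 10.0)
    rho: tuple[float, float] = (28.0, 28.0)
    beta: tuple[float, float] = (8.0 / 3.0, 8.0 / 3.0)
    mu12: float = 0.0
    mu21: float = 0.0
    dt: float = 1e-3
    omega: float = 0.05
    nu: float = 0.0
    length: int = 2000
    transient: float = 50.0
    initial: tuple[float, ...] | None = None  # default: Gaussian around (1,)*6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.omega < self.dt:
            raise ValueError("need 0 < dt <= omega")
        steps = self.omega / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("omega must be an integer multiple of dt")
        if self.length < 2 or self.transient < 0 or self.nu < 0:
            raise ValueError("invalid length/transient/nu")


def _lorenz_deriv(s, p):
    x1, y1, z1, x2, y2, z2 = s
    (s1, s2), (r1, r2), (b1, b2), m12, m21 = p
    return (
        s1 * (y1 - x1) + m12 * x2,
        x1 * (r1 - z1) - y1,
        x1 * y1 - b1 * z1,
        s2 * (y2 - x2) + m21 * x1,
        x2 * (r2 - z2) - y2,
        x2 * y2 - b2 * z2,
    )


def rk4_step(state, dt: float, params):
    """One classical 4th-order Runge-Kutta step of the coupled Lorenz flow."""
    k1 = _lorenz_deriv(state, params)
    s2 = tuple(s + 0.5 * dt * k for s, k in zip(state, k1))
    k2 = _lorenz_deriv(s2, params)
    s3 = tuple(s + 0.5 * dt * k for s, k in zip(state, k2))
    k3 = _lorenz_deriv(s3, params)
    s4 = tuple(s + dt * k for s, k in zip(state, k3))
    k4 = _lorenz_deriv(s4, params)
    return tuple(
        s + dt / 6.0 * (a + 2 * b + 2 * c + d)
        for s, a, b, c, d in zip(state, k1, k2, k3, k4))


def simulate_lorenz_pair(spec: LorenzPairSpec) -> tuple[RawSeries, RawSeries]:
    rng = np.random.default_rng(spec.seed)
    if spec.initial is not None:
        state = tuple(float(v) for v in spec.initial)
        if len(state) != 6:
            raise ValueError("initial state must have 6 components")
    else:
        state = tuple(rng.normal(1.0, 1.0, size=6))
    params = (spec.sigma, spec.rho, spec.beta, spec.mu12, spec.mu21)
    sub = round(spec.omega / spec.dt)
    offset = round((spec.transient + spec.nu) / spec.dt)
    total = offset + (spec.length - 1) * sub + 1
    y1 = np.empty(spec.length)
    y2 = np.empty(spec.length)
    k = 0
    for step in range(total):
        if step >= offset and (step - offset) % sub == 0:
            if not all(math.isfinite(v) for v in state):
                raise RuntimeError(f"non-finite Lorenz state at step {step}")
            y1[k] = state[1]
            y2[k] = state[4]
            k += 1
        if step < total - 1:
            state = rk4_step(state, spec.dt, params)
    return (RawSeries("y1", y1, sample_step=spec.omega),
            RawSeries("y2", y2, sample_step=spec.omega))


def add_observation_noise(series: RawSeries, level: float,
                          kind: str = "additive-gaussian",
                          rng: np.random.Generator | int | None = None) -> RawSeries:
    """Add iid Gaussian noise with SD = level × sample SD of the series."""
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    if kind != "additive-gaussian":
        raise ValueError(f"unknown noise kind {kind!r}")
    if level == 0:
        return series
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sd = float(np.std(series.values)) * level
    noisy = series.values + rng.normal(0.0, sd, size=len(series))
    return RawSeries(series.name, noisy, series.sample_step)
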