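"""Run configuration: every tunable of the pipeline with validated defaults.

The defaults are the study conditions used throughout: ε-grid anchor
e = 0.001 with N_ε = 33 radii, arithmetic δ averaging against the
previous-time partner v_{τ-1} (a harmonic mean is available as
``mean_mode="harmonic"``), Theiler exclusion of one embedding window,
Q = 20 surrogates over N_G = 25 segments, and a significance level α = 0.05.

A flat key–value file (``key = value`` per line, ``#`` comments) can override
any field; per-series embedding overrides use ``dim.<name>`` / ``lag.<name>``.
Unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

from .embedding import EmbeddingParams, RawSeries, select_dim, select_lag

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # scaling-curve parameters
    e: float = 0.001
    n_eps: int = 33
    theiler: int | None = None        # None = auto: one embedding window
    min_neighbors: int = 1
    mean_mode: str = "arithmetic"     # or "harmonic"
    partner_shift: str = "previous"   # or "same"
    refined: bool = False
    min_t0: int = 50
    # surrogate test
    surrogates: int = 20              # Q
    n_segments: int = 25              # N_G
    alpha: float = 0.05
    seed: int | None = None
    # embedding selection
    max_lag: int = 50
    max_dim: int = 10
    n_bins: int = 16
    fnn_rtol: float = 10.0
    fnn_threshold: float = 0.01
    # per-series overrides: name -> {"dim": d, "lag": tau}
    embedding: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.e < 1:
            raise ValueError("e must lie strictly in (0, 1)")
        if self.n_eps < 3:
            raise ValueError("n_eps must be >= 3")
        if self.theiler is not None and self.theiler < 0:
            raise ValueError("theiler must be nonnegative")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if self.mean_mode not in ("harmonic", "arithmetic"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")
        if self.partner_shift not in ("previous", "same"):
            raise ValueError(f"unknown partner_shift {self.partner_shift!r}")
        if self.surrogates < 0:
            raise ValueError("surrogates must be >= 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")

    # -- embedding helpers ------------------------------------------------

    def embedding_for(self, series: RawSeries) -> EmbeddingParams:
        """Per-series override if present, otherwise MI-lag + FNN-dimension."""
        ov = self.embedding.get(series.name, {})
        if "dim" in ov and "lag" in ov:
            return EmbeddingParams(dim=int(ov["dim"]), lag=int(ov["lag"]))
        lag = (int(ov["lag"]) if "lag" in ov
               else select_lag(series, min(self.max_lag, len(series) // 2 - 1),
                               self.n_bins))
        dim = (int(ov["dim"]) if "dim" in ov
               else select_dim(series, lag, self.max_dim, self.fnn_rtol,
                               self.fnn_threshold))
        return EmbeddingParams(dim=dim, lag=lag)

    def with_embedding(self, name: str, dim: int, lag: int) -> "RunConfig":
        emb = dict(self.embedding)
        emb[name] = {"dim": dim, "lag": lag}
        return replace(self, embedding=emb)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` file (JSON-typed values)."""
        data: dict = {}
        emb: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                try:
                    value = json.loads(raw)
                except json.JSONDecodeError:
                    value = raw
                if key.startswith(("dim.", "lag.")):
                    which, name = key.split(".", 1)
                    emb.setdefault(name, {})[which] = int(value)
                else:
                    data[key] = value
        if emb:
            data["embedding"] = emb
        return cls.from_dict(data)
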