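"""Model/Results front end for the continuity-scaling causality test.

``ContinuityScaling`` is built from two series (one ordered causal
direction); ``fit()`` runs the slope estimate and surrogate test and returns
a results object carrying the estimate, its null ensemble, diagnostics and a
``summary()`` table.  ``CausalNetworkModel`` does the same for every ordered
pair of a multivariate table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .embedding import RawSeries
from .network import CausalNetwork, RocResult, pairwise_network, roc_evaluate
from .significance import CausalTestResult, test_direction

__all__ = ["ContinuityScaling", "ContinuityScalingResults",
           "CausalNetworkModel", "CausalNetworkResults"]


def _as_series(obj, name: str) -> RawSeries:
    if isinstance(obj, RawSeries):
        return obj
    return RawSeries(name, np.asarray(obj, dtype=float))


class ContinuityScaling:
    """Directional causality model: does ``cause`` drive ``effect``?

    Parameters
    ----------
    effect, cause : RawSeries or array-like
        The two observables; the test is for the direction cause ↪ effect.
    config : RunConfig, optional
        Pipeline settings; keyword overrides (e.g. ``surrogates=40``,
        ``mean_mode="arithmetic"``) are applied on top.
    """

    def __init__(self, effect, cause, config: RunConfig | None = None,
                 **overrides) -> None:
        base = (config if config is not None else RunConfig()).to_dict()
        base.update(overrides)
        self.config = RunConfig.from_dict(base)
        self.effect = _as_series(effect, "effect")
        self.cause = _as_series(cause, "cause")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cause: str, effect: str,
                       config: RunConfig | None = None,
                       **overrides) -> "ContinuityScaling":
        for col in (cause, effect):
            if col not in df.columns:
                raise KeyError(f"column {col!r} not in dataframe")
        return cls(RawSeries(effect, df[effect].to_numpy(dtype=float)),
                   RawSeries(cause, df[cause].to_numpy(dtype=float)),
                   config=config, **overrides)

    def fit(self, seed: int | None = None) -> "ContinuityScalingResults":
        rng = seed if seed is not None else self.config.seed
        res = test_direction(self.effect, self.cause, self.config, rng)
        return ContinuityScalingResults(self, res)


class ContinuityScalingResults:
    """Fitted slope, surrogate ensemble and verdict for one direction."""

    def __init__(self, model: ContinuityScaling,
                 result: CausalTestResult) -> None:
        self.model = model
        self._result = result

    # estimate and uncertainty ------------------------------------------
    @property
    def slope(self) -> float:
        return self._result.slope

    @property
    def p_value(self) -> float:
        return self._result.p_value

    @property
    def significant(self) -> bool:
        return self._result.significant

    @property
    def curve(self):
        return self._result.curve

    @property
    def ensemble(self):
        return self._result.ensemble

    @property
    def result(self) -> CausalTestResult:
        return self._result

    def null_mean(self) -> float:
        return float(self._result.ensemble.pooled.mean())

    def null_std(self) -> float:
        return float(self._result.ensemble.pooled.std(ddof=1))

    def summary(self) -> str:
        r = self._result
        c = r.curve
        lines = [
            "Continuity-scaling causality test",
            "=" * 44,
            f"direction        {r.direction}",
            f"slope            {r.slope: .6f}",
            f"intercept        {c.intercept: .6f}",
            f"surrogates (Q)   {r.ensemble.surrogate_slopes.size:d}"
            f"   segments (N_G) {r.ensemble.n_segments:d}",
            f"null mean/std    {self.null_mean(): .6f} / "
            f"{self.null_std(): .6f}",
            f"p-value          {r.p_value: .4f}   (alpha {r.alpha:g})",
            f"verdict          {'causal' if r.significant else 'not significant'}",
            "-" * 44,
            f"support points   {c.support.size:d} of {c.ln_eps.size:d}",
            f"dropped times    {c.n_dropped:d}",
            f"plateau fills    {c.n_filled:d}",
            f"zero-dist drops  {c.n_zero_dropped:d}",
        ]
        return "\n".join(lines)

    def plot_scaling(self, ax=None):
        """⟨δ⟩ vs ln ε with the fitted line over the support set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c.ln_eps, c.mean_delta, "o-", ms=3, label=r"$\langle\delta\rangle$")
        xs = c.ln_eps[c.support]
        ax.plot(xs, self.slope * xs + c.intercept, "r--",
                label=f"slope {self.slope:.4f}")
        ax.set_xlabel(r"$\ln\,\varepsilon$")
        ax.set_ylabel(r"$\langle\delta\rangle$")
        ax.set_title(self._result.direction)
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        from .io import result_to_dict
        return result_to_dict(self._result)


class CausalNetworkModel:
    """All-pairs directional causality over a multivariate table."""

    def __init__(self, data, config: RunConfig | None = None,
                 **overrides) -> None:
        base = (config if config is not None else RunConfig()).to_dict()
        base.update(overrides)
        self.config = RunConfig.from_dict(base)
        if isinstance(data, pd.DataFrame):
            self.series = [RawSeries(str(c), data[c].to_numpy(dtype=float))
                           for c in data.columns]
        else:
            self.series = [_as_series(s, f"v{i + 1}")
                           for i, s in enumerate(data)]

    def fit(self, seed: int | None = None,
            surrogates: int | None = None) -> "CausalNetworkResults":
        net = pairwise_network(self.series, self.config, seed=seed,
                               surrogates=surrogates)
        return CausalNetworkResults(self, net)


class CausalNetworkResults:
    """Slope/p matrices, adjacency and ROC evaluation for a fitted network."""

    def __init__(self, model: CausalNetworkModel, net: CausalNetwork) -> None:
        self.model = model
        self.network = net

    @property
    def labels(self) -> list[str]:
        return self.network.labels

    @property
    def slope_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.network.slope_matrix, index=self.labels,
                            columns=self.labels)

    @property
    def p_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.network.p_matrix, index=self.labels,
                            columns=self.labels)

    @property
    def adjacency(self) -> pd.DataFrame:
        return pd.DataFrame(self.network.adjacency, index=self.labels,
                            columns=self.labels)

    def edge_list(self) -> pd.DataFrame:
        return self.network.edge_list()

    def roc(self, truth, score: str = "slope") -> RocResult:
        """Evaluate against a known adjacency, ranking by slope or 1-p."""
        truth = np.asarray(truth)
        if score == "slope":
            scores = self.network.slope_matrix
        elif score == "p":
            scores = 1.0 - self.network.p_matrix
        else:
            raise ValueError("score must be 'slope' or 'p'")
        masked = scores.copy()
        np.fill_diagonal(masked, 0.0)
        return roc_evaluate(masked, truth)

    def summary(self) -> str:
        return self.network.summary()

    def save(self, path, format: str = "both"):
        from .network import export_network
        return export_network(self.network, path, format)
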