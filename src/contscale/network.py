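"""Pairwise causal networks and truth-based ROC evaluation.

Every ordered pair of variables is tested in both directions; the slope and
p-value matrices form a directed network whose adjacency is ``p < α``.  When
a ground-truth adjacency is known, ranking the ordered pairs by slope (or by
1 - p) gives an ROC curve and its AUROC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .config import RunConfig
from .embedding import RawSeries
from .scaling import continuity_slope
from .significance import test_direction

__all__ = [
    "CausalNetwork",
    "RocResult",
    "pairwise_network",
    "roc_evaluate",
    "export_network",
    "load_network",
]

logger = logging.getLogger(__name__)


@dataclass
class CausalNetwork:
    """Slope and p matrices over all ordered pairs; entry (i, j) is i ↪ j."""

    labels: list[str]
    slope_matrix: np.ndarray
    p_matrix: np.ndarray
    alpha: float
    config: RunConfig | None = None
    seed: int | None = None
    failures: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Significant links: p < α, diagonal masked to 0."""
        with np.errstate(invalid="ignore"):
            adj = (self.p_matrix < self.alpha).astype(int)
        np.fill_diagonal(adj, 0)
        return adj

    def summary(self) -> str:
        edges = self.edge_list()
        sig = edges[edges.significant]
        lines = [
            "Pairwise continuity-scaling causal network",
            "=" * 46,
            f"variables        {self.n}  ({', '.join(self.labels)})",
            f"ordered pairs    {len(edges)}",
            f"significant      {len(sig)} at alpha {self.alpha:g}",
        ]
        for _, row in sig.iterrows():
            lines.append(f"  {row.cause} -> {row.effect}   "
                         f"slope {row.slope: .4f}   p {row.p:.4f}")
        if self.failures:
            lines.append(f"failed pairs     {len(self.failures)}")
        return "\n".join(lines)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, ci in enumerate(self.labels):
            for j, cj in enumerate(self.labels):
                if i == j:
                    continue
                p = self.p_matrix[i, j]
                rows.append({
                    "cause": ci, "effect": cj,
                    "slope": self.slope_matrix[i, j],
                    "p": p,
                    "significant": bool(p < self.alpha)
                    if np.isfinite(p) else False,
                })
        return pd.DataFrame(rows,
                            columns=["cause", "effect", "slope", "p",
                                     "significant"])


def pairwise_network(series: list[RawSeries], config: RunConfig | None = None,
                     seed: int | None = None,
                     surrogates: int | None = None) -> CausalNetwork:
    """Directional test for every ordered variable pair.

    Embedding parameters are selected once per variable and reused; per-pair
    seeds are spawned deterministically from the master seed.  With
    ``surrogates=0`` only slopes are computed (p entries NaN) — useful when
    ranking by slope, e.g. for ROC evaluation.  Per-pair failures are
    recorded and masked as NaN, not fatal.
    """
    cfg = config if config is not None else RunConfig()
    if len(series) < 2:
        raise ValueError("need at least 2 variables")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError("all series must have equal length")
    labels = [s.name for s in series]
    if len(set(labels)) != len(labels):
        raise ValueError("series names must be unique")
    if surrogates is not None:
        from dataclasses import replace
        cfg = replace(cfg, surrogates=surrogates)

    # select embedding once per variable, freeze as overrides
    for s in series:
        params = cfg.embedding_for(s)
        cfg = cfg.with_embedding(s.name, params.dim, params.lag)

    n = len(series)
    slope = np.full((n, n), np.nan)
    pmat = np.full((n, n), np.nan)
    failures: dict = {}
    master = seed if seed is not None else cfg.seed
    pair_seeds = np.random.SeedSequence(master).spawn(n * n)
    for i in range(n):          # cause
        for j in range(n):      # effect
            if i == j:
                continue
            rng = np.random.default_rng(pair_seeds[i * n + j])
            try:
                if cfg.surrogates >= 1:
                    res = test_direction(series[j], series[i], cfg, rng)
                    slope[i, j] = res.slope
                    pmat[i, j] = res.p_value
                else:
                    slope[i, j] = continuity_slope(series[j], series[i],
                                                   cfg).slope
            except Exception as exc:  # mask, don't abort the whole scan
                failures[(labels[i], labels[j])] = str(exc)
                logger.warning("pair %s -> %s failed: %s",
                               labels[i], labels[j], exc)
    return CausalNetwork(labels=labels, slope_matrix=slope, p_matrix=pmat,
                         alpha=cfg.alpha, config=cfg, seed=master,
                         failures=failures)


@dataclass
class RocResult:
    """Threshold sweep over off-diagonal scores against a truth adjacency."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def roc_evaluate(score_matrix: np.ndarray, truth: np.ndarray) -> RocResult:
    """ROC/AUROC of ranking ordered pairs by score (higher = more causal).

    The diagonal is ignored; AUROC uses the midrank convention for ties
    (Mann-Whitney).  All-positive or all-negative truth is an error.
    """
    score = np.asarray(score_matrix, dtype=float)
    t = np.asarray(truth)
    if score.shape != t.shape or score.ndim != 2 or score.shape[0] != score.shape[1]:
        raise ValueError("score and truth must be square matrices of equal shape")
    off = ~np.eye(score.shape[0], dtype=bool)
    y = t[off].astype(int)
    s = score[off]
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite entries")
    if y.min() == y.max():
        raise ValueError("AUROC undefined: truth is all-positive or all-negative")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auroc=float(roc_auc_score(y, s)))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def export_network(net: CausalNetwork, path: str | Path,
                   format: str = "both") -> list[Path]:
    """Write the edge list as TSV and/or the full network as JSON.

    ``path`` is the stem; ``<stem>.edges.tsv`` and ``<stem>.json`` are
    produced.  The JSON round-trips losslessly via :func:`load_network`.
    """
    if format not in ("tsv", "json", "both"):
        raise ValueError(f"unknown format {format!r}")
    stem = Path(path)
    written: list[Path] = []
    try:
        if format in ("tsv", "both"):
            p = stem.with_suffix(".edges.tsv")
            net.edge_list().to_csv(p, sep="\t", index=False)
            written.append(p)
        if format in ("json", "both"):
            p = stem.with_suffix(".json")
            doc = {
                "labels": net.labels,
                "slope_matrix": _jsonify(net.slope_matrix),
                "p_matrix": _jsonify(net.p_matrix),
                "alpha": net.alpha,
                "seed": net.seed,
                "config": net.config.to_dict() if net.config else None,
                "failures": {f"{a}->{b}": m
                             for (a, b), m in net.failures.items()},
            }
            p.write_text(json.dumps(doc, indent=2) + "\n")
            written.append(p)
    except OSError as exc:
        raise OSError(f"failed writing network to {stem}: {exc}") from exc
    return written


def load_network(path: str | Path) -> CausalNetwork:
    """Read a network JSON written by :func:`export_network`."""
    doc = json.loads(Path(path).read_text())

    def arr(rows):
        return np.array([[np.nan if v is None else v for v in row]
                         for row in rows], dtype=float)

    cfg = (RunConfig.from_dict({**doc["config"],
                                "embedding": doc["config"]["embedding"]})
           if doc.get("config") else None)
    failures = {tuple(k.split("->", 1)): v
                for k, v in doc.get("failures", {}).items()}
    return CausalNetwork(labels=list(doc["labels"]),
                         slope_matrix=arr(doc["slope_matrix"]),
                         p_matrix=arr(doc["p_matrix"]),
                         alpha=float(doc["alpha"]),
                         config=cfg, seed=doc.get("seed"),
                         failures=failures)
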