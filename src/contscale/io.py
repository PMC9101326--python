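"""Reading and writing delimited series tables and JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .embedding import RawSeries
from .significance import CausalTestResult

__all__ = [
    "read_series_table",
    "write_series_table",
    "series_to_frame",
    "result_to_dict",
    "write_result_json",
]


def _looks_numeric(name: str) -> bool:
    try:
        float(name)
        return True
    except ValueError:
        return False


def read_series_table(path: str | Path, delimiter: str | None = None,
                      time_column: bool | str = False) -> list[RawSeries]:
    """Parse a delimited table into one named series per column.

    Header names are taken from the first row when it is non-numeric,
    otherwise columns are named v1…vn.  With ``time_column`` the first (or
    the named) column is checked for uniform spacing and dropped.  Missing
    or non-numeric cells are rejected with row/column context.
    """
    path = Path(path)
    sep = delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = any(isinstance(v, str) and not _looks_numeric(v)
                     for v in head.iloc[0])
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if not has_header:
        df.columns = [f"v{i + 1}" for i in range(df.shape[1])]

    if time_column:
        col = time_column if isinstance(time_column, str) else df.columns[0]
        if col not in df.columns:
            raise ValueError(f"{path}: no time column named {col!r}")
        tv = pd.to_numeric(df[col], errors="coerce").to_numpy()
        steps = np.diff(tv)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9,
                                          atol=1e-12):
            raise ValueError(f"{path}: time column {col!r} is not uniformly "
                             "spaced")
        df = df.drop(columns=[col])

    series = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: missing or non-numeric cell in column {col!r}, "
                f"row {int(bad[0]) + 1 + int(has_header)}")
        series.append(RawSeries(str(col), vals.to_numpy(dtype=float)))
    if not series:
        raise ValueError(f"{path}: no numeric columns found")
    return series


def series_to_frame(series: list[RawSeries]) -> pd.DataFrame:
    return pd.DataFrame({s.name: s.values for s in series})


def write_series_table(series: list[RawSeries], path: str | Path,
                       delimiter: str = ",") -> None:
    series_to_frame(series).to_csv(path, sep=delimiter, index=False)


def result_to_dict(res: CausalTestResult) -> dict:
    """Full machine-readable record of one directional test."""
    curve = res.curve
    return {
        "library": {"name": "contscale", "version": __version__},
        "direction": {"cause": res.cause, "effect": res.effect},
        "slope": res.slope,
        "p_value": res.p_value,
        "alpha": res.alpha,
        "significant": res.significant,
        "curve": {
            "ln_eps": curve.ln_eps.tolist(),
            "mean_delta": curve.mean_delta.tolist(),
            "increments": curve.increments.tolist(),
            "support": curve.support.tolist(),
            "intercept": curve.intercept,
        },
        "diagnostics": {
            "dropped_time_points": curve.n_dropped,
            "plateau_filled_cells": curve.n_filled,
            "zero_distance_exclusions": curve.n_zero_dropped,
        },
        "ensemble": {
            "original_slope": res.ensemble.original_slope,
            "surrogate_slopes": res.ensemble.surrogate_slopes.tolist(),
            "n_segments": res.ensemble.n_segments,
            "seed": res.ensemble.seed,
            "segment_orders": [
                [oe.tolist(), oc.tolist()]
                for oe, oc in res.ensemble.segment_orders
            ],
        },
        "config": res.config.to_dict(),
    }


def write_result_json(res: CausalTestResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(res), indent=2) + "\n")
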