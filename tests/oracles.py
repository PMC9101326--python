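"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal, loop-based translations of the
procedure definitions — no shared code with the package internals — so the
vectorized implementations can be checked against them exactly.
"""

from __future__ import annotations

import math


def euclid(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_diameter(points) -> float:
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            best = max(best, euclid(points[i], points[j]))
    return best


def brute_mi(x, y, n_bins, lo, hi):
    """Histogram mutual information by explicit binning and summation."""
    width = (hi - lo) / n_bins

    def bin_of(v):
        b = int((v - lo) / width)
        return min(b, n_bins - 1)

    n = len(x)
    joint = [[0] * n_bins for _ in range(n_bins)]
    for xv, yv in zip(x, y):
        joint[bin_of(xv)][bin_of(yv)] += 1
    px = [sum(row) / n for row in joint]
    py = [sum(joint[i][j] for i in range(n_bins)) / n for j in range(n_bins)]
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            p = joint[i][j] / n
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi


def brute_fnn_fraction(values, dim, lag, rtol):
    """FNN via exhaustive nearest-neighbor search at dimension ``dim``."""
    T = len(values)
    n = T - dim * lag
    pts = [[values[t + i * lag] for i in range(dim)] for t in range(n)]
    n_false = 0
    n_counted = 0
    for t in range(n):
        best, best_j = float("inf"), -1
        for j in range(n):
            if j == t:
                continue
            d = euclid(pts[t], pts[j])
            if d < best:
                best, best_j = d, j
        if best == 0.0:
            continue
        extra = abs(values[t + dim * lag] - values[best_j + dim * lag])
        n_counted += 1
        if extra / best > rtol:
            n_false += 1
    return n_false / n_counted if n_counted else 0.0


def brute_neighbors(eff_pts, t, eps, theiler, refined):
    """All 0-based τ with |u_{t+1}-u_τ| < eps, |t+1-τ| > E (strict <)."""
    out = []
    for tau in range(len(eff_pts)):
        if abs((t + 1) - tau) <= theiler:
            continue
        if euclid(eff_pts[t + 1], eff_pts[tau]) >= eps:
            continue
        if refined:
            if tau < 1:
                continue
            if euclid(eff_pts[t], eff_pts[tau - 1]) >= eps:
                continue
        out.append(tau)
    return out


def brute_delta(eff_pts, cau_pts, t, eps, theiler, refined, mean_mode,
                partner_shift, min_neighbors):
    """One δ cell; None when undefined."""
    dists = []
    for tau in brute_neighbors(eff_pts, t, eps, theiler, refined):
        p = tau - 1 if partner_shift == "previous" else tau
        if p < 0:
            continue
        d = euclid(cau_pts[t], cau_pts[p])
        if mean_mode == "harmonic" and d == 0.0:
            continue
        dists.append(d)
    if len(dists) < max(min_neighbors, 1):
        return None
    if mean_mode == "harmonic":
        return len(dists) / sum(1.0 / d for d in dists)
    return sum(dists) / len(dists)


def brute_delta_table(eff_pts, cau_pts, eps_values, theiler, refined,
                      mean_mode, partner_shift, min_neighbors):
    """Full table with plateau fill and row dropping.

    Returns (rows, kept_t, dropped_t, fill_flags) where ``rows[i][j]`` is the
    filled δ value for kept time kept_t[i].
    """
    T0 = len(eff_pts)
    n_eps = len(eps_values)
    table = [[brute_delta(eff_pts, cau_pts, t, eps_values[j], theiler,
                          refined, mean_mode, partner_shift, min_neighbors)
              for j in range(n_eps)] for t in range(T0 - 1)]
    fill = [[False] * n_eps for _ in range(T0 - 1)]
    for row, frow in zip(table, fill):
        for j in range(n_eps - 2, -1, -1):
            if row[j] is None:
                row[j] = row[j + 1]
                frow[j] = True
    kept, dropped = [], []
    for t, row in enumerate(table):
        (kept if row[n_eps - 1] is not None else dropped).append(t)
    rows = [table[t] for t in kept]
    flags = [fill[t] for t in kept]
    return rows, kept, dropped, flags


def brute_fit(mean_delta, ln_eps):
    """Literal sorted-increment slope procedure.

    Increments S_j, stable descending sort (smaller j first on ties), keep
    the ⌊(N_ε+1)/2⌋ largest, support H = ∪{j, j+1}, closed-form least
    squares over H.  Returns (slope, intercept, H as sorted 0-based list).
    """
    n_eps = len(ln_eps)
    S = [(mean_delta[j + 1] - mean_delta[j]) / (ln_eps[j + 1] - ln_eps[j])
         for j in range(n_eps - 1)]
    k = (n_eps + 1) // 2
    order = sorted(range(len(S)), key=lambda j: (-S[j], j))[:k]
    H = sorted({j for j in order} | {j + 1 for j in order})
    xs = [ln_eps[j] for j in H]
    ys = [mean_delta[j] for j in H]
    xm = sum(xs) / len(xs)
    ym = sum(ys) / len(ys)
    sxx = sum((x - xm) ** 2 for x in xs)
    sxy = sum((x - xm) * (y - ym) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return slope, ym - slope * xm, H


def brute_slope_pipeline(eff_series, cau_series, dim, lag, e, n_eps,
                         theiler, refined=False, mean_mode="arithmetic",
                         partner_shift="previous", min_neighbors=1):
    """End-to-end: embed, truncate, grid, table, fit.  Pure loops."""
    def embed(vals):
        T0 = len(vals) - (dim - 1) * lag
        return [[vals[t + i * lag] for i in range(dim)] for t in range(T0)]

    eff_pts = embed(list(eff_series))
    cau_pts = embed(list(cau_series))
    T0 = min(len(eff_pts), len(cau_pts))
    eff_pts, cau_pts = eff_pts[:T0], cau_pts[:T0]
    D = brute_diameter(eff_pts)
    ln_e1, ln_eN = math.log(e * D), math.log(D)
    ln_eps = [ln_e1 + (ln_eN - ln_e1) * j / (n_eps - 1) for j in range(n_eps)]
    eps_values = [math.exp(v) for v in ln_eps]
    eps_values[0], eps_values[-1] = e * D, D
    rows, kept, dropped, _ = brute_delta_table(
        eff_pts, cau_pts, eps_values, theiler, refined, mean_mode,
        partner_shift, min_neighbors)
    mean_delta = [sum(r[j] for r in rows) / len(rows) for j in range(n_eps)]
    ln_eps = [math.log(v) for v in eps_values]
    slope, intercept, H = brute_fit(mean_delta, ln_eps)
    return slope, intercept, H, mean_delta


def brute_auroc(scores, labels):
    """Mann-Whitney pair counting with midrank tie handling."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
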