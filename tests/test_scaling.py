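"""Scaling core: ε-grid, neighbor sets, δ estimates, slope fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contscale import (EmbeddingParams, Manifold, RawSeries, RunConfig,
                       build_epsilon_grid, continuity_slope, delta_estimate,
                       delta_table, fit_slope, neighbor_index)
from contscale.scaling import DeltaTable, _raw_delta_matrix, _pair_distances

from oracles import (brute_delta, brute_delta_table, brute_fit,
                     brute_neighbors, brute_slope_pipeline)

MODES = [("arithmetic", "previous"), ("arithmetic", "same"),
         ("harmonic", "previous"), ("harmonic", "same")]


def toy_manifold(rng, n, dim=2):
    return Manifold(rng.normal(size=(n, dim)), EmbeddingParams(dim, 1), "toy")


class TestEpsilonGrid:
    def test_closed_form_three_points(self):
        g = build_epsilon_grid(1.0, e=0.01, n_eps=3)
        assert g.values == pytest.approx([0.01, 0.1, 1.0], rel=1e-12)

    def test_default_endpoints(self):
        g = build_epsilon_grid(7.3)
        assert g.n_eps == 33 and g.e == 0.001
        assert g.values[0] == pytest.approx(0.001 * 7.3, rel=1e-12)
        assert g.values[-1] == pytest.approx(7.3, rel=1e-12)

    @pytest.mark.parametrize("d,e,n", [(1.0, 0.001, 33), (5.2, 0.03, 7),
                                       (0.04, 0.5, 12)])
    def test_log_spacing_uniform(self, d, e, n):
        diffs = np.diff(np.log(build_epsilon_grid(d, e, n).values))
        assert np.all(np.abs(diffs - diffs[0]) < 1e-12)
        assert diffs[0] == pytest.approx(np.log(1 / e) / (n - 1), rel=1e-12)

    def test_constant_ratio(self):
        g = build_epsilon_grid(2.0, e=0.001, n_eps=33)
        ratios = g.values[1:] / g.values[:-1]
        assert ratios == pytest.approx((1 / 0.001) ** (1 / 32), rel=1e-10)

    @pytest.mark.parametrize("bad", [{"diameter": 0.0}, {"diameter": -1.0},
                                     {"e": 1.5}, {"e": 0.0}, {"n_eps": 2}])
    def test_invalid_inputs(self, bad):
        kwargs = {"diameter": 1.0, "e": 0.01, "n_eps": 5, **bad}
        with pytest.raises(ValueError):
            build_epsilon_grid(**kwargs)


class TestNeighborIndex:
    def test_huge_eps_includes_everything_but_theiler(self, rng):
        m = toy_manifold(rng, 30)
        idx = neighbor_index(m, t=4, eps=1e9, theiler_E=0)
        assert set(idx.taus) == set(range(30)) - {5}

    def test_tiny_eps_empty(self, rng):
        m = toy_manifold(rng, 30)
        assert neighbor_index(m, t=3, eps=1e-12).taus.size == 0

    def test_six_point_hand_instance(self):
        pts = np.array([[0.0], [0.1], [1.0], [0.12], [0.9], [0.11]])
        m = Manifold(pts, EmbeddingParams(1, 1), "h")
        idx = neighbor_index(m, t=0, eps=0.05, theiler_E=1)
        # ball around u_1=0.1: u_3=0.12, u_5=0.11 qualify; u_0 Theiler-excluded
        assert idx.taus.tolist() == [3, 5]
        assert idx.taus.tolist() == brute_neighbors(
            pts.tolist(), 0, 0.05, 1, False)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.booleans(), st.integers(0, 3))
    def test_matches_brute_force(self, seed, refined, theiler):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        m = toy_manifold(rng, n)
        t = int(rng.integers(0, n - 1))
        eps = float(rng.uniform(0.1, 3.0))
        idx = neighbor_index(m, t, eps, theiler, refined)
        assert idx.taus.tolist() == brute_neighbors(
            m.points.tolist(), t, eps, theiler, refined)


class TestDeltaEstimate:
    def test_single_neighbor_both_modes(self, rng):
        eff = toy_manifold(rng, 20)
        cau = toy_manifold(rng, 20)
        idx = neighbor_index(eff, 2, 1e9)
        one = type(idx)(t=2, eps=1.0, taus=np.array([7]))
        d = float(np.linalg.norm(cau.points[6] - cau.points[2]))
        for mode in ("harmonic", "arithmetic"):
            assert delta_estimate(one, cau, 2, mode, "previous") == \
                pytest.approx(d)

    def test_empty_index_undefined(self, rng):
        cau = toy_manifold(rng, 10)
        from contscale import NeighborIndex
        empty = NeighborIndex(t=1, eps=0.1, taus=np.array([], dtype=int))
        assert np.isnan(delta_estimate(empty, cau, 1))

    def test_hand_computed_means(self):
        """Partner distances (1,2,4): harmonic 12/7, arithmetic 7/3."""
        from contscale import NeighborIndex
        pts = np.array([[0.0], [1.0], [2.0], [4.0], [99.0]])
        cau = Manifold(pts, EmbeddingParams(1, 1), "c")
        idx = NeighborIndex(t=0, eps=1.0, taus=np.array([2, 3, 4]))
        assert delta_estimate(idx, cau, 0, "harmonic", "previous") == \
            pytest.approx(12 / 7)
        assert delta_estimate(idx, cau, 0, "arithmetic", "previous") == \
            pytest.approx(7 / 3)

    def test_zero_distance_dropped_in_harmonic(self):
        from contscale import NeighborIndex
        pts = np.array([[0.0], [0.0], [3.0]])
        cau = Manifold(pts, EmbeddingParams(1, 1), "c")
        idx = NeighborIndex(t=0, eps=1.0, taus=np.array([2, 1]))
        # previous-shift partners of taus (2, 1) are (1, 0); both coincide
        # with v_0, so every harmonic term would be an infinite reciprocal
        assert np.isnan(delta_estimate(idx, cau, 0, "harmonic", "previous"))
        # arithmetic keeps zero distances
        assert delta_estimate(idx, cau, 0, "arithmetic", "previous") == 0.0


class TestDeltaTable:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1),
           st.sampled_from(MODES), st.booleans())
    def test_matches_brute_force(self, seed, modes, refined):
        mean_mode, partner_shift = modes
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 60))
        eff = toy_manifold(rng, n)
        cau = toy_manifold(rng, n)
        grid = build_epsilon_grid(eff.diameter, e=0.05, n_eps=7)
        try:
            table = delta_table(eff, cau, grid, theiler_E=1, refined=refined,
                                mean_mode=mean_mode,
                                partner_shift=partner_shift, min_t0=5)
        except ValueError:
            rows, kept, dropped, _ = brute_delta_table(
                eff.points.tolist(), cau.points.tolist(),
                grid.values.tolist(), 1, refined, mean_mode, partner_shift, 1)
            assert not kept
            return
        rows, kept, dropped, flags = brute_delta_table(
            eff.points.tolist(), cau.points.tolist(), grid.values.tolist(),
            1, refined, mean_mode, partner_shift, 1)
        assert table.t_index.tolist() == kept
        assert table.dropped_t.tolist() == dropped
        assert table.fill_mask.tolist() == flags
        np.testing.assert_allclose(table.values, np.array(rows), rtol=1e-10)

    def test_fill_is_noop_when_all_defined(self, rng):
        eff = toy_manifold(rng, 40)
        cau = toy_manifold(rng, 40)
        # huge radii: every cell defined
        grid = build_epsilon_grid(eff.diameter * 10, e=0.9, n_eps=4)
        table = delta_table(eff, cau, grid, min_t0=5)
        assert not table.fill_mask.any()
        assert table.dropped_t.size == 0

    def test_plateau_fill_copies_from_next_radius(self):
        raw = np.array([[np.nan, np.nan, 2.0, 3.0],
                        [1.0, 1.5, 2.5, 3.5],
                        [np.nan, np.nan, np.nan, np.nan]])
        from contscale.scaling import _fill_and_drop
        table = _fill_and_drop(raw.copy())
        assert table.t_index.tolist() == [0, 1]
        assert table.dropped_t.tolist() == [2]
        assert table.values[0].tolist() == [2.0, 2.0, 2.0, 3.0]
        assert table.fill_mask[0].tolist() == [True, True, False, False]
        assert not table.fill_mask[1].any()

    def test_all_rows_dropped_is_error(self):
        from contscale.scaling import _fill_and_drop
        with pytest.raises(ValueError, match="no usable time points"):
            _fill_and_drop(np.full((3, 4), np.nan))

    def test_mismatched_t0_rejected(self, rng):
        eff = toy_manifold(rng, 30)
        cau = toy_manifold(rng, 29)
        grid = build_epsilon_grid(1.0, 0.01, 5)
        with pytest.raises(ValueError, match="common T0"):
            delta_table(eff, cau, grid, min_t0=5)


class TestFitSlope:
    def _table_from_curve(self, mean_delta):
        vals = np.tile(mean_delta, (4, 1))
        return DeltaTable(values=vals, t_index=np.arange(4),
                          fill_mask=np.zeros(vals.shape, bool),
                          dropped_t=np.array([], int))

    def test_recovers_exact_line(self):
        grid = build_epsilon_grid(1.0)
        curve = fit_slope(self._table_from_curve(
            0.2 * grid.ln_values + 1.0), grid)
        assert curve.slope == pytest.approx(0.2, abs=1e-10)
        assert curve.intercept == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-1, 1), st.floats(0, 5))
    def test_recovers_planted_linear_relation(self, a, c):
        grid = build_epsilon_grid(2.5)
        curve = fit_slope(self._table_from_curve(a * grid.ln_values + c), grid)
        assert curve.slope == pytest.approx(a, abs=1e-8)

    def test_constant_curve_gives_zero_slope(self):
        grid = build_epsilon_grid(1.0)
        curve = fit_slope(self._table_from_curve(
            np.full(grid.n_eps, 2.0)), grid)
        assert curve.slope == 0.0
        assert curve.intercept == pytest.approx(2.0)

    def test_piecewise_curve_matches_literal_procedure(self):
        """Flat-linear-flat curve: H and slope equal the step-by-step oracle."""
        grid = build_epsilon_grid(1.0)
        ln = grid.ln_values
        y = np.piecewise(ln, [ln < -4.6, (ln >= -4.6) & (ln <= -2.3),
                              ln > -2.3],
                         [0.1, lambda v: 0.1 + 0.3 * (v + 4.6),
                          0.1 + 0.3 * 2.3])
        curve = fit_slope(self._table_from_curve(y), grid)
        slope, intercept, H = brute_fit(y.tolist(), ln.tolist())
        assert curve.support.tolist() == H
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)

    def test_selects_17_increments_at_default_grid(self):
        grid = build_epsilon_grid(1.0)
        rng = np.random.default_rng(0)
        curve = fit_slope(self._table_from_curve(rng.uniform(size=33)), grid)
        # 17 selected increments touch between 18 and 34 grid points
        assert 18 <= curve.support.size <= 33


class TestContinuitySlope:
    def test_end_to_end_matches_brute_force(self, rng):
        """Full pipeline equals a naive reimplementation on a toy run."""
        n = 300
        a = RawSeries("a", np.cumsum(rng.normal(size=n)))
        b = RawSeries("b", np.cumsum(rng.normal(size=n)))
        cfg = RunConfig(e=0.01, n_eps=9, theiler=2, min_t0=10,
                        embedding={"a": {"dim": 2, "lag": 1},
                                   "b": {"dim": 3, "lag": 2}})
        curve = continuity_slope(a, b, cfg)
        slope, intercept, H, mean_delta = brute_slope_pipeline_pair(
            a.values, b.values, cfg)
        np.testing.assert_allclose(curve.mean_delta, mean_delta, rtol=1e-10)
        assert curve.support.tolist() == H
        assert curve.slope == pytest.approx(slope, rel=1e-10)

    def test_deterministic_and_name_invariant(self, rng):
        v1 = np.cumsum(rng.normal(size=200))
        v2 = np.cumsum(rng.normal(size=200))
        cfg = RunConfig(n_eps=11, embedding={"p": {"dim": 2, "lag": 1},
                                             "q": {"dim": 2, "lag": 1},
                                             "r": {"dim": 2, "lag": 1}})
        s1 = continuity_slope(RawSeries("p", v1), RawSeries("q", v2), cfg)
        s2 = continuity_slope(RawSeries("p", v1), RawSeries("r", v2), cfg)
        assert s1.slope == s2.slope

    def test_self_correspondence_is_strongly_positive(self, map_config):
        """x ↪ x: the identity correspondence is continuous (smoke test)."""
        from contscale import LogisticPairSpec, simulate_logistic_pair
        x1, _ = simulate_logistic_pair(LogisticPairSpec(length=800, seed=9))
        cfg = map_config.with_embedding("x1", 3, 1)
        curve = continuity_slope(x1, x1, cfg)
        assert curve.slope > 0.02

    def test_length_mismatch_rejected(self, map_config):
        a = RawSeries("x1", np.arange(100.0))
        b = RawSeries("x2", np.arange(99.0))
        with pytest.raises(ValueError, match="equal length"):
            continuity_slope(a, b, map_config)


def brute_slope_pipeline_pair(eff_vals, cau_vals, cfg):
    """Brute pipeline honoring per-series embedding overrides of ``cfg``."""
    import math
    from oracles import (brute_delta_table, brute_diameter, brute_fit)

    def embed(vals, dim, lag):
        T0 = len(vals) - (dim - 1) * lag
        return [[vals[t + i * lag] for i in range(dim)] for t in range(T0)]

    de, le = cfg.embedding["a"]["dim"], cfg.embedding["a"]["lag"]
    dc, lc = cfg.embedding["b"]["dim"], cfg.embedding["b"]["lag"]
    eff = embed(list(eff_vals), de, le)
    cau = embed(list(cau_vals), dc, lc)
    T0 = min(len(eff), len(cau))
    eff, cau = eff[:T0], cau[:T0]
    D = brute_diameter(eff)
    n_eps = cfg.n_eps
    lo, hi = math.log(cfg.e * D), math.log(D)
    eps = [math.exp(lo + (hi - lo) * j / (n_eps - 1)) for j in range(n_eps)]
    eps[0], eps[-1] = cfg.e * D, D
    rows, _, _, _ = brute_delta_table(eff, cau, eps, cfg.theiler, cfg.refined,
                                      cfg.mean_mode, cfg.partner_shift,
                                      cfg.min_neighbors)
    mean_delta = [sum(r[j] for r in rows) / len(rows) for j in range(n_eps)]
    slope, intercept, H = brute_fit(mean_delta, [math.log(v) for v in eps])
    return slope, intercept, H, mean_delta
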