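"""Scenario evaluation, sweeps, and the CIR=PR equality root."""

import numpy as np
import pytest

from epiconv import (
    NoRootError,
    RiskWindow,
    ScenarioSpec,
    ci_trajectory,
    evaluate_scenario,
    find_equality_duration,
    prevalence_ratio,
    sweep_duration,
    sweep_duration_by_window,
    table1_scenarios,
    table_deviation,
)

W1 = RiskWindow(delta_t=1.0)

# Printed benchmark cells: scenario name -> (idr, dev_idr, cir, dev_cir)
BENCHMARK_CELLS = {
    "1": (2.053, 2.6, 2.025, 1.2),
    "2": (0.205, -89.7, 0.227, -88.6),
    "3": (2.053, 2.6, 1.809, -9.5),
    "4": (0.205, -89.7, 0.443, -77.8),
    "5": (3.000, 50.0, 2.230, 11.5),
    "6": (0.300, -85.0, 0.656, -67.2),
    "7": (3.000, 50.0, 1.037, -48.1),
    "8": (0.300, -85.0, 1.000, -50.0),
}


class TestBenchmarkTable:
    def test_fixture_has_eight_scenarios_all_with_pr_two(self):
        specs = table1_scenarios()
        assert [s.name for s in specs] == [str(i) for i in range(1, 9)]
        for s in specs:
            assert prevalence_ratio(s.p1, s.p0) == pytest.approx(2.0, rel=1e-12)
            assert s.delta_t == 1.0

    def test_all_sixteen_measure_cells_at_three_decimals(self):
        for spec in table1_scenarios():
            idr_exp, _, cir_exp, _ = BENCHMARK_CELLS[spec.name]
            res = evaluate_scenario(spec)
            assert round(res.measures.idr, 3) == idr_exp, spec.name
            assert round(res.measures.cir, 3) == cir_exp, spec.name

    def test_all_sixteen_deviation_cells_at_one_decimal(self):
        for spec in table1_scenarios():
            _, dev_idr_exp, _, dev_cir_exp = BENCHMARK_CELLS[spec.name]
            res = evaluate_scenario(spec)
            assert table_deviation(res.measures.idr, res.measures.pr) == dev_idr_exp
            assert table_deviation(res.measures.cir, res.measures.pr) == dev_cir_exp

    def test_result_internally_consistent_with_stratum_relations(self):
        for spec in table1_scenarios():
            res = evaluate_scenario(spec)
            # implied rates reproduce the prevalences
            assert res.id1 * spec.t1_bar / (res.id1 * spec.t1_bar + 1) == pytest.approx(
                spec.p1, rel=1e-9
            )
            assert res.measures.cir == pytest.approx(res.ci1 / res.ci0, rel=1e-12)
            assert res.measures.idr == pytest.approx(res.id1 / res.id0, rel=1e-9)


def test_evaluate_scenario_null_contrast_is_all_ones():
    spec = ScenarioSpec(name="null", p1=0.3, p0=0.3, t1_bar=0.7, t0_bar=0.7, delta_t=2.0)
    m = evaluate_scenario(spec).measures
    assert m.pr == m.por == m.idr == pytest.approx(1.0, rel=1e-12)
    assert m.cir == pytest.approx(1.0, rel=1e-12)


def test_classification_labels_do_not_alter_computation():
    base = ScenarioSpec(name="a", p1=0.4, p0=0.2, t1_bar=1.0, t0_bar=1.0, delta_t=1.0)
    labelled = ScenarioSpec(
        name="b", p1=0.4, p0=0.2, t1_bar=1.0, t0_bar=1.0, delta_t=1.0,
        outcome_class="common", duration_class="long", duration_equality="equal",
    )
    assert evaluate_scenario(base).measures == evaluate_scenario(labelled).measures


class TestSweepDuration:
    def test_pr_por_idr_constant_and_cir_crosses(self):
        points = sweep_duration(0.5, 0.25, W1, [0.1, 0.5, 0.69, 1.0, 2.0])
        assert all(p.pr == 2.0 and p.por == 3.0 and p.idr == 3.0 for p in points)
        at_069 = points[2]
        assert round(at_069.cir, 2) == 2.00

    def test_underestimation_of_idr_throughout(self):
        """The constant PR sits 50% below the IDR over the whole range."""
        points = sweep_duration(0.5, 0.25, W1, list(np.arange(0.05, 5.0, 0.05)))
        for p in points:
            assert p.pr / p.idr == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_null_contrast_gives_flat_unit_cir(self):
        points = sweep_duration(0.3, 0.3, W1, [0.2, 1.0, 3.0])
        assert all(p.cir == pytest.approx(1.0, rel=1e-12) for p in points)

    def test_grid_must_be_increasing_and_nonempty(self):
        from epiconv import DomainError

        with pytest.raises(DomainError):
            sweep_duration(0.5, 0.25, W1, [])
        with pytest.raises(DomainError):
            sweep_duration(0.5, 0.25, W1, [1.0, 0.5])


class TestSweepByWindow:
    def test_long_window_overestimates_cir_below_equality_root(self):
        """For Δt=5 the PR overestimates the CIR throughout durations short
        of the equality root T̄* = 0.6927·Δt ≈ 3.46; past the root the CIR
        crosses above the PR again."""
        grid = list(np.round(np.arange(0.1, 3.41, 0.1), 10))
        curves = sweep_duration_by_window(0.5, 0.25, [5.0], grid)
        for p in curves[5.0]:
            assert p.cir < p.pr
        beyond = sweep_duration(0.5, 0.25, RiskWindow(delta_t=5.0), [4.0])
        assert beyond[0].cir > beyond[0].pr

    def test_single_window_matches_plain_sweep(self):
        grid = [0.5, 1.0, 1.5]
        multi = sweep_duration_by_window(0.5, 0.25, [1.0], grid)
        single = sweep_duration(0.5, 0.25, W1, grid)
        assert multi[1.0] == single

    def test_unit_window_curve_crosses_pr_near_069(self):
        grid = list(np.round(np.arange(0.01, 5.0, 0.01), 10))
        curve = sweep_duration_by_window(0.5, 0.25, [1.0], grid)[1.0]
        crossings = [
            (a.x_value, b.x_value)
            for a, b in zip(curve, curve[1:])
            if (a.cir - 2.0) * (b.cir - 2.0) <= 0
        ]
        assert len(crossings) == 1
        assert crossings[0][0] <= 0.70 and crossings[0][1] >= 0.69


class TestCiTrajectory:
    def test_anchor_points(self):
        points = ci_trajectory(1.0, 0.333, 1.0, [1.45, 5.0])
        assert round(points[0].cir, 1) == 2.0
        assert round(points[1].cir, 3) == 1.225
        assert round(points[1].ci0, 3) == 0.811
        assert round(points[1].ci1, 3) == 0.993

    def test_short_window_limit_is_rate_ratio(self):
        points = ci_trajectory(1.0, 1.0 / 3.0, 1.0, [1e-8])
        assert points[0].cir == pytest.approx(3.0, rel=1e-6)

    def test_cir_decreases_towards_one(self):
        points = ci_trajectory(1.0, 1.0 / 3.0, 1.0, list(np.arange(0.5, 20.0, 0.5)))
        cirs = [p.cir for p in points]
        assert all(b < a for a, b in zip(cirs, cirs[1:]))
        assert cirs[-1] > 1.0


class TestEqualityDuration:
    def test_unit_window_root_is_069(self):
        t_star = find_equality_duration(0.5, 0.25, W1)
        assert round(t_star, 2) == 0.69

    def test_root_satisfies_equation_to_1e9(self):
        from epiconv import cir_from_prevalences

        t_star = find_equality_duration(0.5, 0.25, W1)
        cir = cir_from_prevalences(0.5, 0.25, t_star, t_star, W1)
        assert cir == pytest.approx(2.0, abs=1e-9)

    def test_window_scaling_of_the_root(self):
        """With equal durations the root scales linearly with the window."""
        base = find_equality_duration(0.5, 0.25, W1)
        assert find_equality_duration(
            0.5, 0.25, RiskWindow(delta_t=2.5)
        ) == pytest.approx(2.5 * base, rel=1e-6)
        assert 2.5 * base == pytest.approx(1.732, abs=5e-4)

    def test_no_root_when_contrast_is_null(self):
        with pytest.raises(NoRootError):
            find_equality_duration(0.3, 0.3, W1)


def test_scale_invariance_cir_depends_on_dt_over_t_only():
    """With equal durations, CIR is a function of (p1, p0, Δt/T̄) alone."""
    from epiconv import cir_from_prevalences

    rng = np.random.default_rng(12345)
    for _ in range(25):
        p0 = rng.uniform(0.01, 0.45)
        p1 = rng.uniform(p0, 0.9)
        t = rng.uniform(0.05, 5.0)
        dt = rng.uniform(0.05, 5.0)
        k = rng.uniform(0.2, 8.0)
        a = cir_from_prevalences(p1, p0, t, t, RiskWindow(delta_t=dt))
        b = cir_from_prevalences(p1, p0, k * t, k * t, RiskWindow(delta_t=k * dt))
        assert a == pytest.approx(b, rel=1e-9)


def test_cir_tends_to_one_for_very_long_windows():
    from epiconv import cir_from_prevalences

    cir = cir_from_prevalences(0.5, 0.25, 1.0, 1.0, RiskWindow(delta_t=50.0))
    assert cir == pytest.approx(1.0, abs=1e-6)
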