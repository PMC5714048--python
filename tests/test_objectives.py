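"""Objective functions, analytic gradients, and the fluence optimizer."""

import numpy as np
import pytest
from scipy import sparse

import autoimrt as ai
from autoimrt.beams import InfluenceMatrix
from autoimrt.objectives import eud

G = ai.Grid(shape=(4, 4, 4), spacing=(2.0, 2.0, 2.0))


def _set_with_roi(doses_cGy, name="roi"):
    """Structure set whose ROI covers the first len(doses) voxels."""
    s = ai.StructureSet(G)
    data = np.zeros(G.shape, bool)
    data.ravel()[: len(doses_cGy)] = True
    s.add(ai.Mask(name, G, data))
    dose = np.zeros(G.shape)
    dose.ravel()[: len(doses_cGy)] = doses_cGy
    return s, ai.DoseGrid(G, dose)


def _toy_influence(n_voxels, n_beamlets, rng):
    """Small dense random influence wrapped in the sparse container."""
    grid = ai.Grid(shape=(n_voxels, 1, 1), spacing=(2.0, 2.0, 2.0))
    mat = sparse.csc_matrix(rng.random((n_voxels, n_beamlets)))
    return grid, InfluenceMatrix(
        grid=grid, matrix=mat,
        beamlet_beam=np.zeros(n_beamlets, int),
        beamlet_row=np.zeros(n_beamlets, int),
        beamlet_col=np.arange(n_beamlets),
        inert=np.zeros(n_beamlets, bool),
        beams=[],
    )


class TestObjectiveValues:
    @pytest.mark.parametrize("kind,extra", [
        ("min_dose", {}), ("max_dose", {}), ("uniform_dose", {}),
        ("max_eud", {"eud_a": 1.0}),
    ])
    def test_zero_when_dose_exactly_at_target(self, kind, extra):
        s, d = _set_with_roi([7000.0] * 8)
        o = ai.ObjectiveSpec("roi", kind, dose_cGy=7000.0, weight=5.0, **extra)
        assert ai.objective_value(d, s, o) == 0.0

    def test_max_dose_two_voxel_hand_computation(self):
        s, d = _set_with_roi([6000.0, 8000.0])
        o = ai.ObjectiveSpec("roi", "max_dose", dose_cGy=7000.0, weight=1.0)
        assert ai.objective_value(d, s, o) == pytest.approx(1000.0 ** 2 / 2)

    def test_max_eud_with_a1_equals_mean_dose_penalty(self):
        s, d = _set_with_roi([1000.0, 3000.0, 5000.0])
        o = ai.ObjectiveSpec("roi", "max_eud", dose_cGy=2000.0, weight=2.0, eud_a=1.0)
        assert ai.objective_value(d, s, o) == pytest.approx(2.0 * (3000.0 - 2000.0) ** 2)

    def test_empty_roi_raises_naming_it(self):
        s = ai.StructureSet(G)
        s.add(ai.Mask("void", G, np.zeros(G.shape, bool)))
        d = ai.DoseGrid(G, np.zeros(G.shape))
        o = ai.ObjectiveSpec("void", "min_dose", dose_cGy=100.0, weight=1.0)
        with pytest.raises(ai.ObjectiveError, match="void"):
            ai.objective_value(d, s, o)

    def test_values_always_nonnegative(self):
        rng = np.random.default_rng(2)
        s, d = _set_with_roi(rng.random(10) * 8000)
        for kind, extra in [("min_dose", {}), ("max_dose", {}), ("uniform_dose", {}),
                            ("max_eud", {"eud_a": 3.0})]:
            o = ai.ObjectiveSpec("roi", kind, dose_cGy=4000.0, weight=1.0, **extra)
            assert ai.objective_value(d, s, o) >= 0.0


class TestEUD:
    def test_a1_is_mean_dose_exactly(self):
        rng = np.random.default_rng(8)
        doses = rng.random(100) * 7000
        assert eud(doses, 1.0) == pytest.approx(doses.mean(), rel=1e-12)

    def test_a40_approaches_max_dose_on_two_dose_roi(self):
        doses = np.array([2000.0, 6000.0])
        assert eud(doses, 40.0) == pytest.approx(6000.0, rel=0.02)

    def test_monotone_in_a(self):
        doses = np.array([1000.0, 3000.0, 6500.0])
        values = [eud(doses, a) for a in (0.5, 1.0, 2.0, 10.0, 40.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestComposite:
    def test_weighted_sum_properties(self):
        s, d = _set_with_roi([3000.0, 5000.0])
        o1 = ai.ObjectiveSpec("roi", "min_dose", dose_cGy=4000.0, weight=2.0)
        o2 = ai.ObjectiveSpec("roi", "max_dose", dose_cGy=4000.0, weight=3.0)
        both = ai.composite(d, s, [o1, o2])
        assert both == pytest.approx(ai.objective_value(d, s, o1) + ai.objective_value(d, s, o2))
        assert ai.composite(d, s, [o2, o1]) == pytest.approx(both)  # order-free
        assert ai.composite(d, s, [o1]) == pytest.approx(ai.objective_value(d, s, o1))

    def test_zero_weights_give_zero(self):
        s, d = _set_with_roi([3000.0, 5000.0])
        objs = [ai.ObjectiveSpec("roi", "min_dose", dose_cGy=4000.0, weight=0.0)]
        assert ai.composite(d, s, objs) == 0.0

    def test_empty_regional_roi_contributes_zero_and_logs(self):
        s, d = _set_with_roi([3000.0])
        s.add(ai.Mask("spot", G, np.zeros(G.shape, bool)))
        objs = [ai.ObjectiveSpec("spot", "min_dose", dose_cGy=7000.0, weight=100.0,
                                 tag="regional")]
        log = []
        assert ai.composite(d, s, objs, log=log) == 0.0
        assert any("spot" in line for line in log)


class TestGradient:
    @pytest.mark.parametrize("trial", range(5))
    def test_matches_central_finite_differences(self, trial):
        rng = np.random.default_rng(100 + trial)
        grid, A = _toy_influence(12, 10, rng)
        s = ai.StructureSet(grid)
        m1 = np.zeros(grid.shape, bool); m1.ravel()[:6] = True
        m2 = np.zeros(grid.shape, bool); m2.ravel()[6:] = True
        s.add(ai.Mask("target", grid, m1))
        s.add(ai.Mask("oar", grid, m2))
        objs = [
            ai.ObjectiveSpec("target", "min_dose", dose_cGy=5.0, weight=10.0),
            ai.ObjectiveSpec("target", "uniform_dose", dose_cGy=5.0, weight=1.0),
            ai.ObjectiveSpec("oar", "max_dose", dose_cGy=2.0, weight=3.0),
            ai.ObjectiveSpec("oar", "max_eud", dose_cGy=1.0, weight=2.0, eud_a=4.0),
        ]
        x = rng.random(10) + 0.5
        g = ai.gradient(A, s, objs, x)

        def f(xv):
            return ai.composite(ai.total_dose(A, xv), s, objs)

        h = 1e-5
        fd = np.empty_like(x)
        for i in range(10):
            e = np.zeros(10); e[i] = h
            fd[i] = (f(x + e) - f(x - e)) / (2 * h)
        assert np.allclose(g, fd, rtol=1e-4, atol=1e-6 * max(1.0, np.abs(fd).max()))

    def test_zero_where_all_constraints_satisfied(self):
        rng = np.random.default_rng(1)
        grid, A = _toy_influence(6, 4, rng)
        s = ai.StructureSet(grid)
        s.add(ai.Mask("roi", grid, np.ones(grid.shape, bool)))
        x = np.ones(4)
        d = ai.total_dose(A, x)
        # one-sided constraints comfortably satisfied -> flat region
        objs = [ai.ObjectiveSpec("roi", "min_dose", dose_cGy=float(d.dose.min()) / 2, weight=5.0),
                ai.ObjectiveSpec("roi", "max_dose", dose_cGy=float(d.max()) * 2, weight=5.0)]
        assert np.all(ai.gradient(A, s, objs, x) == 0.0)

    def test_max_dose_gradient_sign_on_one_voxel_roi(self):
        grid = ai.Grid(shape=(1, 1, 1), spacing=(2.0, 2.0, 2.0))
        A = InfluenceMatrix(
            grid=grid, matrix=sparse.csc_matrix(np.array([[2.0]])),
            beamlet_beam=np.zeros(1, int), beamlet_row=np.zeros(1, int),
            beamlet_col=np.zeros(1, int), inert=np.zeros(1, bool), beams=[],
        )
        s = ai.StructureSet(grid)
        s.add(ai.Mask("v", grid, np.ones(grid.shape, bool)))
        objs = [ai.ObjectiveSpec("v", "max_dose", dose_cGy=1.0, weight=1.0)]
        g = ai.gradient(A, s, objs, np.array([5.0]))  # dose 10 > 1: push down
        assert g[0] > 0.0


class TestOptimizer:
    def test_single_voxel_single_beamlet_closed_form(self):
        grid = ai.Grid(shape=(1, 1, 1), spacing=(2.0, 2.0, 2.0))
        a11 = 3.5
        A = InfluenceMatrix(
            grid=grid, matrix=sparse.csc_matrix(np.array([[a11]])),
            beamlet_beam=np.zeros(1, int), beamlet_row=np.zeros(1, int),
            beamlet_col=np.zeros(1, int), inert=np.zeros(1, bool), beams=[],
        )
        s = ai.StructureSet(grid)
        s.add(ai.Mask("v", grid, np.ones(grid.shape, bool)))
        D = 700.0
        objs = [ai.ObjectiveSpec("v", "min_dose", dose_cGy=D, weight=1.0)]
        res = ai.optimize_fluence(A, s, objs, ai.OptimizerParams(max_iterations=200))
        assert res.fluence[0] == pytest.approx(D / a11, rel=1e-4)
        assert res.final_objective < 1e-4

    def test_optimal_start_returns_immediately(self):
        rng = np.random.default_rng(3)
        grid, A = _toy_influence(6, 4, rng)
        s = ai.StructureSet(grid)
        s.add(ai.Mask("roi", grid, np.ones(grid.shape, bool)))
        x0 = np.ones(4)
        d0 = ai.total_dose(A, x0)
        objs = [ai.ObjectiveSpec("roi", "max_dose", dose_cGy=float(d0.max()) * 2, weight=1.0)]
        res = ai.optimize_fluence(A, s, objs, x0=x0)
        assert res.converged and res.n_iterations == 0
        assert np.array_equal(res.fluence, x0)

    def test_trace_monotone_non_increasing(self, small_influence, small_derived, hn_template):
        res = ai.optimize_fluence(
            small_influence, small_derived, hn_template.initial_objectives,
            ai.OptimizerParams(max_iterations=30),
        )
        assert np.all(np.diff(res.objective_trace) <= 0)

    def test_warm_restart_never_ends_above_start(self, small_influence, small_derived,
                                                 hn_template, small_initial):
        res = ai.optimize_fluence(
            small_influence, small_derived, hn_template.initial_objectives,
            ai.OptimizerParams(max_iterations=10), x0=small_initial.fluence,
        )
        assert res.final_objective <= small_initial.final_objective + 1e-9

    def test_inert_beamlets_stay_at_zero(self, small_influence, small_derived,
                                         hn_template, small_initial):
        if small_influence.inert.any():
            assert np.all(small_initial.fluence[small_influence.inert] == 0.0)
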