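"""Geometry kernel: set algebra, margins, rings, isodose masks, DVHs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra.numpy import arrays

import autoimrt as ai
from autoimrt.roi_algebra import dose_statistics

G8 = ai.Grid(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0))


def brute_force_expand(mask: ai.Mask, margin_mm: float) -> np.ndarray:
    """Oracle: explicit all-pairs voxel-centre distance check."""
    occ = np.argwhere(mask.data) * np.asarray(mask.grid.spacing)
    out = np.zeros(mask.grid.shape, dtype=bool)
    if occ.size == 0:
        return out
    for idx in np.ndindex(mask.grid.shape):
        p = np.asarray(idx) * np.asarray(mask.grid.spacing)
        out[idx] = np.min(np.linalg.norm(occ - p, axis=1)) <= margin_mm
    return out


class TestCombine:
    @pytest.mark.parametrize("op,fn", [
        ("union", np.logical_or),
        ("intersect", np.logical_and),
        ("subtract", lambda a, b: a & ~b),
    ])
    def test_matches_per_voxel_oracle(self, op, fn):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = ai.Mask("a", G8, rng.random(G8.shape) < 0.4)
            b = ai.Mask("b", G8, rng.random(G8.shape) < 0.4)
            got = ai.combine(a, b, op)
            expected = np.empty(G8.shape, dtype=bool)
            for idx in np.ndindex(G8.shape):  # exhaustive voxel loop
                expected[idx] = fn(a.data[idx], b.data[idx])
            assert np.array_equal(got.data, expected)

    def test_self_subtraction_is_empty(self):
        rng = np.random.default_rng(0)
        a = ai.Mask("a", G8, rng.random(G8.shape) < 0.5)
        assert ai.subtract(a, a).is_empty()

    def test_grid_mismatch_raises_naming_both(self):
        other = ai.Grid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))
        a = ai.Mask("alpha", G8, np.ones(G8.shape, bool))
        b = ai.Mask("beta", other, np.ones(other.shape, bool))
        with pytest.raises(ai.GeometryError, match="alpha.*beta"):
            ai.combine(a, b, "union")


class TestMargins:
    def test_expand_single_voxel_matches_distance_enumeration(self):
        grid = ai.Grid(shape=(15, 15, 15), spacing=(2.0, 2.0, 2.0))
        data = np.zeros(grid.shape, bool)
        data[7, 7, 7] = True
        m = ai.Mask("seed", grid, data)
        got = ai.expand(m, 10.0)
        # enumerate all voxel-centre distances to the single seed
        idx = np.stack(np.meshgrid(*[np.arange(15)] * 3, indexing="ij"), -1)
        dist = np.linalg.norm((idx - 7) * 2.0, axis=-1)
        assert np.array_equal(got.data, dist <= 10.0)

    def test_expand_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(3)
        grid = ai.Grid(shape=(9, 9, 9), spacing=(1.0, 2.0, 3.0))  # anisotropic
        for _ in range(5):
            m = ai.Mask("m", grid, rng.random(grid.shape) < 0.08)
            got = ai.expand(m, 4.0)
            assert np.array_equal(got.data, brute_force_expand(m, 4.0))

    def test_expand_is_extensive_contract_anti_extensive(self):
        rng = np.random.default_rng(11)
        m = ai.Mask("m", G8, rng.random(G8.shape) < 0.3)
        assert np.all(ai.expand(m, 3.0).data >= m.data)
        assert np.all(ai.contract(m, 3.0).data <= m.data)

    def test_expand_composition_contains_single_expansion(self):
        rng = np.random.default_rng(5)
        m = ai.Mask("m", G8, rng.random(G8.shape) < 0.15)
        twice = ai.expand(ai.expand(m, 4.0), 6.0)
        once = ai.expand(m, 10.0)
        assert np.all(twice.data >= once.data)

    def test_expand_empty_returns_empty(self):
        m = ai.Mask("m", G8, np.zeros(G8.shape, bool))
        assert ai.expand(m, 10.0).is_empty()

    def test_contract_sphere_matches_analytic_radius(self):
        # 20 mm sphere contracted by 5 mm ~ 15 mm sphere, within one voxel shell
        grid = ai.Grid(shape=(50, 50, 50), spacing=(1.0, 1.0, 1.0))
        centre = np.array([24.5, 24.5, 24.5])
        idx = np.stack(np.meshgrid(*[np.arange(50)] * 3, indexing="ij"), -1)
        r = np.linalg.norm(idx - centre, axis=-1)
        sphere = ai.Mask("sph", grid, r <= 20.0)
        got = ai.contract(sphere, 5.0)
        inner = int((r <= 14.0).sum())
        outer = int((r <= 16.0).sum())
        assert inner <= got.n_voxels <= outer

    def test_contract_may_empty_a_small_mask(self):
        data = np.zeros(G8.shape, bool)
        data[4, 4, 4] = True
        assert ai.contract(ai.Mask("tiny", G8, data), 3.0).is_empty()


class TestRing:
    def test_ring_composition_equals_expand_minus_seed(self):
        rng = np.random.default_rng(9)
        seed = ai.Mask("seed", G8, rng.random(G8.shape) < 0.1)
        if seed.is_empty():
            seed.data[3, 3, 3] = True
        ring = ai.make_ring([seed], 5.0, [])
        expected = ai.expand(seed, 5.0).data & ~seed.data
        assert np.array_equal(ring.data, expected)

    def test_ring_disjoint_from_seeds_and_exclusions(self):
        rng = np.random.default_rng(12)
        s1 = ai.Mask("s1", G8, rng.random(G8.shape) < 0.1)
        s2 = ai.Mask("s2", G8, rng.random(G8.shape) < 0.1)
        ex = ai.Mask("ex", G8, rng.random(G8.shape) < 0.2)
        ring = ai.make_ring([s1, s2], 6.0, [ex])
        for other in (s1, s2, ex):
            assert not np.any(ring.data & other.data)

    def test_empty_seed_list_is_configuration_error(self):
        with pytest.raises(ValueError):
            ai.make_ring([], 5.0, [])


class TestIsodose:
    def test_threshold_is_inclusive(self):
        d = ai.DoseGrid(G8, np.full(G8.shape, 7000.0))
        assert ai.isodose_mask(d, 7000.0).n_voxels == G8.n_voxels
        zero = ai.DoseGrid(G8, np.zeros(G8.shape))
        assert ai.isodose_mask(zero, 7000.0).is_empty()

    def test_matches_per_voxel_comparison(self):
        rng = np.random.default_rng(21)
        d = ai.DoseGrid(G8, rng.random(G8.shape) * 8000)
        got = ai.isodose_mask(d, 4000.0)
        for idx in np.ndindex(G8.shape):
            assert got.data[idx] == (d.dose[idx] >= 4000.0)

    def test_monotone_nesting_in_level(self):
        rng = np.random.default_rng(22)
        d = ai.DoseGrid(G8, rng.random(G8.shape) * 8000)
        lo = ai.isodose_mask(d, 3000.0)
        hi = ai.isodose_mask(d, 6000.0)
        assert np.all(lo.data >= hi.data)


class TestDVH:
    def test_uniform_dose_gives_step_function(self):
        m = ai.Mask("roi", G8, np.ones(G8.shape, bool))
        d = ai.DoseGrid(G8, np.full(G8.shape, 500.0))
        curve = ai.dvh(d, m, bin_width_cGy=100.0)
        assert np.all(curve.volume_fraction[curve.dose_edges <= 500.0] == 1.0)
        assert np.all(curve.volume_fraction[curve.dose_edges > 500.0] == 0.0)

    def test_two_voxel_hand_enumeration(self):
        data = np.zeros(G8.shape, bool)
        data[0, 0, 0] = data[0, 0, 1] = True
        m = ai.Mask("roi", G8, data)
        dose = np.zeros(G8.shape)
        dose[0, 0, 0], dose[0, 0, 1] = 50.0, 150.0
        curve = ai.dvh(ai.DoseGrid(G8, dose), m, bin_width_cGy=100.0)
        assert curve.value_at(0.0) == 1.0
        assert curve.value_at(100.0) == 0.5
        assert curve.value_at(200.0) == 0.0

    def test_curve_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(31)
        m = ai.Mask("roi", G8, rng.random(G8.shape) < 0.5)
        d = ai.DoseGrid(G8, rng.random(G8.shape) * 7000)
        curve = ai.dvh(d, m)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 0)
        assert np.all((curve.volume_fraction >= 0) & (curve.volume_fraction <= 1))

    def test_empty_roi_raises_naming_it(self):
        m = ai.Mask("empty_roi", G8, np.zeros(G8.shape, bool))
        d = ai.DoseGrid(G8, np.zeros(G8.shape))
        with pytest.raises(ai.DVHError, match="empty_roi"):
            ai.dvh(d, m)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=arrays(bool, (6, 6, 6)), b=arrays(bool, (6, 6, 6)))
def test_set_algebra_identities(a, b):
    """subtract/intersect partition a; union is commutative and extensive."""
    grid = ai.Grid(shape=(6, 6, 6), spacing=(2.0, 2.0, 2.0))
    ma, mb = ai.Mask("a", grid, a), ai.Mask("b", grid, b)
    diff = ai.subtract(ma, mb)
    inter = ai.intersect(ma, mb)
    assert np.array_equal(diff.data | inter.data, ma.data)
    assert not np.any(diff.data & inter.data)
    assert np.array_equal(ai.union(ma, mb).data, ai.union(mb, ma).data)
    assert np.all(ai.union(ma, mb).data >= ma.data)


def test_dose_statistics_uniform_dose_collapses():
    m = ai.Mask("roi", G8, np.ones(G8.shape, bool))
    d = ai.DoseGrid(G8, np.full(G8.shape, 1234.0))
    st = dose_statistics(d, m)
    assert st["Dmax_cGy"] == st["Dmean_cGy"] == st["D95_cGy"] == 1234.0
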