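"""Pixel-overlap percent, rotation null, slab projection, whole-cell pooling."""

import numpy as np
import pytest

from vesicoloc import (
    ChannelSpec,
    DOGParams,
    SyntheticSceneSpec,
    ThresholdConfig,
    cell_coloc,
    coloc_percent,
    coloc_threeway,
    rotation_null,
    simulate_scene,
    slab_project,
)
from vesicoloc.colocalization import rotate_180
from vesicoloc.errors import GeometryError, ParameterError

from conftest import make_mask, make_stack


def brute_force_percent(a, b, direction="B_with_A"):
    """Literal double loop over pixels — the oracle for the overlap equation."""
    num = den = 0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            num += int(a[y, x] and b[y, x])
            den += int(b[y, x] if direction == "B_with_A" else a[y, x])
    return None if den == 0 else 100.0 * num / den


class TestColocPercent:
    def test_identical_masks_are_100(self):
        m = make_mask([(0, 0), (1, 2)])
        assert coloc_percent(m, m).percent == 100.0

    def test_disjoint_masks_are_0(self):
        a = make_mask([(0, 0)])
        b = make_mask([(3, 3)])
        assert coloc_percent(a, b).percent == 0.0

    def test_worked_example_both_directions(self):
        a = make_mask([(0, 0), (0, 1), (1, 0)], label="A")
        b = make_mask([(0, 1), (1, 1), (2, 2), (2, 3)], label="B")
        r = coloc_percent(a, b, "B_with_A")
        assert (r.numerator_px, r.denominator_px) == (1, 4)
        assert r.percent == 25.0
        r2 = coloc_percent(a, b, "A_with_B")
        assert r2.percent == pytest.approx(100 / 3)
        # numerator symmetric under swap, percent generally not
        assert coloc_percent(b, a, "B_with_A").numerator_px == 1

    def test_empty_denominator_is_undefined_not_zero(self):
        a = make_mask([(0, 0)])
        b = make_mask([])
        r = coloc_percent(a, b, "B_with_A")
        assert not r.defined and r.percent is None

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            coloc_percent(make_mask([], (4, 4)), make_mask([], (5, 5)))

    def test_matches_brute_force_on_random_masks(self, rng):
        """The implementation agrees exactly with a literal pixel loop on
        200 random mask pairs."""
        for _ in range(200):
            shape = tuple(rng.integers(1, 33, size=2))
            a = (rng.random(shape) < rng.uniform(0, 0.5)).astype(np.uint8)
            b = (rng.random(shape) < rng.uniform(0, 0.5)).astype(np.uint8)
            ma, mb = make_mask([], shape), make_mask([], shape)
            ma.values, mb.values = a, b
            for direction in ("B_with_A", "A_with_B"):
                got = coloc_percent(ma, mb, direction).percent
                assert got == brute_force_percent(a, b, direction)


class TestThreeway:
    def test_identical_masks_100_any_normalizer(self):
        m = make_mask([(1, 1), (2, 2)], label="A")
        n = make_mask([(1, 1), (2, 2)], label="B")
        o = make_mask([(1, 1), (2, 2)], label="C")
        for norm in "ABC":
            assert coloc_threeway(m, n, o, norm).percent == 100.0

    def test_disjoint_pair_gives_0(self):
        a = make_mask([(0, 0)], label="A")
        b = make_mask([(1, 1)], label="B")
        c = make_mask([(0, 0), (1, 1)], label="C")
        assert coloc_threeway(a, b, c, "C").percent == 0.0

    def test_worked_triple_example(self):
        a = make_mask([(0, 0), (1, 1)], label="A")
        b = make_mask([(1, 1), (2, 2)], label="B")
        c = make_mask([(1, 1)], label="C")
        r = coloc_threeway(a, b, c, "A")
        assert (r.numerator_px, r.denominator_px) == (1, 2)
        assert r.percent == 50.0

    def test_triple_matches_brute_force(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(1, 17, size=2))
            arrs = [(rng.random(shape) < 0.3).astype(np.uint8) for _ in range(3)]
            masks = []
            for lbl, arr in zip("ABC", arrs):
                m = make_mask([], shape, label=lbl)
                m.values = arr
                masks.append(m)
            num = int((arrs[0] * arrs[1] * arrs[2]).sum())
            den = int(arrs[0].sum())
            got = coloc_threeway(*masks, normalizer="A")
            assert (got.numerator_px, got.denominator_px) == (num, den)

    def test_unknown_normalizer(self):
        m = make_mask([(0, 0)], label="A")
        with pytest.raises(ParameterError):
            coloc_threeway(m, m, m, "Z")


class TestRotationNull:
    def test_rotation_is_involution(self, rng):
        m = make_mask([], (7, 6))
        m.values = (rng.random((7, 6)) < 0.4).astype(np.uint8)
        np.testing.assert_array_equal(rotate_180(rotate_180(m)).values, m.values)

    def test_corner_pixel_maps_to_opposite_corner(self):
        """Index-reversal oracle: (0,0) on an n x n grid lands at (n-1, n-1)."""
        for n in (4, 5):
            b = make_mask([(0, 0)], (n, n), label="B")
            a_hit = make_mask([(n - 1, n - 1)], (n, n), label="A")
            a_miss = make_mask([(0, 0)], (n, n), label="A")
            assert rotation_null(a_hit, b).null_percent == 100.0
            assert rotation_null(a_miss, b).null_percent == 0.0

    def test_centrosymmetric_mask_fixed_by_rotation(self):
        a = make_mask([(0, 0), (1, 1), (2, 2)], (4, 4), label="A")
        b = make_mask([(0, 0), (3, 3), (1, 2), (2, 1)], (4, 4), label="B")
        assert rotation_null(a, b).null_percent == coloc_percent(a, b).percent

    def test_independent_masks_null_matches_density(self, rng):
        """For independent uniform masks, E[null B_with_A] = 100 x p_A:
        Monte-Carlo over 1000 pairs stays within 3 standard errors."""
        p_a, p_b, n = 0.2, 0.3, 24
        nulls = []
        for _ in range(1000):
            a, b = make_mask([], (n, n), "A"), make_mask([], (n, n), "B")
            a.values = (rng.random((n, n)) < p_a).astype(np.uint8)
            b.values = (rng.random((n, n)) < p_b).astype(np.uint8)
            r = rotation_null(a, b)
            if r.null_defined:
                nulls.append(r.null_percent)
        mean = np.mean(nulls)
        sem = np.std(nulls, ddof=1) / np.sqrt(len(nulls))
        assert abs(mean - 100 * p_a) < 3 * sem


class TestSlabProjection:
    def test_paper_geometry_ten_slabs(self, rng):
        """50 slices at 100 nm spacing combine into ten 500 nm slabs."""
        stack = make_stack(rng.random((50, 8, 8)), z_spacing_nm=100.0)
        slabs = slab_project(stack, "ch0", 500.0)
        assert len(slabs) == 10
        assert all(s.n_slices == 5 and not s.partial for s in slabs)

    def test_slab_equal_spacing_is_identity(self, rng):
        vol = rng.random((4, 6, 6))
        stack = make_stack(vol, z_spacing_nm=100.0)
        slabs = slab_project(stack, "ch0", 100.0)
        assert len(slabs) == 4
        for i, s in enumerate(slabs):
            np.testing.assert_array_equal(s.plane, vol[i])

    def test_trailing_partial_slab_flagged(self, rng):
        stack = make_stack(rng.random((52, 6, 6)), z_spacing_nm=100.0)
        slabs = slab_project(stack, "ch0", 500.0)
        assert len(slabs) == 11
        assert slabs[-1].partial and slabs[-1].n_slices == 2
        assert not any(s.partial for s in slabs[:-1])

    def test_max_projection_within_slab(self):
        vol = np.zeros((5, 4, 4))
        vol[3, 2, 2] = 9.0
        stack = make_stack(vol, z_spacing_nm=100.0)
        assert slab_project(stack, "ch0", 500.0)[0].plane[2, 2] == 9.0

    def test_2d_input_is_a_geometry_error(self):
        stack = make_stack(np.ones((6, 6)))
        with pytest.raises(GeometryError):
            slab_project(stack, "ch0", 500.0)


class TestCellColoc:
    def test_single_slab_equals_plain_percent(self):
        spec = SyntheticSceneSpec(seed=3, coloc_fraction=0.5)
        stack, _ = simulate_scene(spec)
        res = cell_coloc(stack, "cargo", "marker")
        assert len(res.per_slab) == 1
        (_, num, den) = res.per_slab[0]
        assert (num, den) == (res.numerator_px, res.denominator_px)

    def test_pooled_counts_not_mean_of_ratios(self):
        """(1,4) and (3,4) pool to 50; (1,4) and (1,1) pool to 40, where a
        mean of slab ratios would give 62.5 — pooling is the contract."""
        assert 100 * (1 + 3) / (4 + 4) == 50.0
        assert 100 * (1 + 1) / (4 + 1) == 40.0
        # enforced on a real 3D stack: pooled result equals count sums
        spec = SyntheticSceneSpec(
            shape=(10, 128, 128), z_spacing_nm=100.0, seed=5, coloc_fraction=0.5,
            channels=(
                ChannelSpec(name="cargo", n_puncta=12),
                ChannelSpec(name="marker", n_puncta=12),
            ),
        )
        stack, _ = simulate_scene(spec)
        res = cell_coloc(stack, "cargo", "marker")
        assert res.numerator_px == sum(n for _, n, _ in res.per_slab)
        assert res.denominator_px == sum(d for _, _, d in res.per_slab)

    def test_zero_fraction_scene_measures_near_zero(self):
        spec = SyntheticSceneSpec(seed=11, coloc_fraction=0.0, min_sep_scope="all")
        stack, _ = simulate_scene(spec)
        res = cell_coloc(stack, "cargo", "marker")
        assert res.percent is not None and res.percent < 2.0

    def test_fixed_threshold_override_respected(self):
        spec = SyntheticSceneSpec(seed=7, coloc_fraction=1.0)
        stack, _ = simulate_scene(spec)
        thr = ThresholdConfig(values={"cargo": 5.0, "marker": 5.0})
        res = cell_coloc(stack, "cargo", "marker", thresholds=thr)
        assert res.thresholds == {"cargo": 5.0, "marker": 5.0}
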