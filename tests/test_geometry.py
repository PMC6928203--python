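"""Symmetric difference, perimeter and border-displacement metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from renaldwi import (
    border_displacement,
    displacement_harness,
    extract_border,
    harness_shapes,
    perimeter,
    symmetric_difference,
    translate_mask,
)

from conftest import disk_mask


class TestSymmetricDifference:
    def test_identical_masks(self):
        m = disk_mask(5)
        res = symmetric_difference(m, m)
        assert res.sym_diff == 0
        assert not res.map.any()

    def test_disjoint_masks_add(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[1:3, 1:6] = True   # 10 px
        b[10:11, 5:12] = True  # 7 px
        res = symmetric_difference(a, b)
        assert res.sym_diff == 17

    def test_sign_convention(self):
        """map = reference − test: +1 where only the reference is set
        (false negative), −1 where only the test is set."""
        test = np.zeros((4, 4), bool)
        ref = np.zeros((4, 4), bool)
        test[0, 0] = True
        ref[1, 1] = True
        res = symmetric_difference(test, ref)
        assert res.map[1, 1] == 1 and res.map[0, 0] == -1

    def test_shape_mismatch_error_states_shapes(self):
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(4, 4\)"):
            symmetric_difference(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(
        a=hnp.arrays(bool, (32, 32)),
        b=hnp.arrays(bool, (32, 32)),
    )
    @settings(max_examples=30, deadline=None)
    def test_count_equals_xor_tally_and_is_symmetric(self, a, b):
        """|A Δ B| equals the exhaustive per-pixel XOR tally; swapping
        the masks only flips the map sign."""
        tally = sum(
            bool(a[i, j]) != bool(b[i, j])
            for i in range(32) for j in range(32)
        )
        res = symmetric_difference(a, b)
        assert res.sym_diff == tally
        flipped = symmetric_difference(b, a)
        assert flipped.sym_diff == res.sym_diff
        np.testing.assert_array_equal(flipped.map, -res.map)

    def test_all_3x3_masks_against_reference(self):
        """Exhaustive check: every one of the 2⁹ 3×3 masks against a
        fixed reference matches brute-force XOR enumeration."""
        ref = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]], dtype=bool)
        for bits in itertools.product([0, 1], repeat=9):
            a = np.array(bits, dtype=bool).reshape(3, 3)
            expected = int(np.logical_xor(a, ref).sum())
            assert symmetric_difference(a, ref).sym_diff == expected

    def test_nested_masks_add_up(self):
        """For A ⊂ B ⊂ C: sym_diff(A,C) = sym_diff(A,B) + sym_diff(B,C)."""
        a, b, c = disk_mask(5, (40, 40)), disk_mask(9, (40, 40)), disk_mask(14, (40, 40))
        assert (
            symmetric_difference(a, c).sym_diff
            == symmetric_difference(a, b).sym_diff
            + symmetric_difference(b, c).sym_diff
        )


class TestBorderAndPerimeter:
    def test_single_pixel_is_its_own_border(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        np.testing.assert_array_equal(extract_border(m), m)
        assert perimeter(m) == 1

    def test_filled_square_frame(self):
        """A filled 5×5 square has a 16-pixel one-pixel-thick frame."""
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        border = extract_border(m)
        assert border.sum() == 16
        assert perimeter(m) == 16
        inner = np.zeros_like(m)
        inner[3:6, 3:6] = True
        np.testing.assert_array_equal(border, m & ~inner)

    def test_disk_border_count(self):
        """The 4-neighbour border of a digital disk counts its Chebyshev
        arc length 4√2·r (within 3%); frozen enumeration for r = 20: 112
        pixels, 10.9% below the Euclidean circumference 2πr."""
        m = disk_mask(20)
        count = perimeter(m)
        assert count == 112
        assert count == pytest.approx(4 * np.sqrt(2) * 20, rel=0.03)
        assert count == extract_border(m).sum()  # definitional consistency

    def test_crofton_estimator_tracks_euclidean_circumference(self):
        for r in (15, 30, 60):
            assert perimeter(disk_mask(r), estimator="crofton") == pytest.approx(
                2 * np.pi * r, rel=0.03
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_border(np.zeros((4, 4), bool))


class TestBorderDisplacement:
    def test_identical_masks_give_zero(self):
        m = disk_mask(12)
        assert border_displacement(m, m).bd == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            border_displacement(disk_mask(3), np.zeros((27, 27), bool))

    def test_shift_approaches_analytic_limit(self):
        """A d-px shift of a large disk: |A Δ B| ≈ 4rd and the Euclidean
        perimeter ≈ 2πr, so BD → 2d/π = 3.18 for d = 5 (arc-length
        estimator; ±0.3 discretization band, error shrinking with r)."""
        d = 5
        errs = []
        for r in (15, 30, 60):
            m = disk_mask(r)
            bd = border_displacement(
                translate_mask(m, (0, d)), m, estimator="crofton"
            ).bd
            assert bd == pytest.approx(2 * d / np.pi, abs=0.3)
            errs.append(abs(bd - 2 * d / np.pi))
        assert errs[-1] < errs[0]  # converges with object size

    def test_count_estimator_frozen_values(self):
        """Default (border-pixel-count) BD for a 5-px shift, frozen from
        enumeration: the count perimeter measures Chebyshev length, so
        the limit is d/√2 ≈ 3.54 rather than 2d/π."""
        expected = {15: 294 / 84, 30: 594 / 168, 60: 1194 / 336}
        for r, bd_ref in expected.items():
            m = disk_mask(r)
            res = border_displacement(translate_mask(m, (0, 5)), m)
            assert res.bd == pytest.approx(bd_ref, rel=1e-12)

    def test_size_and_shape_invariance(self):
        """The same 5-px shift on disks of radius 15/30/60 and on the
        kidney shape yields BDs agreeing pairwise within 25%."""
        masks = [disk_mask(r, (160, 160)) for r in (15, 30, 60)]
        masks.append(harness_shapes((160, 160))["kidney"])
        bds = [
            border_displacement(translate_mask(m, (0, 5)), m).bd for m in masks
        ]
        for x, y in itertools.combinations(bds, 2):
            assert abs(x - y) / min(x, y) < 0.25

    def test_multi_component_test_mask_warns(self):
        ref = disk_mask(10, (64, 64))
        test = ref.copy()
        test[2, 2] = True  # spurious speck
        with pytest.warns(UserWarning, match="components"):
            res = border_displacement(test, ref)
        assert res.bd == 0.0  # the speck is dropped


@pytest.fixture(scope="module")
def table():
    return displacement_harness(distances=(0, 5, 10))


class TestDisplacementHarness:
    def test_zero_displacement_zero_bd(self, table):
        assert (table.loc[table.d == 0, "bd"] == 0).all()

    def test_bd_linear_in_displacement(self, table):
        """BD at 10 px ≈ 2× BD at 5 px (within 15%) for every shape and
        direction: the translation symmetric difference is ~linear in d."""
        for (shape, direction), grp in table[table.d > 0].groupby(
            ["shape", "direction"]
        ):
            bd5 = grp.loc[grp.d == 5, "bd"].item()
            bd10 = grp.loc[grp.d == 10, "bd"].item()
            assert bd10 / bd5 == pytest.approx(2.0, rel=0.15)

    def test_horizontal_equals_vertical_on_circles(self, table):
        for shape in ("circle_small", "circle_large"):
            sel = table[table["shape"] == shape]
            for d in (5, 10):
                h = sel[(sel.direction == "horizontal") & (sel.d == d)]["bd"].item()
                v = sel[(sel.direction == "vertical") & (sel.d == d)]["bd"].item()
                assert h == pytest.approx(v, rel=0.02)

    def test_diagonal_larger_than_axis_aligned(self, table):
        """A (d, d) diagonal shift moves content by d√2, so its BD
        exceeds the axis-aligned BD at the same d."""
        for shape, grp in table[table.d == 5].groupby("shape"):
            diag = grp.loc[grp.direction == "diagonal", "bd"].item()
            horiz = grp.loc[grp.direction == "horizontal", "bd"].item()
            assert diag > horiz
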