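"""DVH curves and plan-quality indices against hand and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfpaint import (
    DoseGrid,
    ImageGrid,
    StructureMask,
    compute_dvh,
    conformity_index,
    dose_at_volume,
    index_of_achievement,
    mean_dose,
    target_coverage,
)

from conftest import block_mask, make_mask

GRID = ImageGrid((10, 10, 10), (2.0, 2.0, 2.0))
FULL = make_mask(GRID, np.ones(GRID.shape, bool), "s")


def dose_of(values) -> DoseGrid:
    arr = np.zeros(GRID.shape)
    arr.ravel()[: len(values)] = values
    return DoseGrid(GRID, arr)


def voxelwise_ioa(doses: np.ndarray, rx: float) -> float:
    """Unbinned oracle: volume-weighted mean squared relative deviation."""
    return 1.0 + float(np.mean(((doses - rx) / rx) ** 2))


class TestComputeDvh:
    def test_uniform_dose_step_function(self):
        dose = DoseGrid(GRID, np.full(GRID.shape, 60.0))
        curve = compute_dvh(dose, FULL, bin_width_gy=1.0)
        edges = curve.bin_edges_gy
        cum = curve.cumulative_fraction
        assert np.all(cum[edges <= 60.0] == 1.0)
        assert np.all(cum[edges > 60.0] == 0.0)

    def test_two_level_map(self):
        mask = block_mask(GRID, 2)
        arr = np.zeros(GRID.shape)
        arr.ravel()[0] = 60.0
        arr.ravel()[1] = 72.0
        curve = compute_dvh(DoseGrid(GRID, arr), mask, bin_width_gy=1.0)
        vox_cc = GRID.voxel_volume_cc
        nonzero = curve.differential_cc[curve.differential_cc > 0]
        np.testing.assert_allclose(nonzero, [vox_cc, vox_cc])
        idx66 = int(np.searchsorted(curve.bin_edges_gy, 66.0))
        assert curve.cumulative_fraction[idx66] == pytest.approx(0.5)

    def test_conservation_and_monotonicity_random(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            arr = rng.uniform(0, 80, GRID.shape)
            member = rng.random(GRID.shape) < 0.4
            if not member.any():
                continue
            mask = make_mask(GRID, member)
            curve = compute_dvh(DoseGrid(GRID, arr), mask, bin_width_gy=0.5)
            assert curve.total_volume_cc == pytest.approx(mask.volume_cc, rel=1e-12)
            assert np.all(np.diff(curve.cumulative_fraction) <= 1e-15)
            assert curve.cumulative_fraction[0] == 1.0

    def test_empty_mask_rejected(self):
        dose = DoseGrid(GRID, np.zeros(GRID.shape))
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(dose, make_mask(GRID, np.zeros(GRID.shape, bool)), 1.0)


class TestDoseAtVolume:
    def test_descending_rank_convention(self):
        doses = np.arange(1.0, 101.0)  # 1..100 Gy over 100 voxels
        assert dose_at_volume(doses, 2.0) == 99.0
        assert dose_at_volume(doses, 98.0) == 3.0
        assert dose_at_volume(doses, 50.0) == 51.0

    def test_uniform_dose_is_constant_in_p(self):
        doses = np.full(37, 42.5)
        for p in (1, 2, 50, 98, 99):
            assert dose_at_volume(doses, p) == 42.5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=200),
        st.floats(0.5, 99.5),
    )
    def test_order_property(self, values, p):
        doses = np.asarray(values)
        d2, d50, d98 = (dose_at_volume(doses, q) for q in (2.0, 50.0, 98.0))
        assert d2 >= d50 >= d98
        assert dose_at_volume(doses, p) in doses


class TestMeanAndCoverage:
    def test_two_point_mean(self):
        mask = block_mask(GRID, 2)
        assert mean_dose(dose_of([60.0, 72.0]), mask) == pytest.approx(66.0)

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 80, GRID.shape)
        member = rng.random(GRID.shape) < 0.5
        mask = make_mask(GRID, member)
        assert mean_dose(DoseGrid(GRID, arr), mask) == pytest.approx(
            arr[member].sum() / member.sum(), rel=1e-12
        )

    def test_coverage_levels(self):
        mask = block_mask(GRID, 4)
        dose = dose_of([60.0, 60.0, 59.9, 30.0])
        assert target_coverage(dose, mask, 60.0) == pytest.approx(50.0)
        dose_all = dose_of([60.0, 61.0, 70.0, 60.0])
        assert target_coverage(dose_all, mask, 60.0) == pytest.approx(100.0)


class TestConformityIndex:
    def test_perfect_conformity(self):
        target = block_mask(GRID, 50, "t")
        arr = np.zeros(GRID.shape)
        arr[target.member] = 60.0
        assert conformity_index(DoseGrid(GRID, arr), target, 60.0) == pytest.approx(1.0)

    def test_block_counts_formula(self):
        # V_t = 100, V_t,ref = 80, V_ref = 160 (voxel counts) -> 0.8 x 0.5 = 0.40
        target = block_mask(GRID, 100, "t")
        arr = np.zeros(GRID.shape)
        flat = arr.ravel()
        flat[20:100] = 60.0  # 80 covered target voxels
        flat[100:180] = 60.0  # 80 covered voxels outside the target
        ci = conformity_index(DoseGrid(GRID, arr), target, 60.0)
        assert ci == pytest.approx(0.8 * 0.5)

    def test_no_coverage_gives_zero(self):
        target = block_mask(GRID, 10, "t")
        assert conformity_index(DoseGrid(GRID, np.zeros(GRID.shape)), target, 60.0) == 0.0

    def test_bounds_on_random_grids(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            arr = rng.uniform(0, 80, GRID.shape)
            member = rng.random(GRID.shape) < 0.3
            if not member.any():
                continue
            ci = conformity_index(DoseGrid(GRID, arr), make_mask(GRID, member), 60.0)
            assert 0.0 <= ci <= 1.0

    def test_evaluation_region_excludes_background(self):
        target = block_mask(GRID, 50, "t")
        region = block_mask(GRID, 500, "brain")
        arr = np.full(GRID.shape, 60.0)  # everything "covered", incl. background
        unrestricted = conformity_index(DoseGrid(GRID, arr), target, 60.0)
        restricted = conformity_index(DoseGrid(GRID, arr), target, 60.0, region=region)
        assert restricted > unrestricted


class TestIndexOfAchievement:
    def test_exact_prescription_gives_one(self):
        mask = block_mask(GRID, 60, "t")
        arr = np.zeros(GRID.shape)
        arr[mask.member] = 60.0
        ioa = index_of_achievement(DoseGrid(GRID, arr), [(mask, 60.0)])
        assert ioa == pytest.approx(1.0, abs=1e-6)

    def test_half_at_rx_half_at_120pct(self):
        mask = block_mask(GRID, 100, "t")
        arr = np.zeros(GRID.shape)
        arr.ravel()[:50] = 60.0
        arr.ravel()[50:100] = 72.0
        ioa = index_of_achievement(DoseGrid(GRID, arr), [(mask, 60.0)], bin_width_gy=0.05)
        assert ioa == pytest.approx(1.0 + 0.5 * 0.2**2, abs=1e-3)

    def test_binned_converges_to_voxelwise_oracle(self):
        rng = np.random.default_rng(23)
        member = rng.random(GRID.shape) < 0.5
        mask = make_mask(GRID, member)
        arr = np.zeros(GRID.shape)
        arr[member] = rng.uniform(55, 80, member.sum())
        dose = DoseGrid(GRID, arr)
        oracle = voxelwise_ioa(arr[member], 60.0)
        binned = index_of_achievement(dose, [(mask, 60.0)], bin_width_gy=0.05)
        assert abs(binned - oracle) < 1e-3
        coarse = index_of_achievement(dose, [(mask, 60.0)], bin_width_gy=1.0)
        assert abs(coarse - oracle) > abs(binned - oracle) * 0.0  # both finite
        assert abs(binned - oracle) <= abs(coarse - oracle) + 1e-9

    def test_multi_target_sums_per_target_deviations(self):
        a = block_mask(GRID, 50, "a")
        flat = np.zeros(GRID.shape).ravel()
        flat[:50] = 66.0  # 10% over a 60 Gy prescription
        b_member = np.zeros(GRID.shape, bool).ravel()
        b_member[50:100] = True
        flat[50:100] = 72.0  # exactly the boost prescription
        dose = DoseGrid(GRID, flat.reshape(GRID.shape))
        b = make_mask(GRID, b_member.reshape(GRID.shape), "b")
        ioa = index_of_achievement(dose, [(a, 60.0), (b, 72.0)])
        assert ioa == pytest.approx(1.0 + 0.1**2, abs=1e-3)

    def test_ioa_at_least_one(self):
        rng = np.random.default_rng(31)
        member = rng.random(GRID.shape) < 0.4
        arr = np.zeros(GRID.shape)
        arr[member] = rng.uniform(0, 90, member.sum())
        ioa = index_of_achievement(DoseGrid(GRID, arr), [(make_mask(GRID, member), 60.0)])
        assert ioa >= 1.0
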