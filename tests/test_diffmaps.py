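"""Difference maps, half-split controls, contour counts, displacements."""
import numpy as np
import pytest

from xtal2d import (
    ContourCount,
    DifferenceMap,
    PeakRegion,
    ProjectionMap,
    count_contours,
    estimate_displacement,
    half_split_control,
    resample_common_cell,
    simulate_condition,
    structure_factors,
    subtract_maps,
    synthesize_map,
    UnitCell2D,
)
from xtal2d.diffmaps import ControlError, DetectionError, RegionError
from xtal2d.geometry import GeometryError
from xtal2d.presets import (
    BINDING_TRUTH,
    GRID,
    NOISE_SIGMA,
    build_apo_model,
    build_bound_model,
)


@pytest.fixture(scope="module")
def apo_map(apo_model):
    return synthesize_map(structure_factors(apo_model, 6.0), GRID)


@pytest.fixture(scope="module")
def bound_map(bound_model):
    return synthesize_map(structure_factors(bound_model, 6.0), GRID)


# --------------------------------------------------------------- resampling
def test_resample_same_cell_is_identity(apo_map):
    out = resample_common_cell(apo_map, apo_map.cell, apo_map.shape)
    assert np.allclose(out.grid, apo_map.grid)


def test_resample_constant_map_stays_constant():
    cell_a, cell_b = UnitCell2D(81.2, 104.2), UnitCell2D(80.6, 107.9)
    pmap = ProjectionMap(grid=np.full((32, 40), 3.7), cell=cell_a)
    out = resample_common_cell(pmap, cell_b, (48, 56))
    assert np.allclose(out.grid, 3.7)
    assert out.cell == cell_b


def test_resample_between_study_cells_preserves_mean(bound_map, apo_map):
    out = resample_common_cell(bound_map, apo_map.cell, (96, 120))
    scale = max(abs(bound_map.mean), bound_map.sigma)
    assert abs(out.mean - bound_map.mean) <= 0.01 * scale


def test_resample_rejects_large_cell_mismatch(apo_map):
    with pytest.raises(GeometryError):
        resample_common_cell(apo_map, UnitCell2D(60.0, 104.2), apo_map.shape)


# --------------------------------------------------------------- subtraction
def test_self_difference_is_identically_zero(apo_map):
    diff = subtract_maps(apo_map, apo_map, contour_step=1.0)
    assert np.all(diff.grid == 0.0)


def test_subtraction_antisymmetry(apo_map, bound_map):
    b = resample_common_cell(bound_map, apo_map.cell, apo_map.shape)
    d1 = subtract_maps(apo_map, b, contour_step=1.0)
    d2 = subtract_maps(b, apo_map, contour_step=1.0)
    assert np.allclose(d1.grid, -d2.grid)


def test_two_state_difference_strongest_in_helix_pair_region(
    apo_map, bound_map, regions
):
    """The dominant positive/negative pair localizes to the 5c/12e region."""
    b = resample_common_cell(bound_map, apo_map.cell, apo_map.shape)
    diff = subtract_maps(b, apo_map, contour_step=1.0)
    m1 = regions["set1_5c12e"].mask(diff.cell, diff.grid.shape)
    in_p2t = diff.grid[m1].max() - diff.grid[m1].min()
    for rid, region in regions.items():
        if rid == "set1_5c12e":
            continue
        m = region.mask(diff.cell, diff.grid.shape)
        assert diff.grid[m].max() - diff.grid[m].min() < in_p2t
    # and no declared no-change region comes close
    m_ctrl = regions["bundle_left_4_11_12c"].mask(diff.cell, diff.grid.shape)
    assert diff.grid[m_ctrl].max() - diff.grid[m_ctrl].min() < 0.35 * in_p2t


def test_grid_mismatch_rejected(apo_map):
    other = ProjectionMap(grid=np.zeros((16, 16)), cell=apo_map.cell)
    with pytest.raises(GeometryError):
        subtract_maps(apo_map, other, contour_step=1.0)


# --------------------------------------------------------------- counting
def _region_at(cell, x, y, r=4.0):
    return PeakRegion(id="probe", center=(x, y), semi_axes=(r, r))


def test_contour_count_floor_arithmetic():
    cell = UnitCell2D(40.0, 50.0)
    grid = np.zeros((40, 50))
    grid[10, 12] = 4.6   # region max = 4.6 steps
    grid[11, 13] = -3.2  # region min = -3.2 steps
    diff = DifferenceMap(grid=grid, cell=cell, contour_step=1.0)
    cc = count_contours(diff, _region_at(cell, 10.0, 12.0, r=4.0))
    assert (cc.positive_levels, cc.negative_levels, cc.peak_to_trough) == (4, 3, 7)


def test_contour_count_zero_map():
    cell = UnitCell2D(40.0, 50.0)
    diff = DifferenceMap(grid=np.zeros((40, 50)), cell=cell, contour_step=1.0)
    cc = count_contours(diff, _region_at(cell, 20.0, 25.0))
    assert (cc.positive_levels, cc.negative_levels, cc.peak_to_trough) == (0, 0, 0)


def test_contour_count_negation_swaps_signs():
    cell = UnitCell2D(40.0, 50.0)
    rng = np.random.default_rng(3)
    diff = DifferenceMap(grid=rng.normal(0, 1, (40, 50)), cell=cell, contour_step=0.7)
    region = _region_at(cell, 20.0, 25.0, r=6.0)
    cc = count_contours(diff, region)
    nn = count_contours(diff.negated(), region)
    assert (nn.positive_levels, nn.negative_levels) == (
        cc.negative_levels, cc.positive_levels
    )
    assert nn.peak_to_trough == cc.peak_to_trough


def test_empty_region_rejected():
    cell = UnitCell2D(40.0, 50.0)
    diff = DifferenceMap(grid=np.zeros((8, 8)), cell=cell, contour_step=1.0)
    with pytest.raises(RegionError):
        # ellipse smaller than the pixel spacing, centered between pixels
        count_contours(diff, PeakRegion(id="x", center=(2.6, 3.2), semi_axes=(0.4, 0.4)))


def test_contour_count_invariant():
    cc = ContourCount(region_id="x", positive_levels=4, negative_levels=3)
    assert cc.peak_to_trough >= max(cc.positive_levels, cc.negative_levels)


# --------------------------------------------------------------- half-split
def _condition_lattices(n=6, noise=NOISE_SIGMA, seed=0, na=0.0, ph=8.0):
    apo, bound = build_apo_model(), build_bound_model()
    return simulate_condition(apo, bound, BINDING_TRUTH.at_ph(ph), na, n, noise, seed)


def test_half_split_needs_two_lattices():
    lats = _condition_lattices(n=2, noise=0.0)
    with pytest.raises(ControlError):
        half_split_control(lats[:1], seed=0)


def test_half_split_zero_noise_gives_empty_control():
    lats = _condition_lattices(n=4, noise=0.0, seed=1)
    control, background = half_split_control(lats, seed=5, grid=(64, 80))
    assert background == 0
    assert control.contour_step == 1e-12  # configured minimum
    # residue only at the numerical precision of the origin refinement
    assert np.max(np.abs(control.grid)) < 1e-6


def test_half_split_identical_lattices_is_exactly_zero():
    lats = _condition_lattices(n=1, noise=0.0, seed=1) * 2
    control, background = half_split_control(lats, seed=5, grid=(64, 80))
    assert background == 0
    assert np.allclose(control.grid, 0.0, atol=1e-9)


def test_half_split_background_is_about_two_levels():
    """Default calibration: the 1.5 sigma contour step puts the control-map
    extremes at ~3 sigma, i.e. a +/-2-level background."""
    bgs = [
        half_split_control(_condition_lattices(seed=s), seed=100 + s, grid=GRID)[1]
        for s in range(5)
    ]
    assert int(np.median(bgs)) == 2
    assert all(b in (2, 3) for b in bgs)


def test_half_split_noise_scales_inverse_sqrt_lattices():
    sig6 = [
        half_split_control(_condition_lattices(n=6, seed=s), seed=s, grid=(64, 80))[0].sigma
        for s in range(6)
    ]
    sig12 = [
        half_split_control(_condition_lattices(n=12, seed=s), seed=s, grid=(64, 80))[0].sigma
        for s in range(6)
    ]
    ratio = np.mean(sig6) / np.mean(sig12)
    assert ratio == pytest.approx(np.sqrt(2.0), rel=0.2)


def test_half_split_background_independent_of_occupancy():
    """Controls split same-condition data, so the conformational signal
    cancels: the noise floor at saturating sodium matches the sodium-free one."""
    s_apo = [
        half_split_control(_condition_lattices(na=0.0, seed=s), seed=s, grid=(64, 80))[0].sigma
        for s in range(5)
    ]
    s_sat = [
        half_split_control(_condition_lattices(na=500.0, seed=s), seed=s, grid=(64, 80))[0].sigma
        for s in range(5)
    ]
    assert np.mean(s_sat) == pytest.approx(np.mean(s_apo), rel=0.15)


# --------------------------------------------------------------- displacement
def test_identical_maps_have_zero_displacement(apo_map, regions):
    assert estimate_displacement(apo_map, apo_map, regions["set1_5c12e"]) == 0.0


def test_two_angstrom_shift_recovered(apo_map, bound_map, regions):
    b = resample_common_cell(bound_map, apo_map.cell, apo_map.shape)
    d = estimate_displacement(apo_map, b, regions["set1_5c12e"])
    assert d == pytest.approx(2.0, abs=0.2)


def test_displacement_estimates_are_ordered(small_cell, regions):
    """1 A vs 3 A ground-truth shifts give monotonically ordered estimates."""
    from xtal2d import ConformationModel, HelixRod

    base = ConformationModel(
        "apo", (HelixRod.make("a", 15.0, 20.0, 3.0),), small_cell, dimer_op=None
    )
    region = PeakRegion(id="probe", center=(15.5, 21.0), semi_axes=(6.0, 6.0))
    estimates = []
    for shift in (1.0, 2.0, 3.0):
        moved = ConformationModel(
            "apo", (base.rods[0].shifted((shift * 0.6, shift * 0.8)),),
            small_cell, dimer_op=None,
        )
        ma = synthesize_map(structure_factors(base, 6.0), (64, 80))
        mb = synthesize_map(structure_factors(moved, 6.0), (64, 80))
        estimates.append(estimate_displacement(ma, mb, region))
        assert estimates[-1] == pytest.approx(shift, abs=0.1 * shift + 0.1)
    assert estimates[0] < estimates[1] < estimates[2]


def test_no_peak_raises_detection_error(small_cell):
    flat = ProjectionMap(grid=np.zeros((32, 40)), cell=small_cell)
    with pytest.raises(DetectionError):
        estimate_displacement(flat, flat, PeakRegion(id="x", center=(20, 25), semi_axes=(5, 5)))
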