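"""Watershed module: oracle equivalences, invariants, and examples."""

import numpy as np
import pytest

from oligotrend.raster import GridRaster
from oligotrend.watershed import (
    NEIGHBOR_OFFSETS,
    areas,
    compute_d8,
    delineate,
    fill_depressions,
    flow_accumulation,
    snap_outlet,
)

from conftest import make_tilted_plane, random_dem


# ---------------------------------------------------------------------------
# independent oracles


def fill_oracle(dem: GridRaster, max_sweeps: int = 10_000) -> np.ndarray:
    """Brute-force raise-until-drained relaxation.

    filled = z on the boundary; elsewhere iterate
    filled[c] = max(z[c], min over neighbors of filled) to a fixpoint.
    """
    z = dem.values.astype(float)
    nrows, ncols = z.shape
    filled = np.full_like(z, np.inf)
    filled[0, :] = z[0, :]
    filled[-1, :] = z[-1, :]
    filled[:, 0] = z[:, 0]
    filled[:, -1] = z[:, -1]
    for _ in range(max_sweeps):
        changed = False
        for r in range(1, nrows - 1):
            for c in range(1, ncols - 1):
                nbr_min = min(
                    filled[r + dr, c + dc] for dr, dc in NEIGHBOR_OFFSETS
                )
                new = max(z[r, c], nbr_min)
                if new < filled[r, c]:
                    filled[r, c] = new
                    changed = True
        if not changed:
            return filled
    raise RuntimeError("fill oracle did not converge")


def follow_path(flow, r, c):
    """Cells visited by following D8 codes from (r, c), outlet included."""
    nrows, ncols = flow.shape
    seen = []
    steps = 0
    while True:
        seen.append((r, c))
        ds = flow.downstream(r, c)
        if ds is None:
            return seen
        r, c = ds
        steps += 1
        if steps > nrows * ncols:
            raise AssertionError("D8 path did not terminate (cycle)")


def delineate_oracle(flow, outlet):
    """Follow D8 from every cell; keep cells whose path hits the outlet."""
    nrows, ncols = flow.shape
    mask = np.zeros((nrows, ncols), dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            if flow.valid[r, c] and outlet in follow_path(flow, r, c):
                mask[r, c] = True
    return mask


def accumulation_oracle(flow):
    nrows, ncols = flow.shape
    acc = np.zeros((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            if flow.valid[r, c]:
                for cell in follow_path(flow, r, c):
                    acc[cell] += 1
    return acc


# ---------------------------------------------------------------------------
# fill_depressions


def test_fill_tilted_plane_unchanged():
    dem = make_tilted_plane()
    filled = fill_depressions(dem)
    np.testing.assert_array_equal(filled.values, dem.values)


def test_fill_single_pit_raised_to_min_neighbor():
    dem = make_tilted_plane(8, 8, slope=0.0)
    z = dem.values.copy()
    z[:, :] = 5.0
    z[4, 4] = 1.0
    dem = GridRaster(values=z, cell_size=100.0)
    filled = fill_depressions(dem)
    # epsilon-free policy: pit raised exactly to the spill (min neighbor)
    assert filled.values[4, 4] == 5.0
    np.testing.assert_array_equal(np.delete(filled.values.ravel(), 4 * 8 + 4),
                                  np.delete(z.ravel(), 4 * 8 + 4))


@pytest.mark.parametrize("seed", range(5))
def test_fill_matches_bruteforce_oracle_30x30(seed):
    rng = np.random.default_rng(seed)
    dem = random_dem(rng, 30, 30)
    filled = fill_depressions(dem)
    expected = fill_oracle(dem)
    np.testing.assert_allclose(filled.values, expected, atol=1e-12)


def test_fill_idempotent(rng):
    dem = random_dem(rng)
    once = fill_depressions(dem)
    twice = fill_depressions(once)
    np.testing.assert_array_equal(once.values, twice.values)


def test_fill_never_lowers(rng):
    dem = random_dem(rng)
    filled = fill_depressions(dem)
    assert np.all(filled.values >= dem.values - 1e-12)


def test_fill_all_nodata_fails():
    dem = GridRaster(values=np.full((8, 8), -9999.0), nodata=-9999.0)
    with pytest.raises(ValueError):
        fill_depressions(dem)


# ---------------------------------------------------------------------------
# compute_d8


def test_d8_plane_dipping_east_codes_east():
    # values decrease with column -> east (code 1) everywhere it can flow
    dem = make_tilted_plane(6, 8, slope=-1.0)
    flow = compute_d8(fill_depressions(dem))
    # every cell with a lower neighbor points east; the flat last column
    # drains along the edge to its first-popped (sink) cell
    assert np.all(flow.codes[:, :-1] == 1)
    assert flow.codes[0, -1] == 0
    assert np.all(flow.codes[1:, -1] == 3)  # south toward the sink


def test_d8_symmetric_tie_takes_first_neighbor_in_order():
    # center cell with equal drop to all 8 neighbors: E (code 1) wins
    z = np.full((3, 3), 1.0)
    z[1, 1] = 2.0
    flow = compute_d8(GridRaster(values=z, cell_size=100.0))
    assert flow.codes[1, 1] == 1


@pytest.mark.parametrize("seed", range(5))
def test_d8_paths_terminate_at_edge(seed):
    rng = np.random.default_rng(100 + seed)
    dem = random_dem(rng)
    flow = compute_d8(fill_depressions(dem))
    nrows, ncols = flow.shape
    for r in range(nrows):
        for c in range(ncols):
            path = follow_path(flow, r, c)  # raises on cycle
            er, ec = path[-1]
            assert er in (0, nrows - 1) or ec in (0, ncols - 1)


def test_d8_descends_on_filled(rng):
    dem = random_dem(rng)
    filled = fill_depressions(dem)
    flow = compute_d8(filled)
    for r in range(flow.shape[0]):
        for c in range(flow.shape[1]):
            ds = flow.downstream(r, c)
            if ds is not None:
                assert filled.values[ds] <= filled.values[r, c] + 1e-12


# ---------------------------------------------------------------------------
# flow_accumulation


def test_accumulation_chain():
    # 1x5 line all flowing right (east): accumulations 1..5
    from oligotrend.watershed import D8FlowField

    codes = np.array([[1, 1, 1, 1, 0]], dtype=np.int8)
    flow = D8FlowField(codes=codes, valid=np.ones((1, 5), dtype=bool))
    acc = flow_accumulation(flow)
    np.testing.assert_array_equal(acc.values, [[1, 2, 3, 4, 5]])


def test_accumulation_head_cells_are_one():
    dem = make_tilted_plane(6, 8, slope=-1.0)  # flows east
    flow = compute_d8(fill_depressions(dem))
    acc = flow_accumulation(flow)
    np.testing.assert_array_equal(acc.values[:, 0], np.ones(6))


@pytest.mark.parametrize("seed", range(5))
def test_accumulation_matches_bfs_oracle_20x20(seed):
    rng = np.random.default_rng(200 + seed)
    dem = random_dem(rng)
    flow = compute_d8(fill_depressions(dem))
    acc = flow_accumulation(flow)
    np.testing.assert_allclose(acc.values, accumulation_oracle(flow))


def test_accumulation_conservation(rng):
    # sum of accumulation at sink cells = number of valid cells
    dem = random_dem(rng)
    flow = compute_d8(fill_depressions(dem))
    acc = flow_accumulation(flow)
    sinks = flow.codes == 0
    assert acc.values[sinks].sum() == flow.valid.sum()


def test_accumulation_cycle_detected():
    from oligotrend.watershed import D8FlowField

    codes = np.array([[1, 5]], dtype=np.int8)  # two cells pointing at each other
    flow = D8FlowField(codes=codes, valid=np.ones((1, 2), dtype=bool))
    with pytest.raises(ValueError, match="cycle"):
        flow_accumulation(flow)


# ---------------------------------------------------------------------------
# snap_outlet


def _accum_for(dem):
    flow = compute_d8(fill_depressions(dem))
    return flow_accumulation(flow)


def test_snap_identity_radius_zero():
    dem = make_tilted_plane(6, 8, slope=-1.0, cell_size=100.0)
    acc = _accum_for(dem)
    # max accumulation in row 2 is at the east edge; point on that cell
    x, y = acc.cell_center(2, 7)
    assert snap_outlet((x, y), acc, radius=0.0) == (2, 7)


def test_snap_to_river_one_cell_off():
    # build a strong river line along row 3 by carving a valley
    z = np.abs(np.arange(10)[:, None] - 3) * 5.0 + np.arange(12)[None, :] * -0.1
    dem = GridRaster(values=z.astype(float), cell_size=100.0)
    acc = _accum_for(dem)
    x, y = acc.cell_center(4, 5)  # one row off the valley line
    r, c = snap_outlet((x, y), acc, radius=2 * acc.cell_size)
    assert r == 3  # snapped onto the valley


@pytest.mark.parametrize("seed", range(10))
def test_snap_never_decreases_accumulation(seed):
    rng = np.random.default_rng(300 + seed)
    dem = random_dem(rng, 15, 15)
    acc = _accum_for(dem)
    r0 = int(rng.integers(0, 15))
    c0 = int(rng.integers(0, 15))
    x, y = acc.cell_center(r0, c0)
    r, c = snap_outlet((x, y), acc, radius=3 * acc.cell_size)
    assert acc.values[r, c] >= acc.values[r0, c0]


def test_snap_no_cell_in_radius_fails():
    dem = make_tilted_plane()
    acc = _accum_for(dem)
    with pytest.raises(ValueError):
        snap_outlet((-1e6, -1e6), acc, radius=10.0)


# ---------------------------------------------------------------------------
# delineate


@pytest.mark.parametrize("seed", range(5))
def test_delineate_matches_path_following_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    dem = random_dem(rng)
    flow = compute_d8(fill_depressions(dem))
    acc = flow_accumulation(flow)
    outlet = tuple(int(v) for v in np.unravel_index(np.argmax(acc.values),
                                                    acc.values.shape))
    np.testing.assert_array_equal(delineate(flow, outlet),
                                  delineate_oracle(flow, outlet))


def test_delineate_source_cell_is_singleton():
    dem = make_tilted_plane(6, 8, slope=-1.0)  # flows east
    flow = compute_d8(fill_depressions(dem))
    mask = delineate(flow, (3, 0))  # westmost cell has no upstream
    assert mask.sum() == 1 and mask[3, 0]


def test_delineate_nestedness(rng):
    dem = random_dem(rng)
    flow = compute_d8(fill_depressions(dem))
    # walk two cells on one stream: downstream basin contains upstream basin
    upstream = (10, 10)
    ds = flow.downstream(*upstream)
    if ds is None:
        pytest.skip("picked a sink")
    m_up = delineate(flow, upstream)
    m_down = delineate(flow, ds)
    assert np.all(m_down[m_up])


def test_watershed_masks_200_random_20x20_grids():
    """Acceptance 5a: traversal equals brute-force oracle on 200 DEMs."""
    rng = np.random.default_rng(9999)
    for _ in range(200):
        dem = random_dem(rng, 20, 20)
        flow = compute_d8(fill_depressions(dem))
        acc = flow_accumulation(flow)
        outlet = tuple(
            int(v)
            for v in np.unravel_index(np.argmax(acc.values), acc.values.shape)
        )
        np.testing.assert_array_equal(
            delineate(flow, outlet), delineate_oracle(flow, outlet)
        )


# ---------------------------------------------------------------------------
# areas


def test_areas_unit_arithmetic():
    mask = np.zeros((20, 20), dtype=bool)
    mask.ravel()[:100] = True
    catch, lake, drain = areas(mask, np.zeros_like(mask), cell_size=100.0)
    assert catch == pytest.approx(1.0)
    assert lake == 0.0 and drain == pytest.approx(1.0)


def test_areas_subtraction():
    catchment = np.zeros((60, 60), dtype=bool)
    catchment.ravel()[:2500] = True
    lake = np.zeros_like(catchment)
    lake.ravel()[:36] = True
    c, l, d = areas(catchment, lake, cell_size=100.0)
    assert (c, l, d) == pytest.approx((25.0, 0.36, 24.64))


def test_areas_lake_fixture_946_077():
    # catchment 9.46 km2 and lake 0.77 km2 at 100 m cells -> drainage 8.69
    catchment = np.zeros((40, 40), dtype=bool)
    catchment.ravel()[:946] = True
    lake = np.zeros_like(catchment)
    lake.ravel()[:77] = True
    c, l, d = areas(catchment, lake, cell_size=100.0)
    assert c == pytest.approx(9.46)
    assert l == pytest.approx(0.77)
    assert d == pytest.approx(8.69)


def test_areas_lake_outside_catchment_fails():
    catchment = np.zeros((5, 5), dtype=bool)
    catchment[0, 0] = True
    lake = np.zeros_like(catchment)
    lake[4, 4] = True
    with pytest.raises(ValueError):
        areas(catchment, lake, cell_size=100.0)
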