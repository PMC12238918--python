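"""Lake catchment delineation from a DEM.

Pipeline: depression filling (priority-flood, epsilon-free), D8 flow
directions, flow accumulation, outlet snapping, and upstream basin
traversal.  Areas are reported in km² with drainage = catchment − lake.

Conventions
-----------
Neighbor order and direction codes are fixed as::

    1=E, 2=SE, 3=S, 4=SW, 5=W, 6=NW, 7=N, 8=NE    (0 = sink / edge outlet)

with row 0 the southernmost row, so "south" decreases the row index.
Ties in steepest descent are broken by the first neighbor in that order.
Flats are resolved by the breadth-first pop order of the priority-flood
pass: a flat cell drains to the equal-elevation neighbor that was reached
first from the grid edge, which guarantees a cycle-free field.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = [
    "D8FlowField",
    "LakeSite",
    "NEIGHBOR_OFFSETS",
    "fill_depressions",
    "compute_d8",
    "flow_accumulation",
    "snap_outlet",
    "delineate",
    "areas",
]

# (drow, dcol) for codes 1..8: E, SE, S, SW, W, NW, N, NE.
# Row 0 is southernmost, so S = row-1 and N = row+1.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 1 E
    (-1, 1),   # 2 SE
    (-1, 0),   # 3 S
    (-1, -1),  # 4 SW
    (0, -1),   # 5 W
    (1, -1),   # 6 NW
    (1, 0),    # 7 N
    (1, 1),    # 8 NE
)

_DIAG = {2, 4, 6, 8}


@dataclass
class D8FlowField:
    """Single-flow-direction field; ``codes[r, c]`` ∈ 0..8.

    Code 0 marks a sink/edge outlet (no downstream neighbor inside the
    grid); codes 1–8 index :data:`NEIGHBOR_OFFSETS`.
    """

    codes: np.ndarray
    valid: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def downstream(self, row: int, col: int) -> tuple[int, int] | None:
        """Downstream cell index, or None for a sink/outlet."""
        code = int(self.codes[row, col])
        if code == 0:
            return None
        dr, dc = NEIGHBOR_OFFSETS[code - 1]
        return row + dr, col + dc


@dataclass
class LakeSite:
    """A study lake with its delineated masks and areas."""

    id: str
    name: str = ""
    outlet_xy: tuple[float, float] | None = None
    lake_mask: GridRaster | None = None
    catchment_mask: GridRaster | None = None
    catchment_km2: float | None = None
    lake_km2: float | None = None
    drainage_km2: float | None = None


def _priority_flood(dem: GridRaster) -> tuple[np.ndarray, np.ndarray]:
    """Epsilon-free priority-flood fill.

    Returns ``(filled, order)`` where ``order[r, c]`` is the pop sequence
    number of each cell.  Cells are popped in nondecreasing filled
    elevation, FIFO within ties (breadth-first across flats), so ``order``
    gives every flat cell a defined path toward its spill point.
    """
    valid = dem.valid_mask()
    if not valid.any():
        raise ValueError("all-nodata raster cannot be filled")
    nrows, ncols = dem.shape
    z = np.asarray(dem.values, dtype=float)
    filled = np.where(valid, z, np.inf)
    closed = np.zeros((nrows, ncols), dtype=bool)
    order = np.full((nrows, ncols), -1, dtype=np.int64)

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # Seed with valid edge cells and valid cells adjacent to nodata holes
    # (holes drain out of the modeled domain).
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            edge = r in (0, nrows - 1) or c in (0, ncols - 1)
            if not edge:
                for dr, dc in NEIGHBOR_OFFSETS:
                    rr, cc = r + dr, c + dc
                    if not valid[rr, cc]:
                        edge = True
                        break
            if edge:
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1
                closed[r, c] = True

    pop_seq = 0
    while heap:
        elev, _, r, c = heapq.heappop(heap)
        filled[r, c] = elev
        order[r, c] = pop_seq
        pop_seq += 1
        for dr, dc in NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols):
                continue
            if closed[rr, cc] or not valid[rr, cc]:
                continue
            closed[rr, cc] = True
            heapq.heappush(heap, (max(z[rr, cc], elev), counter, rr, cc))
            counter += 1
    return np.where(valid, filled, dem.nodata), order


def fill_depressions(dem: GridRaster) -> GridRaster:
    """Raise closed depressions to their spill elevation.

    Output elevations are ≥ input everywhere, already-drained cells are
    unchanged, and every valid cell gains a non-ascending D8 path to the
    grid edge (flats permitted; see module docstring for their resolution).
    """
    filled, _ = _priority_flood(dem)
    return dem.like(filled)


def compute_d8(filled: GridRaster) -> D8FlowField:
    """Steepest-descent D8 directions on a depression-free DEM.

    Drop is measured as (elevation difference) / distance with diagonal
    distance ``cell_size * sqrt(2)``.  Ties take the first neighbor in the
    documented E, SE, S, SW, W, NW, N, NE order.  A cell with no lower
    neighbor (a flat) drains to the equal-elevation neighbor with the
    smallest priority-flood pop order below its own; edge cells with no
    receiving neighbor are sinks (code 0).
    """
    _, order = _priority_flood(filled)
    valid = filled.valid_mask()
    z = np.asarray(filled.values, dtype=float)
    nrows, ncols = filled.shape
    codes = np.zeros((nrows, ncols), dtype=np.int8)
    sqrt2 = np.sqrt(2.0)

    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            best_code = 0
            best_drop = 0.0
            flat_code = 0
            flat_order = order[r, c]
            for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS, start=1):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols) or not valid[rr, cc]:
                    continue
                dz = z[r, c] - z[rr, cc]
                if dz > 0:
                    drop = dz / (sqrt2 if k in _DIAG else 1.0)
                    if drop > best_drop:  # strict: first-in-order wins ties
                        best_drop = drop
                        best_code = k
                elif dz == 0 and order[rr, cc] < flat_order:
                    flat_order = order[rr, cc]
                    flat_code = k
            if best_code:
                codes[r, c] = best_code
            elif flat_code:
                codes[r, c] = flat_code
            # else: sink/edge outlet, stays 0
    return D8FlowField(
        codes=codes,
        valid=valid,
        x_origin=filled.x_origin,
        y_origin=filled.y_origin,
        cell_size=filled.cell_size,
    )


def flow_accumulation(flow: D8FlowField) -> GridRaster:
    """Cells draining through each cell, the cell itself included.

    Processes cells in topological order (Kahn's algorithm on the flow
    graph); a residual cycle is reported with a member cell.
    """
    nrows, ncols = flow.shape
    valid = flow.valid
    accum = np.where(valid, 1.0, 0.0)
    indeg = np.zeros((nrows, ncols), dtype=np.int32)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            ds = flow.downstream(r, c)
            if ds is not None:
                indeg[ds] += 1

    queue = deque(
        (r, c)
        for r in range(nrows)
        for c in range(ncols)
        if valid[r, c] and indeg[r, c] == 0
    )
    processed = 0
    n_valid = int(valid.sum())
    while queue:
        r, c = queue.popleft()
        processed += 1
        ds = flow.downstream(r, c)
        if ds is not None:
            accum[ds] += accum[r, c]
            indeg[ds] -= 1
            if indeg[ds] == 0:
                queue.append(ds)
    if processed != n_valid:
        leftover = np.argwhere(valid & (indeg > 0))
        cell = tuple(int(v) for v in leftover[0])
        raise ValueError(f"flow field contains a cycle through cell {cell}")
    return GridRaster(
        values=np.where(valid, accum, -1.0),
        x_origin=flow.x_origin,
        y_origin=flow.y_origin,
        cell_size=flow.cell_size,
        nodata=-1.0,
    )


def snap_outlet(
    point: tuple[float, float],
    accum: GridRaster,
    radius: float = 250.0,
) -> tuple[int, int]:
    """Snap a sample-site coordinate to the nearby cell of maximal flow
    accumulation.

    Candidates are valid cells whose centers lie within ``radius`` meters
    of ``point``; ties on accumulation go to the nearest candidate, then
    to row-major scan order (row 0 = southernmost).
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    x, y = point
    valid = accum.valid_mask()
    cs = accum.cell_size
    best: tuple[float, float, int, int] | None = None  # (-acc, dist, r, c)
    try:
        # the containing cell is always a candidate, even at radius 0
        hr, hc = accum.point_to_cell(x, y)
        if valid[hr, hc]:
            best = (-float(accum.values[hr, hc]), 0.0, hr, hc)
    except ValueError:
        pass
    r0 = max(0, int(np.floor((y - radius - accum.y_origin) / cs)))
    r1 = min(accum.nrows - 1, int(np.ceil((y + radius - accum.y_origin) / cs)))
    c0 = max(0, int(np.floor((x - radius - accum.x_origin) / cs)))
    c1 = min(accum.ncols - 1, int(np.ceil((x + radius - accum.x_origin) / cs)))
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if not valid[r, c]:
                continue
            cx, cy = accum.cell_center(r, c)
            dist = float(np.hypot(cx - x, cy - y))
            if dist > radius:
                continue
            key = (-float(accum.values[r, c]), dist, r, c)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError(
            f"no valid cell within {radius} m of point ({x}, {y})"
        )
    return best[2], best[3]


def delineate(flow: D8FlowField, outlet: tuple[int, int]) -> np.ndarray:
    """Boolean mask of every cell whose D8 path reaches ``outlet``.

    Reverse-graph breadth-first traversal from the outlet; the outlet
    itself is included.
    """
    nrows, ncols = flow.shape
    orow, ocol = outlet
    if not (0 <= orow < nrows and 0 <= ocol < ncols) or not flow.valid[orow, ocol]:
        raise ValueError(f"outlet {outlet} is not a valid cell")
    mask = np.zeros((nrows, ncols), dtype=bool)
    mask[orow, ocol] = True
    queue = deque([(orow, ocol)])
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS, start=1):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols):
                continue
            if mask[rr, cc] or not flow.valid[rr, cc]:
                continue
            # neighbor drains into (r, c) iff its code points back here
            ds = flow.downstream(rr, cc)
            if ds == (r, c):
                mask[rr, cc] = True
                queue.append((rr, cc))
    return mask


def areas(
    catchment_mask: np.ndarray,
    lake_mask: np.ndarray,
    cell_size: float,
) -> tuple[float, float, float]:
    """(catchment_km2, lake_km2, drainage_km2) from cell counts.

    ``drainage = catchment − lake``; lake cells outside the catchment are
    inconsistent inputs and raise.
    """
    catchment_mask = np.asarray(catchment_mask, dtype=bool)
    lake_mask = np.asarray(lake_mask, dtype=bool)
    if catchment_mask.shape != lake_mask.shape:
        raise ValueError("masks must share geometry")
    if np.any(lake_mask & ~catchment_mask):
        raise ValueError("lake cells found outside the catchment mask")
    cell_km2 = (cell_size / 1000.0) ** 2
    catchment_km2 = float(catchment_mask.sum()) * cell_km2
    lake_km2 = float(lake_mask.sum()) * cell_km2
    return catchment_km2, lake_km2, catchment_km2 - lake_km2
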