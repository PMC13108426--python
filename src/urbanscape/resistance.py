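"""Landscape resistance surfaces and circuit-theory effective resistance.

The landscape is modelled as a resistor network: each defined raster cell
is a node, adjacent cells (8-neighbourhood) are joined by a resistor equal
to the mean of the two cell costs (times sqrt(2) for diagonal neighbours,
the "average resistance" convention).  The effective resistance between
two focal cells summarises conductance over all pathways and is obtained
by solving the graph Laplacian system with one node grounded; an optional
per-cell current magnitude for a unit injection yields a gene-flow density
surface.

Cost schemes encode competing movement hypotheses on a 1 (no resistance)
to 100 (strong barrier) scale: linear in night-light intensity, linear in
distance from orchards, inverse in percent tree cover, categorical land
cover with three urban-cost scenarios, and the mean of the orchard and
light surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .containers import SymmetricMatrix
from .synthetic import LAND_COVER_CODES

log = logging.getLogger(__name__)

HYPOTHESES = (
    "light",
    "orchard_distance",
    "tree_cover",
    "land_cover_1",
    "land_cover_2",
    "land_cover_3",
    "orchard_plus_light",
)

# categorical land-cover costs; urban varies across the three scenarios
_LAND_COVER_BASE = {"orchard": 1.0, "forest": 10.0, "grassland": 80.0, "arable": 90.0, "bare": 100.0}
_URBAN_COST = {"land_cover_1": 50.0, "land_cover_2": 30.0, "land_cover_3": 10.0}


@dataclass
class AsciiGrid:
    """ESRI ASCII grid; row 0 is the northernmost row, nan = NODATA."""

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float

    @property
    def shape(self):
        return self.data.shape

    def same_grid(self, other: "AsciiGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map coordinate (x, y)."""
        nrows = self.shape[0]
        col = int((x - self.xll) / self.cellsize)
        row = nrows - 1 - int((y - self.yll) / self.cellsize)
        if not (0 <= row < nrows and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col


def read_ascii_grid(path) -> AsciiGrid:
    """Parse an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return AsciiGrid(data, header["xllcorner"], header["yllcorner"], header["cellsize"])


@dataclass
class ResistanceSurface:
    """Per-cell movement cost in [1, 100]; nan marks undefined cells."""

    grid: AsciiGrid
    hypothesis: str = "other"

    def __post_init__(self) -> None:
        vals = self.grid.data
        defined = ~np.isnan(vals)
        if defined.any() and (np.nanmin(vals) < 1.0 - 1e-9 or np.nanmax(vals) > 100.0 + 1e-9):
            raise ValueError("resistance costs must lie in [1, 100]")
        if self.grid.cellsize <= 0:
            raise ValueError("cellsize must be positive")


@dataclass
class CostScheme:
    """Named hypothesis plus its parameters.

    ``light_max`` / ``d_cap`` default to the corresponding raster's own
    maximum when left unset.
    """

    hypothesis: str
    light_max: float | None = None
    d_cap: float | None = None
    category_costs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")


def _orchard_distance_grid(orchard: AsciiGrid) -> np.ndarray:
    """Distance (in cell units, chebyshev-ish BFS over 8 neighbours) from orchard cells."""
    mask = orchard.data > 0
    nrows, ncols = mask.shape
    dist = np.full(mask.shape, np.inf)
    dist[mask] = 0.0
    # multi-source BFS with diagonal moves counting sqrt(2)
    import heapq

    heap = [(0.0, r, c) for r, c in zip(*np.nonzero(mask))]
    heapq.heapify(heap)
    steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                nd = d + (np.sqrt(2.0) if dr and dc else 1.0)
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist * orchard.cellsize


def build_surface(scheme: CostScheme, layers: dict[str, AsciiGrid]) -> ResistanceSurface:
    """Build the resistance surface for one hypothesis from named layers.

    Expected layer names: "light", "tree_cover", "land_cover", "orchard".
    All supplied layers must be co-registered.
    """
    grids = list(layers.values())
    for g in grids[1:]:
        if not grids[0].same_grid(g):
            raise ValueError("layers are not co-registered")

    h = scheme.hypothesis
    if h == "light":
        light = layers["light"].data
        lmax = scheme.light_max if scheme.light_max is not None else np.nanmax(light)
        cost = 1.0 + 99.0 * (light / lmax) if lmax > 0 else np.ones_like(light)
        ref = layers["light"]
    elif h == "orchard_distance":
        ref = layers["orchard"]
        d = _orchard_distance_grid(ref)
        cap = scheme.d_cap if scheme.d_cap is not None else np.nanmax(d[np.isfinite(d)])
        cost = 1.0 + 99.0 * np.minimum(np.where(np.isfinite(d), d, cap) / cap, 1.0)
    elif h == "tree_cover":
        ref = layers["tree_cover"]
        cost = 100.0 - 99.0 * (ref.data / 100.0)
    elif h in ("land_cover_1", "land_cover_2", "land_cover_3"):
        ref = layers["land_cover"]
        table = dict(_LAND_COVER_BASE)
        table["urban"] = _URBAN_COST[h]
        table.update(scheme.category_costs)
        code_to_cost = {LAND_COVER_CODES[k]: v for k, v in table.items()}
        codes = ref.data
        cost = np.full(codes.shape, np.nan)
        for code in np.unique(codes[~np.isnan(codes)]):
            if int(code) not in code_to_cost:
                raise ValueError(f"unknown land-cover code {int(code)}")
            cost[codes == code] = code_to_cost[int(code)]
    elif h == "orchard_plus_light":
        s1 = build_surface(CostScheme("orchard_distance", d_cap=scheme.d_cap), layers)
        s2 = build_surface(CostScheme("light", light_max=scheme.light_max), layers)
        cost = (s1.grid.data + s2.grid.data) / 2.0
        ref = layers["light"]
    else:  # pragma: no cover
        raise ValueError(h)

    grid = AsciiGrid(np.clip(cost, 1.0, 100.0), ref.xll, ref.yll, ref.cellsize)
    grid.data[np.isnan(cost)] = np.nan
    return ResistanceSurface(grid, hypothesis=h)


def _build_laplacian(surface: ResistanceSurface, neighbourhood: int):
    """Sparse Laplacian of the cell graph; returns (L, node index grid)."""
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    cost = surface.grid.data
    defined = ~np.isnan(cost)
    nrows, ncols = cost.shape
    node = -np.ones(cost.shape, dtype=int)
    node[defined] = np.arange(defined.sum())
    n = defined.sum()

    rows, cols, conds = [], [], []
    offsets = [(0, 1), (1, 0)]
    if neighbourhood == 8:
        offsets += [(1, 1), (1, -1)]
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = node[r0, c0], node[r1, c1]
        ca, cb = cost[r0, c0], cost[r1, c1]
        ok = (a >= 0) & (b >= 0)
        res = (ca[ok] + cb[ok]) / 2.0
        if dr and dc:
            res = res * np.sqrt(2.0)
        rows.append(a[ok])
        cols.append(b[ok])
        conds.append(1.0 / res)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    conds = np.concatenate(conds)
    g = coo_matrix(
        (np.concatenate([conds, conds]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(g.sum(axis=1)).ravel()
    lap = csr_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n)) - g
    return lap.tocsc(), node


def effective_resistance(
    surface: ResistanceSurface,
    focal: pd.DataFrame,
    neighbourhood: int = 8,
    return_current: bool = False,
):
    """Pairwise effective resistance between focal colonies.

    ``focal`` needs columns colony_id, lon, lat (map x, y of the raster's
    coordinate system).  One Laplacian factorisation (grounded at the last
    focal node) serves all pairs.  If ``return_current`` is set, also
    returns a per-cell current-magnitude grid for a unit current driven
    between the first focal pair (a gene-flow density surface).

    Disconnected pairs come back as ``inf``.
    """
    lap, node = _build_laplacian(surface, neighbourhood)
    n = lap.shape[0]
    focal_nodes = []
    for _, row in focal.iterrows():
        r, c = surface.grid.cell_of(row["lon"], row["lat"])
        if node[r, c] < 0:
            raise ValueError(f"focal colony {row['colony_id']} falls on a NODATA cell")
        focal_nodes.append(node[r, c])

    # component labelling so that disconnected pairs come back infinite
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(lap != 0 if n > 1 else lap, directed=False)
    if n_comp > 1:
        log.warning("resistance grid has %d disconnected components", n_comp)

    solvers: dict[int, tuple] = {}
    pots: dict[int, np.ndarray] = {}
    for fn in set(focal_nodes):
        cid = comp[fn]
        if cid not in solvers:
            members = np.flatnonzero(comp == cid)
            local = -np.ones(n, dtype=int)
            local[members] = np.arange(len(members))
            sub = lap[members][:, members]
            ground = len(members) - 1
            keep = np.arange(len(members)) != ground
            solvers[cid] = (splu(sub[keep][:, keep].tocsc()), members, local, ground, keep)
        solver, members, local, ground, keep = solvers[cid]
        rhs = np.zeros(len(members) - 1)
        lf = local[fn]
        if lf != ground:
            rhs[lf if lf < ground else lf - 1] = 1.0
            # right-hand side is in the reduced (ground removed) indexing
        rhs_full = np.zeros(len(members))
        rhs_full[keep] = solver.solve(rhs) if lf != ground else 0.0
        full = np.zeros(n)
        full[members] = rhs_full
        pots[fn] = full

    labels = list(focal["colony_id"])
    m = len(labels)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = focal_nodes[i], focal_nodes[j]
            if comp[a] != comp[b]:
                values[i, j] = values[j, i] = np.inf
                continue
            # R_ab = v_a(a) - v_a(b) - v_b(a) + v_b(b) with grounded reference
            r_ab = pots[a][a] - pots[a][b] - pots[b][a] + pots[b][b]
            values[i, j] = values[j, i] = max(r_ab, 0.0)
    result = SymmetricMatrix(labels, values, kind="resistance")
    if not return_current:
        return result

    # unit current between the first two focal colonies
    a, b = focal_nodes[0], focal_nodes[1]
    v = pots[a] - pots[b]
    current = _cell_current(surface, neighbourhood, node, v)
    return result, current


def _cell_current(surface, neighbourhood, node, potential) -> np.ndarray:
    """Per-cell current magnitude = half the summed |I| of incident edges."""
    cost = surface.grid.data
    nrows, ncols = cost.shape
    out = np.zeros(cost.shape)
    offsets = [(0, 1), (1, 0)]
    if neighbourhood == 8:
        offsets += [(1, 1), (1, -1)]
    for dr, dc in offsets:
        for r in range(nrows):
            rr = r + dr
            if not (0 <= rr < nrows):
                continue
            for c in range(ncols):
                cc = c + dc
                if not (0 <= cc < ncols):
                    continue
                a, b = node[r, c], node[rr, cc]
                if a < 0 or b < 0:
                    continue
                res = (cost[r, c] + cost[rr, cc]) / 2.0
                if dr and dc:
                    res *= np.sqrt(2.0)
                i_edge = abs(potential[a] - potential[b]) / res
                out[r, c] += i_edge / 2.0
                out[rr, cc] += i_edge / 2.0
    out[node < 0] = np.nan
    return out
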