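"""Circuit-theory connectivity on raster resistance surfaces.

Re-implements pairwise circuit-theory connectivity in the Circuitscape
tradition: every valid cell is a node connected to its four nearest
neighbors, edge resistance is the arithmetic mean of the two cell
resistances, and each focal region is contracted to a zero-internal-
resistance supernode. For each unordered focal pair, one unit of current is
injected at the source with the ground fixed at 0 V and the graph Laplacian
system solved directly (sparse LU); the voltage at the source equals the
pairwise effective resistance. Per-cell current is half the sum of absolute
incident edge currents (pass-through counted once); member cells of the
source and ground regions are reported at the injected 1.0. Cumulative
current — the connectivity surface — is the cellwise sum over all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon

from .raster import Raster, require_same_grid
from .vectors import FocalRegion


@dataclass
class CircuitGraph:
    """Weighted grid graph with focal supernodes."""

    grid: Raster
    node_of: np.ndarray  # (nrows, ncols) int node id, -1 invalid
    n_nodes: int
    edge_u: np.ndarray
    edge_v: np.ndarray
    edge_g: np.ndarray  # conductances
    edge_cell_a: np.ndarray  # flat cell index of each grid edge endpoint
    edge_cell_b: np.ndarray
    focal_nodes: dict[str, int]
    focal_cells: dict[str, np.ndarray] = field(default_factory=dict)

    def laplacian(self) -> sparse.csr_matrix:
        n = self.n_nodes
        i = np.concatenate([self.edge_u, self.edge_v, self.edge_u, self.edge_v])
        j = np.concatenate([self.edge_v, self.edge_u, self.edge_u, self.edge_v])
        w = np.concatenate([-self.edge_g, -self.edge_g, self.edge_g, self.edge_g])
        return sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()

    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_nodes
        i = np.concatenate([self.edge_u, self.edge_v])
        j = np.concatenate([self.edge_v, self.edge_u])
        w = np.concatenate([self.edge_g, self.edge_g])
        return sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()


def build_graph(resistance: Raster, focal: list[FocalRegion]) -> CircuitGraph:
    """Raster to 4-neighbor graph; conductance of edge (i,j) = 1/((r_i+r_j)/2).

    Cells whose centers fall inside a focal polygon are contracted to one
    supernode per region. A focal region covering no valid cell is an error.
    """
    if len(focal) < 2:
        raise ValueError("need at least 2 focal regions")
    valid = resistance.valid_mask()
    nrows, ncols = resistance.shape
    xx, yy = resistance.centers()

    member = np.full((nrows, ncols), -1, dtype=int)
    focal_cells: dict[str, np.ndarray] = {}
    for k, region in enumerate(focal):
        inside = shapely.contains_xy(region.geometry, xx.ravel(), yy.ravel()).reshape(nrows, ncols)
        inside &= valid
        if not inside.any():
            raise ValueError(f"focal region '{region.name}' intersects no valid cell")
        member[inside] = k
        focal_cells[region.name] = np.flatnonzero(inside.ravel())

    node_of = np.full((nrows, ncols), -1, dtype=int)
    node_of[valid & (member >= 0)] = member[valid & (member >= 0)]
    free = valid & (member < 0)
    node_of[free] = len(focal) + np.arange(int(free.sum()))
    n_nodes = len(focal) + int(free.sum())

    r = resistance.values
    eu, ev, eg, ca, cb = [], [], [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = node_of[: nrows - dr, : ncols - dc]
        b = node_of[dr:, dc:]
        ra = r[: nrows - dr, : ncols - dc]
        rb = r[dr:, dc:]
        ok = (a >= 0) & (b >= 0)
        g = 1.0 / ((ra[ok] + rb[ok]) / 2.0)
        rows, cols = np.nonzero(ok)
        eu.append(a[ok])
        ev.append(b[ok])
        eg.append(g)
        ca.append(rows * ncols + cols)
        cb.append((rows + dr) * ncols + (cols + dc))
    edge_u = np.concatenate(eu)
    edge_v = np.concatenate(ev)
    edge_g = np.concatenate(eg)
    cell_a = np.concatenate(ca)
    cell_b = np.concatenate(cb)
    keep = edge_u != edge_v  # drop intra-supernode edges
    return CircuitGraph(
        grid=resistance,
        node_of=node_of,
        n_nodes=n_nodes,
        edge_u=edge_u[keep],
        edge_v=edge_v[keep],
        edge_g=edge_g[keep],
        edge_cell_a=cell_a[keep],
        edge_cell_b=cell_b[keep],
        focal_nodes={reg.name: k for k, reg in enumerate(focal)},
        focal_cells=focal_cells,
    )


@dataclass
class PairSolve:
    """Result of one unit-current injection between a focal pair."""

    source: str
    ground: str
    current: Raster
    effective_resistance: float
    connected: bool
    voltages: np.ndarray | None = None
    edge_currents: np.ndarray | None = None


def solve_pair(graph: CircuitGraph, source: str, ground: str) -> PairSolve:
    """Solve L v = b with +1 A at the source supernode and the ground at 0 V."""
    if source == ground:
        raise ValueError("source and ground must differ")
    s = graph.focal_nodes[source]
    t = graph.focal_nodes[ground]

    n_comp, labels = connected_components(graph.adjacency(), directed=False)
    if labels[s] != labels[t]:
        warnings.warn(f"focal pair ({source}, {ground}) is disconnected; infinite resistance")
        zero = graph.grid.with_values(np.where(graph.node_of >= 0, 0.0, np.nan))
        return PairSolve(source, ground, zero, np.inf, connected=False)

    L = graph.laplacian()
    b = np.zeros(graph.n_nodes)
    b[s] = 1.0
    keep = np.ones(graph.n_nodes, dtype=bool)
    keep[t] = False
    # restrict to the component containing the pair; other components are inert
    keep &= labels == labels[s]
    idx = np.flatnonzero(keep)
    L_red = L[idx][:, idx].tocsc()
    v_red = spsolve(L_red, b[idx])
    v = np.zeros(graph.n_nodes)
    v[idx] = v_red

    edge_i = (v[graph.edge_u] - v[graph.edge_v]) * graph.edge_g
    cell_cur = np.zeros(graph.grid.nrows * graph.grid.ncols)
    np.add.at(cell_cur, graph.edge_cell_a, np.abs(edge_i))
    np.add.at(cell_cur, graph.edge_cell_b, np.abs(edge_i))
    cell_cur *= 0.5
    cell_cur[graph.focal_cells[source]] = 1.0
    cell_cur[graph.focal_cells[ground]] = 1.0
    vals = cell_cur.reshape(graph.grid.shape)
    vals = np.where(graph.node_of >= 0, vals, np.nan)
    return PairSolve(
        source,
        ground,
        graph.grid.with_values(vals, kind="current", pair=f"{source}-{ground}"),
        effective_resistance=float(v[s]),
        connected=True,
        voltages=v,
        edge_currents=edge_i,
    )


@dataclass
class CurrentMap:
    """Cumulative current over all focal pairs, plus the per-pair maps."""

    cumulative: Raster
    pair_maps: dict[tuple[str, str], Raster]
    effective_resistances: dict[tuple[str, str], float]

    def summed_current(self, region: Polygon) -> float:
        """Sum of cumulative current over valid cells whose center is in ``region``."""
        r = self.cumulative
        xx, yy = r.centers()
        inside = shapely.contains_xy(region, xx.ravel(), yy.ravel()).reshape(r.shape)
        vals = r.values[inside & r.valid_mask()]
        return float(np.nansum(vals))

    @property
    def total_current(self) -> float:
        return float(np.nansum(self.cumulative.values))


def cumulative_current(graph: CircuitGraph, pairs: list[tuple[str, str]] | None = None) -> CurrentMap:
    """Solve every unordered focal pair and sum the current maps cellwise."""
    names = sorted(graph.focal_nodes, key=graph.focal_nodes.get)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if not pairs:
        raise ValueError("no focal pairs to solve")
    total = np.zeros(graph.grid.shape)
    pair_maps: dict[tuple[str, str], Raster] = {}
    reffs: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        res = solve_pair(graph, a, b)
        pair_maps[(a, b)] = res.current
        reffs[(a, b)] = res.effective_resistance
        total += np.nan_to_num(res.current.values)
    vals = np.where(graph.node_of >= 0, total, np.nan)
    return CurrentMap(
        cumulative=graph.grid.with_values(vals, kind="cumulative_current"),
        pair_maps=pair_maps,
        effective_resistances=reffs,
    )


def identify_corridors(current: Raster | CurrentMap, top_fraction: float = 0.10) -> tuple[Raster, float]:
    """Corridor mask: cells strictly above the (1 - top_fraction) quantile.

    Returns the binary mask raster (1 = corridor) and the threshold used.
    """
    if isinstance(current, CurrentMap):
        current = current.cumulative
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    vals = current.values[current.valid_mask()]
    threshold = float(np.quantile(vals, 1.0 - top_fraction))
    if vals.min() == vals.max():
        warnings.warn("constant current map: corridor mask is empty")
    mask = np.where(current.valid_mask(), (current.values > threshold).astype(float), np.nan)
    return current.with_values(mask, kind="corridor_mask", threshold=threshold), threshold


def connectivity_change(fenced: Raster | CurrentMap, prefence: Raster | CurrentMap) -> Raster:
    """Cellwise fenced minus pre-fencing current (negative = connectivity loss)."""
    if isinstance(fenced, CurrentMap):
        fenced = fenced.cumulative
    if isinstance(prefence, CurrentMap):
        prefence = prefence.cumulative
    require_same_grid(fenced, prefence, ("fenced", "prefence"))
    return fenced.with_values(fenced.values - prefence.values, kind="connectivity_change")
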