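"""Resistance surfaces: inverted suitability, fence barriers, enclosed parcels.

Movement resistance is the inverse of habitat suitability, mapped linearly
onto [r_min, r_max] (defaults 1 and 100) so that the fence barrier value 100
is the natural maximum; a reciprocal (1/s) variant is available behind a
flag. Fence lines are burned in with a supercover rule — every cell whose
square the polyline touches becomes a barrier — and fully enclosed parcels
are filled to the barrier value as well, treating fences as blocking all
movement (a worst-case, fence-type-agnostic assumption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.ops import polygonize, unary_union

from .raster import Raster
from .vectors import FenceNetwork, segmentize

BARRIER_RESISTANCE = 100.0
SQ_M_PER_ACRE = 4046.8564224


@dataclass
class Parcel:
    """A land parcel enclosed by fencing — the unit of removal cost."""

    polygon: Polygon
    bounding_fence_ids: list[str]
    fully_enclosed: bool = True
    nested: bool = False  # enclosed only by virtue of lying inside a larger parcel

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_acres(self) -> float:
        return self.area_m2 / SQ_M_PER_ACRE


def suitability_to_resistance(
    suitability: Raster,
    r_min: float = 1.0,
    r_max: float = BARRIER_RESISTANCE,
    mode: str = "linear",
) -> Raster:
    """Invert suitability into movement resistance.

    ``linear``: r = r_max - (r_max - r_min) * s, strictly decreasing in s with
    r(1) = r_min and r(0) = r_max. ``reciprocal``: r = clip(1/s, r_min, r_max).
    """
    if not (0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    s = suitability.values
    valid = suitability.valid_mask()
    if np.any(valid & ~((s > 0) & (s < 1))):
        raise ValueError("suitability must lie strictly in (0, 1) on valid cells")
    if mode == "linear":
        r = r_max - (r_max - r_min) * s
    elif mode == "reciprocal":
        r = np.clip(1.0 / s, r_min, r_max)
    else:
        raise ValueError(f"unknown resistance mode '{mode}'")
    r = np.where(valid, r, np.nan)
    return suitability.with_values(r, kind="resistance", resistance_mode=mode, r_min=r_min, r_max=r_max)


def _cells_touched(raster: Raster, line: LineString) -> list[tuple[int, int]]:
    """Supercover rasterization: cells whose closed square the line touches."""
    cs = raster.cell_size
    ox, oy = raster.origin
    cells = []
    for seg in segmentize(line):
        (x0, y0), (x1, y1) = seg.coords
        cmin = int(np.floor((min(x0, x1) - ox) / cs))
        cmax = int(np.floor((max(x0, x1) - ox) / cs))
        rmin = int(np.floor((oy - max(y0, y1)) / cs))
        rmax = int(np.floor((oy - min(y0, y1)) / cs))
        for r in range(max(rmin, 0), min(rmax, raster.nrows - 1) + 1):
            for c in range(max(cmin, 0), min(cmax, raster.ncols - 1) + 1):
                sq = box(ox + c * cs, oy - (r + 1) * cs, ox + (c + 1) * cs, oy - r * cs)
                if seg.intersects(sq):
                    cells.append((r, c))
    return cells


def burn_fences(
    resistance: Raster,
    fences: FenceNetwork,
    barrier_value: float = BARRIER_RESISTANCE,
    fill_enclosed: bool = True,
    parcels: list[Parcel] | None = None,
) -> Raster:
    """Burn fence lines (and optionally enclosed-parcel interiors) to the barrier value.

    Every cell intersected by a fence polyline is set to ``barrier_value``;
    with ``fill_enclosed`` the interiors of fully enclosed parcels are filled
    too. All other cells are returned bit-identical. Pre-detected ``parcels``
    may be passed to skip re-polygonization.
    """
    out = resistance.copy()
    if len(fences) == 0:
        return out
    vals = out.values
    for line in fences.lines:
        for r, c in _cells_touched(out, line):
            vals[r, c] = barrier_value
    if fill_enclosed:
        if parcels is None:
            parcels = detect_parcels(fences)
        if parcels:
            filled = unary_union([Polygon(p.polygon.exterior) for p in parcels])
            xx, yy = out.centers()
            inside = shapely.contains_xy(filled, xx.ravel(), yy.ravel()).reshape(out.shape)
            vals[inside] = barrier_value
    out.meta.update(barrier_value=barrier_value, fenced=True)
    return out


def detect_parcels(fences: FenceNetwork, min_bounding_lines: int = 3) -> list[Parcel]:
    """Extract enclosed land parcels from the fence-line arrangement.

    The polylines are noded into a planar arrangement and its bounded faces
    extracted; a face is a parcel when its boundary uses at least
    ``min_bounding_lines`` distinct original fence lines (rule 1), or when it
    lies fully within another parcel (rule 2, nested parcels).
    """
    if len(fences) == 0:
        return []
    noded = unary_union(fences.lines)
    faces = [f for f in polygonize(noded) if f.area > 0]
    if not faces:
        return []

    tree_lines = fences.tree()
    tol = 1e-9
    candidates: list[tuple[Polygon, list[str]]] = []
    for face in faces:
        boundary = face.exterior
        ids = []
        for idx in tree_lines.query(boundary):
            inter = fences.lines[idx].intersection(boundary)
            if inter.length > tol:
                ids.append(fences.ids[idx])
        candidates.append((face, sorted(set(ids))))

    parcels = [
        Parcel(polygon=f, bounding_fence_ids=ids)
        for f, ids in candidates
        if len(ids) >= min_bounding_lines
    ]
    # rule 2: faces inside a larger enclosed parcel count even with few lines
    if parcels:
        enclosing = unary_union([Polygon(p.polygon.exterior) for p in parcels])
        for f, ids in candidates:
            if len(ids) >= min_bounding_lines:
                continue
            if f.representative_point().within(enclosing):
                parcels.append(Parcel(polygon=f, bounding_fence_ids=ids, nested=True))
    return parcels
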