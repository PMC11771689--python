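"""Fence-removal corridor scenarios: geometry, connectivity gain, and cost.

A scenario is a corridor centerline buffered to a width (defaults 0.5, 1, 2
and 3 km); fence segments inside the buffer are removed (clipped at the
boundary), the fenced resistance surface is rebuilt, and the cumulative
current re-solved. Improvement is the percentage of the connectivity lost to
fencing — summed current over a region of interest covering all candidate
corridors — that the scenario restores. Cost is the fenced-parcel area
intersecting the corridor times a per-acre compensation rate (default
US$75/acre, the Pardamat Conservation Area de-fencing payment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Polygon
from shapely.ops import unary_union

from .circuit import build_graph, cumulative_current
from .raster import Raster
from .resistance import SQ_M_PER_ACRE, Parcel, burn_fences, detect_parcels
from .vectors import Corridor, FenceNetwork, FocalRegion

DEFAULT_WIDTHS_KM = (0.5, 1.0, 2.0, 3.0)
DEFAULT_UNIT_COST = 75.0  # USD per acre


@dataclass
class ScenarioResult:
    corridor_id: str
    width_km: float
    fence_length_removed_m: float
    n_fences_removed: int
    parcel_intersection_acres: float
    n_parcels_intersected: int
    cost_usd: float
    improvement_pct: float
    sum_pre: float
    sum_fenced: float
    sum_scenario: float

    @property
    def fence_km_removed(self) -> float:
        return self.fence_length_removed_m / 1000.0


def apply_scenario(fences: FenceNetwork, corridor: Corridor, width_km: float) -> tuple[FenceNetwork, float, int]:
    """Delete fence-line portions inside the buffered corridor.

    Lines are clipped at the corridor boundary — only the inside portion is
    removed, the rest is retained. Returns the modified network, the removed
    length (m), and the number of lines touched.
    """
    buf = corridor.buffered(width_km * 1000.0)
    new_lines: list[LineString] = []
    new_ids: list[str] = []
    removed = 0.0
    touched = 0
    for line, lid in zip(fences.lines, fences.ids):
        if not line.intersects(buf):
            new_lines.append(line)
            new_ids.append(lid)
            continue
        touched += 1
        outside = line.difference(buf)
        removed += line.length - outside.length
        parts = (
            list(outside.geoms) if isinstance(outside, MultiLineString) else ([outside] if outside.length > 0 else [])
        )
        for k, part in enumerate(parts):
            new_lines.append(part)
            new_ids.append(lid if k == 0 else f"{lid}~{k}")
    net = FenceNetwork(lines=new_lines, ids=new_ids, meta=dict(fences.meta))
    return net, float(removed), touched


def improvement_metric(sum_pre: float, sum_fenced: float, sum_scenario: float) -> float:
    """Percent of the fencing-induced connectivity loss restored by the scenario.

    100 * (scenario - fenced) / (pre - fenced); may exceed 100 if a scenario
    outperforms the pre-fencing baseline over the region of interest.
    """
    if sum_pre <= sum_fenced:
        raise ValueError("no connectivity loss to restore (sum_pre <= sum_fenced)")
    return 100.0 * (sum_scenario - sum_fenced) / (sum_pre - sum_fenced)


def scenario_cost(
    parcels: list[Parcel],
    corridor: Corridor,
    width_km: float,
    unit_cost_per_acre: float = DEFAULT_UNIT_COST,
) -> tuple[float, float, int]:
    """Compensation cost of the fenced-parcel area intersecting the corridor.

    Only the parcel portion inside the buffered corridor is paid for.
    Returns (cost USD, intersected acres, number of parcels intersected).
    """
    if unit_cost_per_acre <= 0:
        raise ValueError("unit_cost_per_acre must be positive")
    buf = corridor.buffered(width_km * 1000.0)
    area_m2 = 0.0
    n_hit = 0
    for p in parcels:
        inter = p.polygon.intersection(buf)
        if inter.area > 0:
            n_hit += 1
            area_m2 += inter.area
    acres = area_m2 / SQ_M_PER_ACRE
    return acres * unit_cost_per_acre, acres, n_hit


def run_scenarios(
    resistance_prefence: Raster,
    fences: FenceNetwork,
    focal: list[FocalRegion],
    corridors: list[Corridor],
    roi: Polygon | None = None,
    widths_km: tuple[float, ...] = DEFAULT_WIDTHS_KM,
    unit_cost_per_acre: float = DEFAULT_UNIT_COST,
    barrier_value: float = 100.0,
    parcels: list[Parcel] | None = None,
    roi_margin_m: float = 500.0,
) -> list[ScenarioResult]:
    """Evaluate every corridor x width fence-removal scenario.

    For each scenario the fenced resistance is rebuilt from the post-removal
    network, the pairwise circuit problem re-solved, and improvement measured
    against the pre-fencing and fully fenced baselines over the region of
    interest (default: union of all corridor buffers plus a margin). Results
    are sorted by improvement per dollar (best value first).
    """
    if parcels is None:
        parcels = detect_parcels(fences)
    if roi is None:
        roi = unary_union(
            [c.buffered(max(widths_km) * 1000.0).buffer(roi_margin_m) for c in corridors]
        )

    cm_pre = cumulative_current(build_graph(resistance_prefence, focal))
    sum_pre = cm_pre.summed_current(roi)
    r_fenced = burn_fences(resistance_prefence, fences, barrier_value, parcels=parcels)
    cm_fenced = cumulative_current(build_graph(r_fenced, focal))
    sum_fenced = cm_fenced.summed_current(roi)

    results: list[ScenarioResult] = []
    for corridor in corridors:
        for w in widths_km:
            net, removed_m, n_removed = apply_scenario(fences, corridor, w)
            r_scen = burn_fences(resistance_prefence, net, barrier_value)
            cm_scen = cumulative_current(build_graph(r_scen, focal))
            sum_scen = cm_scen.summed_current(roi)
            cost, acres, n_parc = scenario_cost(parcels, corridor, w, unit_cost_per_acre)
            results.append(
                ScenarioResult(
                    corridor_id=corridor.corridor_id,
                    width_km=w,
                    fence_length_removed_m=removed_m,
                    n_fences_removed=n_removed,
                    parcel_intersection_acres=acres,
                    n_parcels_intersected=n_parc,
                    cost_usd=cost,
                    improvement_pct=improvement_metric(sum_pre, sum_fenced, sum_scen),
                    sum_pre=sum_pre,
                    sum_fenced=sum_fenced,
                    sum_scenario=sum_scen,
                )
            )
    results.sort(key=lambda r: r.improvement_pct / r.cost_usd if r.cost_usd > 0 else np.inf, reverse=True)
    return results


def results_table(results: list[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "corridor_id": [r.corridor_id for r in results],
            "width_km": [r.width_km for r in results],
            "fence_km_removed": [r.fence_km_removed for r in results],
            "area_acres": [r.parcel_intersection_acres for r in results],
            "n_parcels": [r.n_parcels_intersected for r in results],
            "cost_usd": [r.cost_usd for r in results],
            "improvement_pct": [r.improvement_pct for r in results],
        }
    )
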