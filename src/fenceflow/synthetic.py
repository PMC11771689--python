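"""Synthetic landscapes, fence networks, and GPS movement data.

The generators here produce inputs with the statistical structure the
analysis pipeline assumes — spatially autocorrelated environmental
covariates, a 16-day NDVI time series, Euclidean distance layers, fence
polylines enclosing rectangular land parcels, and animal trajectories
simulated from a known habitat-selection model — so that every downstream
stage (model fitting, resistance surfaces, circuit solves, restoration
scenarios, validation statistics) can be tested end to end without any
remote data.

Movement defaults mirror wildebeest GPS collar data: 3-hour fixes with a
step-length distribution of mean 11 km and SD 9 km (validation collars:
4-hour fixes). Step lengths are gamma distributed (moment-matched) with
uniform turning angles; habitat selection acts on candidate destinations
with probability proportional to ``exp(beta . x)``; fence lines, when
supplied, are absolute barriers to a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from .raster import Raster, grids_match
from .vectors import Corridor, FenceNetwork, FocalRegion

#: Covariate vocabulary of the habitat-selection design. ``ndvi`` and
#: ``dndvi`` are time-varying (backed by the NDVI series); the ``dist_*``
#: layers enter the model with a quadratic term.
COVARIATES = (
    "ndvi",
    "dndvi",
    "twi",
    "footprint",
    "dist_woody",
    "dist_rivers",
    "dist_road_primary",
    "dist_road_secondary",
)
DISTANCE_COVARIATES = tuple(c for c in COVARIATES if c.startswith("dist_"))


@dataclass
class CovariateStack:
    """Named covariate rasters on one shared grid, plus an NDVI time series."""

    layers: dict[str, Raster]
    ndvi_series: list[tuple[np.datetime64, Raster]] = field(default_factory=list)
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.grid
        for name, r in self.layers.items():
            if not grids_match(ref, r):
                raise ValueError(f"layer '{name}' is not on the shared grid")
        for _, r in self.ndvi_series:
            if not grids_match(ref, r):
                raise ValueError("NDVI series raster is not on the shared grid")
        dates = [d for d, _ in self.ndvi_series]
        if dates != sorted(dates):
            raise ValueError("NDVI series dates must be ascending")

    @property
    def grid(self) -> Raster:
        if self.layers:
            return next(iter(self.layers.values()))
        return self.ndvi_series[0][1]

    @property
    def covariate_names(self) -> list[str]:
        names = []
        if len(self.ndvi_series) >= 2:
            names += ["ndvi", "dndvi"]
        names += [c for c in COVARIATES if c in self.layers]
        return names

    # -- NDVI time handling -------------------------------------------------
    def _series_values_at(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return np.stack([r.values[row, col] for _, r in self.ndvi_series])

    def _bracket(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (lo, hi) of the two nearest series dates and the weight on hi."""
        dates = np.array([d for d, _ in self.ndvi_series], dtype="datetime64[s]").astype(float)
        t = np.asarray(times, dtype="datetime64[s]").astype(float)
        hi = np.clip(np.searchsorted(dates, t), 1, len(dates) - 1)
        lo = hi - 1
        w = np.clip((t - dates[lo]) / (dates[hi] - dates[lo]), 0.0, 1.0)
        return lo, hi, w

    def ndvi_at(self, x, y, times) -> np.ndarray:
        """NDVI interpolated between the two nearest 16-day composites."""
        row, col = self._clipped_index(x, y)
        vals = self._series_values_at(row, col)
        lo, hi, w = self._bracket(times)
        pts = np.arange(len(row))
        return (1 - w) * vals[lo, pts] + w * vals[hi, pts]

    def dndvi_at(self, x, y, times) -> np.ndarray:
        """NDVI change rate: difference between the two nearest composites."""
        row, col = self._clipped_index(x, y)
        vals = self._series_values_at(row, col)
        lo, hi, _ = self._bracket(times)
        pts = np.arange(len(row))
        return vals[hi, pts] - vals[lo, pts]

    def ndvi_mean(self) -> Raster:
        """Long-term mean NDVI over the series."""
        vals = np.mean([r.values for _, r in self.ndvi_series], axis=0)
        return self.grid.with_values(vals)

    def dndvi_snapshot(self, date: np.datetime64 | str | None = None) -> Raster:
        """NDVI change for the series interval containing ``date`` (default: mid-series)."""
        if date is None:
            date = self.ndvi_series[len(self.ndvi_series) // 2][0]
        lo, hi, _ = self._bracket(np.array([np.datetime64(date, "s")]))
        vals = self.ndvi_series[int(hi[0])][1].values - self.ndvi_series[int(lo[0])][1].values
        return self.grid.with_values(vals)

    def _clipped_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid
        row, col = g.index_of(np.atleast_1d(x), np.atleast_1d(y))
        return np.clip(row, 0, g.nrows - 1), np.clip(col, 0, g.ncols - 1)

    # -- sampling -----------------------------------------------------------
    def covariates_at(
        self,
        x,
        y,
        times=None,
        names: list[str] | None = None,
        dndvi_date=None,
    ) -> pd.DataFrame:
        """Covariate values at points (nearest cell; NDVI matched to ``times``).

        With ``times=None`` the time-varying layers fall back to the long-term
        NDVI mean and the default change-rate snapshot.
        """
        names = names or self.covariate_names
        x = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
        y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
        out = {}
        for name in names:
            if name == "ndvi" and len(self.ndvi_series) >= 2:
                out[name] = (
                    self.ndvi_at(x, y, times) if times is not None else self.ndvi_mean().sample(x, y)
                )
            elif name == "dndvi" and len(self.ndvi_series) >= 2:
                out[name] = (
                    self.dndvi_at(x, y, times)
                    if times is not None
                    else self.dndvi_snapshot(dndvi_date).sample(x, y)
                )
            else:
                out[name] = self.layers[name].sample(x, y)
        return pd.DataFrame(out)

    def covariate_grids(self, dndvi_date=None, names: list[str] | None = None) -> dict[str, np.ndarray]:
        """Full-grid covariate arrays for prediction (NDVI at its long-term mean)."""
        names = names or self.covariate_names
        out = {}
        for name in names:
            if name == "ndvi" and len(self.ndvi_series) >= 2:
                out[name] = self.ndvi_mean().values
            elif name == "dndvi" and len(self.ndvi_series) >= 2:
                out[name] = self.dndvi_snapshot(dndvi_date).values
            else:
                out[name] = self.layers[name].values
        return out


# -- field generation -------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian random field via smoothing of white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_cells, 1e-6), mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _distance_layer(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (m) to the nearest True cell of ``mask``."""
    if not mask.any():
        raise ValueError("distance layer requires at least one source cell")
    return distance_transform_edt(~mask) * cell_size


def _river_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """A meandering west-east river, one cell wide."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(nrows // 4, 3 * nrows // 4)
    for c in range(ncols):
        mask[r, c] = True
        r = int(np.clip(r + rng.integers(-1, 2), 0, nrows - 1))
        mask[r, c] = True
    return mask


def _line_mask(shape, r0, c0, r1, c1) -> np.ndarray:
    """Cells along the straight segment (r0,c0)-(r1,c1), densely sampled."""
    n = 4 * max(abs(r1 - r0), abs(c1 - c0), 1)
    rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, shape[1] - 1)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_covariates(
    grid_shape: tuple[int, int],
    cell_size: float = 50.0,
    correlation_length: float = 500.0,
    seed: int | None = None,
    layers: list[str] | None = None,
    n_ndvi_dates: int = 8,
    start_date: str = "2010-12-19",
    origin: tuple[float, float] | None = None,
) -> CovariateStack:
    """Generate a covariate stack with spatially autocorrelated fields.

    ``correlation_length`` (m) sets the Gaussian smoothing scale of every
    random field. NDVI is a 16-day series of ``n_ndvi_dates`` composites with
    AR(1) temporal anomalies; distance layers are exact Euclidean distance
    transforms from generated river/woodland/road features.
    """
    nrows, ncols = grid_shape
    if nrows < 3 or ncols < 3:
        raise ValueError("degenerate grid: both dimensions must be >= 3")
    if correlation_length < cell_size:
        raise ValueError("correlation_length must be >= cell_size")
    names = list(layers) if layers is not None else list(COVARIATES)
    unknown = set(names) - set(COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariate names: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sigma = correlation_length / cell_size
    if origin is None:
        origin = (0.0, nrows * cell_size)
    grid = Raster(np.zeros(grid_shape), cell_size=cell_size, origin=origin)

    static: dict[str, Raster] = {}
    features: dict[str, np.ndarray] = {}

    def add_static(name: str, values: np.ndarray) -> None:
        static[name] = grid.with_values(values)

    if "twi" in names:
        add_static("twi", 8.0 + 2.0 * _smooth_field(rng, grid_shape, sigma))
    if "footprint" in names:
        add_static("footprint", np.clip(0.5 + 0.25 * _smooth_field(rng, grid_shape, sigma), 0.0, None))
    if "dist_rivers" in names:
        features["rivers"] = _river_mask(rng, grid_shape)
        add_static("dist_rivers", _distance_layer(features["rivers"], cell_size))
    if "dist_woody" in names:
        f = _smooth_field(rng, grid_shape, sigma)
        features["woody"] = f > np.quantile(f, 0.8)
        add_static("dist_woody", _distance_layer(features["woody"], cell_size))
    if "dist_road_primary" in names:
        features["road_primary"] = _line_mask(
            grid_shape, 0, rng.integers(ncols), nrows - 1, rng.integers(ncols)
        )
        add_static("dist_road_primary", _distance_layer(features["road_primary"], cell_size))
    if "dist_road_secondary" in names:
        m = _line_mask(grid_shape, rng.integers(nrows), 0, rng.integers(nrows), ncols - 1)
        m |= _line_mask(grid_shape, 0, rng.integers(ncols), nrows - 1, rng.integers(ncols))
        features["road_secondary"] = m
        add_static("dist_road_secondary", _distance_layer(m, cell_size))

    series: list[tuple[np.datetime64, Raster]] = []
    if "ndvi" in names or "dndvi" in names:
        base = _smooth_field(rng, grid_shape, sigma)
        anom = _smooth_field(rng, grid_shape, sigma)
        t0 = np.datetime64(start_date)
        for i in range(max(n_ndvi_dates, 2)):
            anom = 0.7 * anom + np.sqrt(1 - 0.7**2) * _smooth_field(rng, grid_shape, sigma)
            vals = np.clip(0.5 + 0.15 * base + 0.08 * anom, 0.02, 0.98)
            series.append((t0 + np.timedelta64(16 * i, "D"), grid.with_values(vals)))

    return CovariateStack(layers=static, ndvi_series=series, features=features)


# -- fences -----------------------------------------------------------------

def _rect_lines(xmin, ymin, xmax, ymax) -> list[LineString]:
    """The four sides of a rectangle as separate fence lines."""
    return [
        LineString([(xmin, ymin), (xmax, ymin)]),
        LineString([(xmax, ymin), (xmax, ymax)]),
        LineString([(xmax, ymax), (xmin, ymax)]),
        LineString([(xmin, ymax), (xmin, ymin)]),
    ]


def generate_fences(
    stack: CovariateStack,
    n_parcels: int,
    seed: int | None = None,
    parcel_cells: tuple[int, int] = (3, 8),
    n_open_lines: int | None = None,
    suitability: Raster | None = None,
) -> FenceNetwork:
    """Fence network with ``n_parcels`` enclosed rectangular parcels.

    Parcel centers are sampled with probability increasing in habitat
    suitability (fences tend to be established in high-suitability areas);
    each parcel contributes its four sides as distinct fence lines. Distractor
    open polylines that touch nothing are added so that parcel detection has
    to discriminate bounded faces from loose fencing.
    """
    if n_parcels < 0:
        raise ValueError("n_parcels must be >= 0")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    cs = grid.cell_size
    if suitability is not None:
        weight_field = suitability.values
    elif stack.ndvi_series:
        weight_field = stack.ndvi_mean().values
    else:
        weight_field = next(iter(stack.layers.values())).values
    z = (weight_field - np.nanmean(weight_field)) / (np.nanstd(weight_field) + 1e-12)
    prob = np.exp(2.0 * np.nan_to_num(z)).ravel()
    prob /= prob.sum()

    lines: list[LineString] = []
    ids: list[str] = []
    placed: list[Polygon] = []
    true_parcels: list[Polygon] = []
    attempts = 0
    while len(true_parcels) < n_parcels:
        attempts += 1
        if attempts > 200 * max(n_parcels, 1):
            raise ValueError("n_parcels exceeds grid capacity for non-overlapping parcels")
        cell = rng.choice(prob.size, p=prob)
        r, c = divmod(cell, grid.ncols)
        cx, cy = grid.cell_center(r, c)
        w = rng.integers(parcel_cells[0], parcel_cells[1] + 1) * cs
        h = rng.integers(parcel_cells[0], parcel_cells[1] + 1) * cs
        rect = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        xmin, ymin, xmax, ymax = grid.bounds
        if not rect.within(box(xmin + cs, ymin + cs, xmax - cs, ymax - cs)):
            continue
        if any(rect.buffer(cs).intersects(p) for p in placed):
            continue
        placed.append(rect)
        true_parcels.append(rect)
        k = len(true_parcels) - 1
        for j, side in enumerate(_rect_lines(*rect.bounds)):
            lines.append(side)
            ids.append(f"parcel{k:03d}_side{j}")

    n_open = n_open_lines if n_open_lines is not None else max(2, n_parcels // 2 + 2)
    existing = unary_union(lines) if lines else None
    xmin, ymin, xmax, ymax = grid.bounds
    made = 0
    guard = 0
    while made < n_open and guard < 500:
        guard += 1
        x0 = rng.uniform(xmin + cs, xmax - cs)
        y0 = rng.uniform(ymin + cs, ymax - cs)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(2, 5) * cs
        cand = LineString([(x0, y0), (x0 + length * np.cos(ang), y0 + length * np.sin(ang))])
        if not cand.within(box(xmin, ymin, xmax, ymax)):
            continue
        if existing is not None and cand.distance(existing) < cs / 2:
            continue
        lines.append(cand)
        ids.append(f"open{made:03d}")
        existing = unary_union([existing, cand]) if existing is not None else cand
        made += 1

    return FenceNetwork(
        lines=lines,
        ids=ids,
        meta={"n_true_parcels": n_parcels, "true_parcels": true_parcels},
    )


def generate_focal_regions(
    stack: CovariateStack,
    names: tuple[str, ...] = ("west", "east", "north"),
    radius_cells: float = 2.5,
) -> list[FocalRegion]:
    """Focal polygons at the landscape margins (seasonal-range end nodes)."""
    g = stack.grid
    xmin, ymin, xmax, ymax = g.bounds
    cs = g.cell_size
    rad = radius_cells * cs
    anchors = {
        "west": (xmin + 2 * cs, (ymin + ymax) / 2),
        "east": (xmax - 2 * cs, (ymin + ymax) / 2),
        "north": ((xmin + xmax) / 2, ymax - 2 * cs),
        "south": ((xmin + xmax) / 2, ymin + 2 * cs),
    }
    regions = []
    for name in names:
        if name not in anchors:
            raise ValueError(f"unknown focal anchor '{name}'")
        regions.append(FocalRegion(name=name, geometry=Point(*anchors[name]).buffer(rad)))
    return regions


# -- trajectories -----------------------------------------------------------

@dataclass
class Trajectory:
    """One animal's timestamped fix sequence in projected meters."""

    animal_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    x: np.ndarray
    y: np.ndarray
    fix_interval_h: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        if len(self.times) > 1 and not (np.diff(self.times).astype(float) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def max_step_length(self) -> float:
        if len(self) < 2:
            raise ValueError("max step length undefined for a single-fix trajectory")
        return float(self.step_lengths().max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal_id, "timestamp": self.times, "x": self.x, "y": self.y}
        )


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> Path:
    path = Path(path)
    df = pd.concat([t.to_dataframe() for t in trajectories], ignore_index=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)
    return path


def read_trajectories(path: str | Path, fix_interval_h: float | None = None) -> list[Trajectory]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        times = grp["timestamp"].to_numpy().astype("datetime64[s]")
        interval = fix_interval_h
        if interval is None and len(times) > 1:
            interval = float(np.diff(times).astype(float).min()) / 3600.0
        out.append(
            Trajectory(
                animal_id=str(aid),
                times=times,
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
                fix_interval_h=interval or 0.0,
            )
        )
    return out


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, sd**2 / mean


def raw_linear_predictor(cov: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    """eta = const + sum beta_j x_j, with ``name_sq`` keys read as x_j**2."""
    eta = np.full(len(cov), float(beta.get("const", 0.0)))
    for name, b in beta.items():
        if name == "const":
            continue
        base = name[:-3] if name.endswith("_sq") else name
        vals = cov[base].to_numpy(float)
        eta += b * (vals**2 if name.endswith("_sq") else vals)
    return eta


def simulate_trajectories(
    stack: CovariateStack,
    true_beta: dict[str, float],
    n_animals: int,
    n_steps: int,
    step_mean_km: float = 11.0,
    step_sd_km: float = 9.0,
    fix_interval_h: float = 3.0,
    fences: FenceNetwork | None = None,
    seed: int | None = None,
    n_candidates: int = 30,
    start_date: str = "2011-01-01",
    kernel: str = "gamma",
    migration_targets: list[tuple[float, float]] | None = None,
    migration_switch_steps: int = 15,
    migration_strength_per_km: float = 0.4,
) -> list[Trajectory]:
    """Simulate selection-driven movement on the synthetic landscape.

    Each step draws ``n_candidates`` destinations from a movement kernel
    (gamma step lengths moment-matched to ``step_mean_km``/``step_sd_km``,
    uniform turning angles) and picks one with probability proportional to
    ``exp(true_beta . x)`` evaluated at the candidate. Candidates outside the
    landscape, on invalid cells, or whose straight-line step crosses a fence
    line are excluded; if every candidate is excluded the animal stays in
    place for that fix (counted in ``meta['blocked_steps']``).

    ``kernel='uniform_disk'`` replaces the gamma kernel with candidates drawn
    area-uniformly in the disk of radius ``step_mean_km`` — an availability
    model that matches the pseudo-absence sampling design, so selection
    coefficients estimated from such data are directly comparable to
    ``true_beta`` (useful for parameter-recovery experiments).

    ``migration_targets`` adds seasonal migratory taxis: animals cycle
    through the target points (switching every ``migration_switch_steps``
    fixes), and each candidate's selection weight is additionally penalized
    by ``migration_strength_per_km`` per km of distance to the current
    target. This emulates range-to-range migration, whose tracks align with
    the connective pathways between focal ranges.
    """
    if step_mean_km <= 0 or step_sd_km <= 0:
        raise ValueError("step_mean_km and step_sd_km must be positive")
    if kernel not in ("gamma", "uniform_disk"):
        raise ValueError("kernel must be 'gamma' or 'uniform_disk'")
    rng = np.random.default_rng(seed)
    shape_k, scale = _gamma_params(step_mean_km * 1000.0, step_sd_km * 1000.0)
    grid = stack.grid
    xmin, ymin, xmax, ymax = grid.bounds
    names = sorted({(k[:-3] if k.endswith("_sq") else k) for k in true_beta if k != "const"})
    tree = fences.tree() if fences is not None and len(fences) else None

    # flat numpy covariate sampler (avoids per-step DataFrame construction)
    static_arrays = {n: stack.layers[n].values for n in names if n in stack.layers}
    need_series = any(n in ("ndvi", "dndvi") for n in names)
    if need_series:
        series_vals = np.stack([r.values for _, r in stack.ndvi_series])
        series_t = np.array([d for d, _ in stack.ndvi_series], dtype="datetime64[s]").astype(float)

    def _eta_at(cx: np.ndarray, cy: np.ndarray, t_sec: float) -> np.ndarray:
        row, col = grid.index_of(cx, cy)
        row = np.clip(row, 0, grid.nrows - 1)
        col = np.clip(col, 0, grid.ncols - 1)
        cov: dict[str, np.ndarray] = {n: a[row, col] for n, a in static_arrays.items()}
        if need_series:
            hi = int(np.clip(np.searchsorted(series_t, t_sec), 1, len(series_t) - 1))
            lo = hi - 1
            w = float(np.clip((t_sec - series_t[lo]) / (series_t[hi] - series_t[lo]), 0.0, 1.0))
            vlo = series_vals[lo, row, col]
            vhi = series_vals[hi, row, col]
            if "ndvi" in names:
                cov["ndvi"] = (1 - w) * vlo + w * vhi
            if "dndvi" in names:
                cov["dndvi"] = vhi - vlo
        eta = np.zeros(len(cx))
        finite = np.ones(len(cx), dtype=bool)
        for key, b in true_beta.items():
            if key == "const":
                continue
            base = key[:-3] if key.endswith("_sq") else key
            v = cov[base]
            finite &= np.isfinite(v)
            eta = eta + b * (v**2 if key.endswith("_sq") else v)
        return np.where(finite, eta, -np.inf)

    # collared animals never start inside an enclosed (fenced) parcel
    enclosed = None
    if tree is not None:
        from .resistance import detect_parcels

        parcels = detect_parcels(fences)
        if parcels:
            enclosed = unary_union([Polygon(p.polygon.exterior) for p in parcels])

    t0 = np.datetime64(start_date, "s")
    dt = np.timedelta64(int(fix_interval_h * 3600), "s")
    trajectories = []
    for a in range(n_animals):
        for _ in range(200):
            x = rng.uniform(xmin + grid.cell_size, xmax - grid.cell_size)
            y = rng.uniform(ymin + grid.cell_size, ymax - grid.cell_size)
            if enclosed is None or not enclosed.contains(Point(x, y)):
                break
        else:
            raise RuntimeError("could not place a start position outside fenced parcels")
        xs, ys, ts = [x], [y], [t0]
        blocked = 0
        for s in range(n_steps):
            t = t0 + (s + 1) * dt
            if kernel == "gamma":
                lengths = rng.gamma(shape_k, scale, size=n_candidates)
            else:
                lengths = step_mean_km * 1000.0 * np.sqrt(rng.uniform(size=n_candidates))
            angles = rng.uniform(0, 2 * np.pi, size=n_candidates)
            cx = x + lengths * np.cos(angles)
            cy = y + lengths * np.sin(angles)
            ok = (cx > xmin) & (cx < xmax) & (cy > ymin) & (cy < ymax)
            if ok.any() and tree is not None:
                for i in np.flatnonzero(ok):
                    seg = LineString([(x, y), (cx[i], cy[i])])
                    if fences.crosses(seg, tree):
                        ok[i] = False
            eta = np.zeros(int(ok.sum()))
            if ok.any() and names:
                eta = _eta_at(cx[ok], cy[ok], float(t.astype("datetime64[s]").astype(float)))
                idx_ok = np.flatnonzero(ok)
                ok[idx_ok[~np.isfinite(eta)]] = False
                eta = eta[np.isfinite(eta)]
            if not ok.any():
                blocked += 1
            else:
                idx_ok = np.flatnonzero(ok)
                if migration_targets is not None:
                    tx, ty = migration_targets[(s // migration_switch_steps) % len(migration_targets)]
                    dist_km = np.hypot(cx[idx_ok] - tx, cy[idx_ok] - ty) / 1000.0
                    eta = eta - migration_strength_per_km * dist_km
                if names or migration_targets is not None:
                    w = np.exp(eta - eta.max())
                    pick = idx_ok[rng.choice(len(idx_ok), p=w / w.sum())]
                else:
                    pick = rng.choice(idx_ok)
                x, y = float(cx[pick]), float(cy[pick])
            xs.append(x)
            ys.append(y)
            ts.append(t)
        trajectories.append(
            Trajectory(
                animal_id=f"animal_{a:02d}",
                times=np.array(ts),
                x=np.array(xs),
                y=np.array(ys),
                fix_interval_h=fix_interval_h,
                meta={"blocked_steps": blocked},
            )
        )
    return trajectories


# -- constructed fenced-corridor world --------------------------------------

@dataclass
class FencedWorld:
    """A landscape whose ground truth is known by construction.

    High-suitability east-west bands (the historic corridors) connect the
    west and east focal ranges; fence "ladders" of enclosed parcels sever
    each band partway along, so the pre-fencing versus fenced contrast and
    the best restoration corridor are known in advance.
    """

    stack: CovariateStack
    true_beta: dict[str, float]
    suitability_true: Raster
    fences: FenceNetwork
    fences_partial: FenceNetwork
    focal: list[FocalRegion]
    corridors: list[Corridor]
    roi: Polygon
    corridor_rows: list[int]


def make_fenced_world(
    seed: int,
    shape: tuple[int, int] = (70, 70),
    cell_size: float = 200.0,
    n_corridors: int = 3,
    band_sigma_cells: float = 3.0,
    band_height: float = 7.0,
    wall_half_cells: int = 7,
    wall_len_cells: int = 12,
    n_distractor_parcels: int = 4,
    roi_half_width_m: float = 800.0,
    partial_fraction: float = 0.4,
) -> FencedWorld:
    """Construct the synthetic severed-corridor study system.

    The TWI covariate carries ``n_corridors`` Gaussian ridge bands; habitat
    selection (``true_beta``) loads positively on TWI, so true suitability is
    high on the bands. Each band is crossed by a vertical ladder of enclosed
    parcels (4 fence lines each) at a corridor-specific longitude, with
    ladder extent ``wall_half_cells`` above/below the band.
    """
    nrows, ncols = shape
    stack = generate_covariates(
        shape,
        cell_size=cell_size,
        correlation_length=3 * cell_size,
        seed=seed,
        layers=["ndvi", "twi", "dist_rivers"],
    )
    grid = stack.grid

    # corridor bands in the upper part of the landscape plus one unfenced
    # southern detour route (slightly poorer habitat, outside the ROI)
    rows = np.arange(nrows)[:, None]
    span = nrows - 10
    band_rows = [int(round((i + 1) * span / (n_corridors + 1))) for i in range(n_corridors)]
    south_row = nrows - 6
    ridge = np.zeros(shape)
    for r0 in band_rows:
        ridge += np.exp(-0.5 * ((rows - r0) / band_sigma_cells) ** 2)
    ridge += 1.0 * np.exp(-0.5 * ((rows - south_row) / band_sigma_cells) ** 2)
    # damp the TWI background noise (sd 1 instead of 2) so the corridor
    # ridges, not noise peaks, dominate the suitability structure
    twi = 8.0 + (stack.layers["twi"].values - 8.0) / 2.0 + band_height * ridge
    stack.layers["twi"] = grid.with_values(twi)

    # TWI has mean ~8 off-band; the ridge lifts it by ~band_height on
    # corridors, so suitability is ~0.12 in the matrix (resistance ~88) and
    # ~0.9 on the bands (resistance ~11): current concentrates on corridors
    # while off-band movement stays possible, as in a grassland matrix.
    true_beta = {"const": -7.2, "twi": 0.6, "ndvi": 0.8}
    cov = stack.covariate_grids(names=["ndvi", "twi"])
    eta = true_beta["const"] + true_beta["twi"] * cov["twi"] + true_beta["ndvi"] * cov["ndvi"]
    suit = grid.with_values(1.0 / (1.0 + np.exp(-eta)))

    # fenced blocks: a grid of small enclosed parcels (2x2 cells each)
    # straddling each corridor band at a corridor-specific longitude; dense
    # enough fencing that current diverts to the southern route
    rng = np.random.default_rng(seed + 1)
    cs = cell_size
    lines: list[LineString] = []
    ids: list[str] = []
    partial_lines: list[LineString] = []
    partial_ids: list[str] = []
    wall_cols = [int(round(ncols * f)) for f in np.linspace(0.38, 0.62, n_corridors)]
    parcel_cells = 2
    for band_i, (r0, c0) in enumerate(zip(band_rows, wall_cols)):
        for r in range(r0 - wall_half_cells, r0 + wall_half_cells, parcel_cells):
            for c in range(c0 - wall_len_cells // 2, c0 + wall_len_cells // 2, parcel_cells):
                x_lo = grid.origin[0] + c * cs
                y_hi = grid.origin[1] - r * cs
                rect = (x_lo, y_hi - parcel_cells * cs, x_lo + parcel_cells * cs, y_hi)
                # the partial (fence-expansion era) network holds a subset of
                # the eventual wall parcels
                in_partial = rng.random() < partial_fraction
                for j, side in enumerate(_rect_lines(*rect)):
                    lines.append(side)
                    ids.append(f"wall{band_i}_r{r - r0 + wall_half_cells:02d}_c{c - c0:+03d}_s{j}")
                    if in_partial:
                        partial_lines.append(side)
                        partial_ids.append(ids[-1])

    # distractor parcels away from the bands
    placed = 0
    guard = 0
    while placed < n_distractor_parcels and guard < 300:
        guard += 1
        r = int(rng.integers(2, nrows - 8))
        c = int(rng.integers(2, ncols - 8))
        if any(abs(r - b) < wall_half_cells + 4 for b in band_rows + [south_row]):
            continue
        x0 = grid.origin[0] + c * cs
        y1 = grid.origin[1] - r * cs
        w = int(rng.integers(2, 5)) * cs
        h = int(rng.integers(2, 5)) * cs
        for j, side in enumerate(_rect_lines(x0, y1 - h, x0 + w, y1)):
            lines.append(side)
            ids.append(f"distractor{placed:02d}_s{j}")
            partial_lines.append(side)
            partial_ids.append(ids[-1])
        placed += 1

    fences = FenceNetwork(lines=lines, ids=ids, meta={"band_rows": band_rows, "wall_cols": wall_cols})
    fences_partial = FenceNetwork(lines=partial_lines, ids=partial_ids, meta={"partial_fraction": partial_fraction})

    # focal ranges: vertical strips at the west and east margins reaching
    # every route (corridor bands and the southern detour), so each route is
    # a parallel path between the two seasonal ranges
    xmin, ymin, xmax, ymax = grid.bounds
    focal = [
        FocalRegion("west", box(xmin, ymin, xmin + 3 * cs, ymax)),
        FocalRegion("east", box(xmax - 3 * cs, ymin, xmax, ymax)),
    ]
    corridors = []
    for i, r0 in enumerate(band_rows):
        _, yc = grid.cell_center(r0, 0)
        xmin, _, xmax, _ = grid.bounds
        corridors.append(
            Corridor(
                corridor_id=f"corridor_{'I' * (i + 1) if i < 3 else i + 1}",
                centerline=LineString([(xmin + 2 * cs, yc), (xmax - 2 * cs, yc)]),
            )
        )
    # one region of interest covering all candidate corridors and their fence
    # walls; the southern detour lies outside it, so diverted current
    # registers as local connectivity loss
    roi_y_hi = grid.origin[1] - (band_rows[0] - wall_half_cells - 2) * cs
    roi_y_lo = grid.origin[1] - (band_rows[-1] + wall_half_cells + 2) * cs
    roi = box(xmin + cs, roi_y_lo, xmax - cs, roi_y_hi)
    return FencedWorld(
        stack=stack,
        true_beta=true_beta,
        suitability_true=suit,
        fences=fences,
        fences_partial=fences_partial,
        focal=focal,
        corridors=corridors,
        roi=roi,
        corridor_rows=band_rows,
    )
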