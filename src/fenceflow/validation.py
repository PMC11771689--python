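"""Presence versus pseudo-absence validation of modeled surfaces.

Tests whether suitability, connectivity, and connectivity change are higher
at independent occurrence locations than at matched pseudo-absences, at a
regional scale (all points) and a local scale (points inside the restoration
region of interest). Each metric is sampled at the points, transformed
(logit for suitability, log for current, identity for change), and fitted
against the presence indicator in a linear mixed model with a per-animal
random intercept; the sign and size of the presence coefficient is the
validation statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
import statsmodels.formula.api as smf
from shapely.geometry import Polygon

from .raster import Raster

TRANSFORMS = ("logit", "log", "none")


@dataclass
class ValidationResult:
    metric: str
    scale: str  # 'regional' | 'local'
    coefficient: float
    se: float
    transform: str
    n: int
    model: str = "lmm_animal_intercept"

    @property
    def z(self) -> float:
        return self.coefficient / self.se if self.se > 0 else np.nan


def extract_metric_at_points(raster: Raster, table: pd.DataFrame, name: str) -> pd.DataFrame:
    """Sample the raster (nearest cell) at the table's points into column ``name``.

    Rows falling outside valid cells are dropped; the count is recorded in
    ``table.attrs``. All points invalid is an error.
    """
    vals = raster.sample(table["x"].to_numpy(float), table["y"].to_numpy(float))
    out = table.copy()
    out[name] = vals
    keep = np.isfinite(vals)
    if not keep.any():
        raise ValueError(f"no points fall on valid cells of metric '{name}'")
    dropped = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["dropped_invalid"] = dropped
    return out


def _apply_transform(values: np.ndarray, transform: str) -> tuple[np.ndarray, dict]:
    info: dict = {}
    if transform == "none":
        return values, info
    if transform == "logit":
        if np.any((values <= 0) | (values >= 1)):
            raise ValueError("logit transform requires values in (0, 1)")
        return np.log(values / (1 - values)), info
    if transform == "log":
        v = values.copy()
        if np.any(v < 0):
            raise ValueError("log transform requires non-negative values")
        if np.any(v == 0):
            pos = v[v > 0]
            offset = float(pos.min()) / 2.0 if pos.size else 1e-12
            info["log_offset"] = offset
            v = v + offset
        return np.log(v), info
    raise ValueError(f"unknown transform '{transform}'; choose from {TRANSFORMS}")


def compare_presence_absence(
    table: pd.DataFrame,
    metric: str,
    transform: str = "none",
    scale_label: str = "regional",
) -> ValidationResult:
    """Presence-effect coefficient for one metric at one scale.

    Fits ``t(metric) ~ is_presence + (1 | animal_id)`` and returns the
    presence coefficient with its SE. Falls back to OLS when the mixed fit is
    degenerate (recorded in ``model``).
    """
    if table["is_presence"].nunique() < 2:
        raise ValueError("both presence and pseudo-absence rows are required")
    y, info = _apply_transform(table[metric].to_numpy(float), transform)
    df = pd.DataFrame(
        {"y": y, "is_presence": table["is_presence"].to_numpy(float), "animal_id": table["animal_id"]}
    )
    model_name = "lmm_animal_intercept"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("y ~ is_presence", df, groups=df["animal_id"]).fit(reml=True)
        coef = float(res.params["is_presence"])
        se = float(res.bse["is_presence"])
        if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
            raise RuntimeError("degenerate mixed fit")
    except Exception:
        res = sm.OLS(df["y"], sm.add_constant(df["is_presence"])).fit()
        coef = float(res.params["is_presence"])
        se = float(res.bse["is_presence"])
        model_name = "ols"
    tname = transform + (f"+offset{info['log_offset']:.3g}" if "log_offset" in info else "")
    return ValidationResult(
        metric=metric, scale=scale_label, coefficient=coef, se=se, transform=tname, n=len(df), model=model_name
    )


def restrict_to_region(table: pd.DataFrame, region: Polygon) -> pd.DataFrame:
    """Rows whose point lies inside the region (the local validation scale)."""
    inside = shapely.contains_xy(region, table["x"].to_numpy(float), table["y"].to_numpy(float))
    return table.loc[inside].reset_index(drop=True)


def validate_metrics(
    table: pd.DataFrame,
    metrics: dict[str, tuple[Raster, str]],
    roi: Polygon | None = None,
) -> pd.DataFrame:
    """Run the full validation design.

    ``metrics`` maps metric name to (raster, transform). Each metric is
    evaluated at the regional scale and, when ``roi`` is given, at the local
    scale restricted to the region of interest. Returns a table shaped like a
    coefficients summary: metric, scale, coefficient, SE, transform, n.
    """
    rows = []
    for name, (raster, transform) in metrics.items():
        aug = extract_metric_at_points(raster, table, name)
        rows.append(compare_presence_absence(aug, name, transform, "regional"))
        if roi is not None:
            local = restrict_to_region(aug, roi)
            if local["is_presence"].nunique() == 2:
                rows.append(compare_presence_absence(local, name, transform, "local"))
    return pd.DataFrame(
        {
            "metric": [r.metric for r in rows],
            "scale": [r.scale for r in rows],
            "coefficient": [r.coefficient for r in rows],
            "se": [r.se for r in rows],
            "transform": [r.transform for r in rows],
            "n": [r.n for r in rows],
            "model": [r.model for r in rows],
        }
    )
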