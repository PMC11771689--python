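"""Resource selection function: presence/pseudo-absence GLMM and prediction.

The selection model contrasts each GPS fix (presence) against pseudo-absence
points drawn area-uniformly within a disk of radius equal to that animal's
maximum observed step length (default 50 per presence). The model is a
logistic mixed model with a per-animal random intercept; every distance
covariate enters with linear and quadratic terms. Covariates are z-scored
before fitting and the scaler is stored with the coefficients so prediction
reapplies it. Prediction sets NDVI to its long-term series mean and the NDVI
change rate to a named snapshot, evaluates the fixed-effect linear predictor
with the random intercept at zero, and maps it through the inverse logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import sparse
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .raster import Raster
from .synthetic import DISTANCE_COVARIATES, CovariateStack, Trajectory

PSEUDO_RATIO_DEFAULT = 50
_EPS = np.finfo(float).eps


@dataclass
class Scaler:
    """Per-covariate z-score parameters, fitted once and reapplied at prediction."""

    mean: dict[str, float]
    sd: dict[str, float]

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: list[str]) -> "Scaler":
        mean, sd = {}, {}
        for c in columns:
            v = df[c].to_numpy(float)
            mean[c] = float(np.mean(v))
            s = float(np.std(v))
            sd[c] = s if s > 0 else 1.0
        return cls(mean=mean, sd=sd)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.mean:
            out[c] = (out[c].to_numpy(float) - self.mean[c]) / self.sd[c]
        return out


@dataclass
class RSFCoefficients:
    """Fitted selection model: fixed effects, SEs, random-intercept SD, scaler."""

    beta: dict[str, float]
    se: dict[str, float]
    random_intercept_sd: float
    scaler: Scaler
    covariate_names: list[str]
    fit_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "random_intercept_sd": self.random_intercept_sd,
            "scaler": {"mean": self.scaler.mean, "sd": self.scaler.sd},
            "covariate_names": self.covariate_names,
            "fit_meta": self.fit_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSFCoefficients":
        return cls(
            beta=d["beta"],
            se=d["se"],
            random_intercept_sd=d["random_intercept_sd"],
            scaler=Scaler(mean=d["scaler"]["mean"], sd=d["scaler"]["sd"]),
            covariate_names=d["covariate_names"],
            fit_meta=d.get("fit_meta", {}),
        )


def design_columns(covariate_names: list[str]) -> list[str]:
    """Design column order: base covariates, then quadratic distance terms."""
    cols = list(covariate_names)
    cols += [f"{c}_sq" for c in covariate_names if c in DISTANCE_COVARIATES]
    return cols


def build_design(
    df: pd.DataFrame, covariate_names: list[str], scaler: Scaler | None = None
) -> tuple[pd.DataFrame, Scaler]:
    """Standardize base covariates and append squared standardized distance terms."""
    if scaler is None:
        scaler = Scaler.fit(df, covariate_names)
    z = scaler.transform(df[covariate_names])
    for c in covariate_names:
        if c in DISTANCE_COVARIATES:
            z[f"{c}_sq"] = z[c] ** 2
    return z[design_columns(covariate_names)], scaler


def standardize_beta(raw_beta: dict[str, float], scaler: Scaler) -> dict[str, float]:
    """Map raw-scale coefficients onto the standardized design's scale.

    For a covariate with raw coefficients ``a`` (linear) and ``b`` (quadratic)
    and z-score parameters (m, s): the standardized-design coefficients are
    ``s*(a + 2*b*m)`` on z and ``b*s**2`` on z**2 (intercepts are absorbed and
    not comparable across parameterizations).
    """
    out: dict[str, float] = {}
    for name, m in scaler.mean.items():
        s = scaler.sd[name]
        a = raw_beta.get(name, 0.0)
        b = raw_beta.get(f"{name}_sq", 0.0)
        out[name] = s * (a + 2.0 * b * m)
        if name in DISTANCE_COVARIATES:
            out[f"{name}_sq"] = b * s**2
    return out


# -- pseudo-absence sampling ------------------------------------------------

def sample_pseudo_absences(
    trajectory: Trajectory,
    stack: CovariateStack,
    pseudo_ratio: int = PSEUDO_RATIO_DEFAULT,
    seed: int | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Presence/pseudo-absence table for one animal.

    Each fix contributes one presence row and ``pseudo_ratio`` absence rows
    placed area-uniformly in the disk of radius equal to the animal's maximum
    observed step length, clipped to the landscape bounds. Time-varying
    covariates are matched to the presence fix's timestamp.
    """
    if len(trajectory) < 2:
        raise ValueError(
            f"trajectory '{trajectory.animal_id}' has a single fix; "
            "maximum step length (the pseudo-absence buffer radius) is undefined"
        )
    rng = np.random.default_rng(seed)
    radius = trajectory.max_step_length()
    if radius <= 0:
        raise ValueError(
            f"trajectory '{trajectory.animal_id}' never moved; "
            "the pseudo-absence buffer radius would be zero"
        )
    grid = stack.grid
    xmin, ymin, xmax, ymax = grid.bounds
    names = covariate_names or stack.covariate_names

    rows = []
    for i in range(len(trajectory)):
        px, py, pt = trajectory.x[i], trajectory.y[i], trajectory.times[i]
        xs = np.empty(pseudo_ratio)
        ys = np.empty(pseudo_ratio)
        got = 0
        while got < pseudo_ratio:
            n = (pseudo_ratio - got) * 2 + 8
            # area-uniform in the disk: r = R * sqrt(u)
            r = radius * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * np.pi, size=n)
            ax, ay = px + r * np.cos(th), py + r * np.sin(th)
            keep = (ax > xmin) & (ax < xmax) & (ay > ymin) & (ay < ymax)
            take = min(int(keep.sum()), pseudo_ratio - got)
            xs[got : got + take] = ax[keep][:take]
            ys[got : got + take] = ay[keep][:take]
            got += take
        all_x = np.concatenate([[px], xs])
        all_y = np.concatenate([[py], ys])
        cov = stack.covariates_at(all_x, all_y, times=np.full(len(all_x), pt), names=names)
        cov.insert(0, "animal_id", trajectory.animal_id)
        cov.insert(1, "is_presence", np.concatenate([[1], np.zeros(pseudo_ratio, int)]))
        cov.insert(2, "timestamp", pt)
        cov.insert(3, "x", all_x)
        cov.insert(4, "y", all_y)
        rows.append(cov)
    table = pd.concat(rows, ignore_index=True)
    bad = ~np.isfinite(table[names].to_numpy(float)).all(axis=1)
    if bad.any():
        table = table.loc[~bad].reset_index(drop=True)
    return table


def build_presence_absence_table(
    trajectories: list[Trajectory],
    stack: CovariateStack,
    pseudo_ratio: int = PSEUDO_RATIO_DEFAULT,
    seed: int | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate per-animal presence/pseudo-absence tables."""
    rng = np.random.default_rng(seed)
    parts = []
    for t in trajectories:
        try:
            parts.append(
                sample_pseudo_absences(
                    t,
                    stack,
                    pseudo_ratio=pseudo_ratio,
                    seed=int(rng.integers(2**31)),
                    covariate_names=covariate_names,
                )
            )
        except ValueError as exc:
            warnings.warn(f"skipping animal: {exc}")
    if not parts:
        raise ValueError("no usable trajectories for the presence/absence table")
    return pd.concat(parts, ignore_index=True)


# -- fitting ----------------------------------------------------------------

def fit_rsf(
    table: pd.DataFrame,
    covariate_names: list[str] | None = None,
    method: str = "mixed",
) -> RSFCoefficients:
    """Fit the logistic mixed selection model.

    ``method='mixed'`` fits a per-animal random-intercept logistic model by
    Laplace/MAP approximation; on failure (or ``method='glm'``) it falls back
    to a fixed-effects logistic regression with animal indicator variables,
    recorded in ``fit_meta['method']``. A small ridge (1e-8) stabilizes
    near-separated designs.
    """
    animals = table["animal_id"].unique()
    if len(animals) < 2:
        raise ValueError("selection model requires >= 2 animals for the random intercept")
    y = table["is_presence"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both presence and pseudo-absence rows are required")
    if covariate_names is None:
        reserved = {"animal_id", "is_presence", "timestamp", "x", "y"}
        covariate_names = [c for c in table.columns if c not in reserved]
    X, scaler = build_design(table, covariate_names)
    cols = list(X.columns)
    Xc = sm.add_constant(X, has_constant="add")

    # intercept offset of the use-availability (case-control) design: the
    # fitted intercept absorbs -log(n_absence/n_presence); prediction adds it
    # back so the suitability scale does not depend on the sampling ratio
    log_ratio = float(np.log((y == 0).sum() / (y == 1).sum()))
    fit_meta: dict = {
        "n": int(len(y)),
        "n_animals": int(len(animals)),
        "log_sampling_ratio": log_ratio,
    }
    if method == "mixed":
        try:
            vc = pd.get_dummies(table["animal_id"]).to_numpy(float)
            model = BinomialBayesMixedGLM(
                y,
                Xc.to_numpy(float),
                exog_vc=sparse.csr_matrix(vc),
                ident=np.zeros(vc.shape[1], dtype=int),
                vcp_p=2.0,
                fe_p=2.0,
            )
            # the MAP optimizer draws its random-effect start values from the
            # global RNG; pin it so fits are deterministic, then restore
            state = np.random.get_state()
            try:
                np.random.seed(0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit_map()
            finally:
                np.random.set_state(state)
            fe = np.asarray(res.fe_mean, float)
            fe_sd = np.asarray(res.fe_sd, float)
            if not (np.isfinite(fe).all() and np.isfinite(fe_sd).all()):
                raise RuntimeError("non-finite mixed-model estimates")
            names_full = ["const"] + cols
            beta = dict(zip(names_full, fe.tolist()))
            se = dict(zip(names_full, fe_sd.tolist()))
            ri_sd = float(np.exp(np.asarray(res.vcp_mean, float)[0]))
            fit_meta.update(method="mixed_laplace", converged=True)
            return RSFCoefficients(beta, se, ri_sd, scaler, list(covariate_names), fit_meta)
        except Exception as exc:  # documented fallback, flagged in fit_meta
            fit_meta["mixed_error"] = str(exc)

    dummies = pd.get_dummies(table["animal_id"], prefix="animal", drop_first=True).astype(float)
    Xg = pd.concat([Xc.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    glm = sm.GLM(y, Xg.to_numpy(float), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit_regularized(alpha=1e-8, L1_wt=0.0)
        # refit unpenalized at the regularized solution for standard errors
        res = glm.fit(start_params=res.params, maxiter=200)
    if not res.converged:
        raise RuntimeError(
            "selection model failed to converge (possible complete separation); "
            f"deviance={res.deviance:.3g}"
        )
    params = np.asarray(res.params, float)
    bse = np.asarray(res.bse, float)
    names_full = ["const"] + cols
    k = len(names_full)
    beta = dict(zip(names_full, params[:k].tolist()))
    se = dict(zip(names_full, bse[:k].tolist()))
    ri_sd = float(np.std(np.concatenate([[0.0], params[k:]]))) if len(params) > k else 0.0
    fit_meta.update(method="glm_animal_dummies", converged=bool(res.converged))
    return RSFCoefficients(beta, se, ri_sd, scaler, list(covariate_names), fit_meta)


# -- prediction -------------------------------------------------------------

def predict_suitability(
    coef: RSFCoefficients,
    stack: CovariateStack,
    dndvi_snapshot=None,
    correct_sampling_ratio: bool = True,
) -> Raster:
    """Population-level suitability surface (random intercept at zero).

    NDVI is set to its long-term series mean and the NDVI change rate to the
    ``dndvi_snapshot`` date (default: mid-series, an early wet-season proxy).
    With ``correct_sampling_ratio`` the case-control intercept offset
    ``log(n_absence/n_presence)`` is added back, so the suitability scale is
    invariant to the pseudo-absence ratio used in fitting. Output values are
    clamped to the open interval (0, 1).
    """
    missing = [c for c in coef.covariate_names if c not in stack.covariate_names]
    if missing:
        raise ValueError(f"stack is missing model covariates: {missing}")
    grids = stack.covariate_grids(dndvi_date=dndvi_snapshot, names=coef.covariate_names)
    shape = stack.grid.shape
    flat = pd.DataFrame({c: grids[c].ravel() for c in coef.covariate_names})
    X, _ = build_design(flat, coef.covariate_names, scaler=coef.scaler)
    intercept = coef.beta.get("const", 0.0)
    if correct_sampling_ratio:
        intercept += coef.fit_meta.get("log_sampling_ratio", 0.0)
    eta = np.full(len(X), intercept)
    for c in X.columns:
        eta += coef.beta[c] * X[c].to_numpy(float)
    s = np.clip(expit(eta), _EPS, 1.0 - _EPS).reshape(shape)
    return stack.grid.with_values(s, kind="suitability")


def suitability_from_raw_beta(stack: CovariateStack, raw_beta: dict[str, float], dndvi_snapshot=None) -> Raster:
    """Suitability implied by raw-scale coefficients (ground truth for simulations)."""
    names = sorted({(k[:-3] if k.endswith("_sq") else k) for k in raw_beta if k != "const"})
    grids = stack.covariate_grids(dndvi_date=dndvi_snapshot, names=names)
    eta = np.full(stack.grid.shape, float(raw_beta.get("const", 0.0)))
    for k, b in raw_beta.items():
        if k == "const":
            continue
        base = k[:-3] if k.endswith("_sq") else k
        eta += b * (grids[base] ** 2 if k.endswith("_sq") else grids[base])
    return stack.grid.with_values(np.clip(expit(eta), _EPS, 1.0 - _EPS), kind="suitability_true")
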