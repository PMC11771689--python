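import numpy as np
import pandas as pd
import pytest

from fenceflow import fit_rsf, predict_suitability, sample_pseudo_absences, simulate_trajectories
from fenceflow.habitat import (
    RSFCoefficients,
    Scaler,
    build_design,
    build_presence_absence_table,
    design_columns,
    standardize_beta,
)


@pytest.fixture(scope="module")
def short_trajectory(small_stack):
    return simulate_trajectories(small_stack, {"twi": 0.5}, 1, 9, step_mean_km=1.0, step_sd_km=0.8, seed=2)[0]


class TestPseudoAbsences:
    def test_fifty_to_one_ratio(self, small_stack, short_trajectory):
        """A 10-fix trajectory at the standard 50:1 ratio yields 500 absences."""
        assert len(short_trajectory) == 10
        table = sample_pseudo_absences(short_trajectory, small_stack, pseudo_ratio=50, seed=0)
        assert (table.is_presence == 1).sum() == 10
        assert (table.is_presence == 0).sum() == 500

    def test_absences_within_max_step_disk(self, small_stack, short_trajectory):
        radius = short_trajectory.max_step_length()
        table = sample_pseudo_absences(short_trajectory, small_stack, pseudo_ratio=20, seed=1)
        for _, grp in table.groupby("timestamp"):
            pres = grp[grp.is_presence == 1].iloc[0]
            d = np.hypot(grp.x - pres.x, grp.y - pres.y)
            assert (d <= radius + 1e-9).all()

    def test_determinism(self, small_stack, short_trajectory):
        a = sample_pseudo_absences(short_trajectory, small_stack, pseudo_ratio=1, seed=42)
        b = sample_pseudo_absences(short_trajectory, small_stack, pseudo_ratio=1, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_single_fix_rejected(self, small_stack):
        from fenceflow.synthetic import Trajectory

        t = Trajectory("x", np.array(["2011-01-01"], dtype="datetime64[s]"), np.array([500.0]), np.array([500.0]), 3.0)
        with pytest.raises(ValueError, match="single fix"):
            sample_pseudo_absences(t, small_stack)


def _sim_table(stack, beta, seed, n_animals=6, n_steps=80, ratio=8):
    # uniform-disk kernel with the disk covering the whole (4x4 km) landscape:
    # availability matches the pseudo-absence design, so estimates are
    # comparable to the simulated truth
    rng = np.random.default_rng(seed)
    trajs = simulate_trajectories(
        stack, beta, n_animals, n_steps, step_mean_km=6, step_sd_km=4, seed=int(rng.integers(2**31)),
        kernel="uniform_disk", n_candidates=600,
    )
    return build_presence_absence_table(
        trajs, stack, pseudo_ratio=ratio, seed=int(rng.integers(2**31)), covariate_names=["ndvi", "twi", "dist_rivers"]
    )


class TestFitRSF:
    def test_preconditions(self, small_stack):
        table = _sim_table(small_stack, {"twi": 0.3}, 1, n_animals=2, n_steps=20, ratio=2)
        one_animal = table[table.animal_id == table.animal_id.iloc[0]]
        with pytest.raises(ValueError, match="2 animals"):
            fit_rsf(one_animal)
        with pytest.raises(ValueError, match="presence"):
            fit_rsf(table[table.is_presence == 0])

    def test_null_covariate_ci_covers_zero(self, small_stack):
        """A permuted covariate should carry no detectable effect."""
        table = _sim_table(small_stack, {"twi": 0.5}, 3)
        rng = np.random.default_rng(0)
        table["dist_rivers"] = rng.permutation(table["dist_rivers"].to_numpy())
        coef = fit_rsf(table)
        for name in ("dist_rivers", "dist_rivers_sq"):
            assert abs(coef.beta[name]) < 2.5 * coef.se[name]

    def test_duplicated_data_same_estimates_smaller_se(self, small_stack):
        table = _sim_table(small_stack, {"twi": 0.5}, 4, n_animals=4, n_steps=40, ratio=4)
        doubled = pd.concat([table, table], ignore_index=True)
        a = fit_rsf(table, method="glm")
        b = fit_rsf(doubled, method="glm")
        for k in a.beta:
            if k == "const":
                continue
            assert a.beta[k] == pytest.approx(b.beta[k], abs=1e-5)
            assert b.se[k] < a.se[k]

    def test_row_order_invariance(self, small_stack):
        table = _sim_table(small_stack, {"twi": 0.5}, 5, n_animals=3, n_steps=30, ratio=3)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_rsf(table, method="glm")
        b = fit_rsf(shuffled, method="glm")
        for k in a.beta:
            assert a.beta[k] == pytest.approx(b.beta[k], abs=1e-6)

    def test_recovery_single_replicate(self, small_stack):
        """Estimates from matched-availability simulation land near truth."""
        beta = {"ndvi": 1.5, "twi": 0.4, "dist_rivers": 4e-4, "dist_rivers_sq": -6e-8}
        table = _sim_table(small_stack, beta, 6, n_animals=8, n_steps=150)
        coef = fit_rsf(table)
        truth = standardize_beta(beta, coef.scaler)
        for k in ("ndvi", "twi"):
            assert coef.beta[k] == pytest.approx(truth[k], abs=4 * coef.se[k])


class TestPredictSuitability:
    def test_zero_coefficients_give_half(self, small_stack):
        names = ["ndvi", "twi", "dist_rivers"]
        cols = ["const"] + design_columns(names)
        coef = RSFCoefficients(
            beta={c: 0.0 for c in cols},
            se={c: 0.0 for c in cols},
            random_intercept_sd=0.0,
            scaler=Scaler(mean={n: 0.0 for n in names}, sd={n: 1.0 for n in names}),
            covariate_names=names,
        )
        s = predict_suitability(coef, small_stack)
        np.testing.assert_allclose(s.values, 0.5)

    def test_monotone_in_single_layer(self, small_stack):
        names = ["twi"]
        coef = RSFCoefficients(
            beta={"const": 0.0, "twi": 2.0},
            se={},
            random_intercept_sd=0.0,
            scaler=Scaler(mean={"twi": 8.0}, sd={"twi": 2.0}),
            covariate_names=names,
        )
        s = predict_suitability(coef, small_stack)
        twi = small_stack.layers["twi"].values.ravel()
        order = np.argsort(twi)
        assert np.all(np.diff(s.values.ravel()[order]) >= 0)
        assert np.all((s.values > 0) & (s.values < 1))

    def test_missing_layer_named(self, small_stack):
        coef = RSFCoefficients(
            beta={"const": 0.0, "footprint": 1.0},
            se={},
            random_intercept_sd=0.0,
            scaler=Scaler(mean={"footprint": 0.0}, sd={"footprint": 1.0}),
            covariate_names=["footprint"],
        )
        with pytest.raises(ValueError, match="footprint"):
            predict_suitability(coef, small_stack)

    def test_sampling_ratio_correction_invariance(self, small_stack):
        """Predicted suitability scale is stable across pseudo-absence ratios."""
        beta = {"twi": 0.5}
        t1 = _sim_table(small_stack, beta, 8, n_animals=4, n_steps=60, ratio=3)
        t2 = _sim_table(small_stack, beta, 8, n_animals=4, n_steps=60, ratio=12)
        s1 = predict_suitability(fit_rsf(t1, method="glm"), small_stack)
        s2 = predict_suitability(fit_rsf(t2, method="glm"), small_stack)
        assert abs(np.mean(s1.values) - np.mean(s2.values)) < 0.1


def test_design_standardization_roundtrip(small_stack):
    xx, yy = small_stack.grid.centers()
    df = small_stack.covariates_at(xx.ravel(), yy.ravel())
    X, scaler = build_design(df, ["ndvi", "twi", "dist_rivers"])
    assert list(X.columns) == ["ndvi", "twi", "dist_rivers", "dist_rivers_sq"]
    np.testing.assert_allclose(X["ndvi"].mean(), 0, atol=1e-9)
    np.testing.assert_allclose(X["ndvi"].to_numpy().std(), 1, atol=1e-6)  # population sd
    np.testing.assert_allclose(X["dist_rivers_sq"], X["dist_rivers"] ** 2)
    X2, _ = build_design(df.iloc[:10], ["ndvi", "twi", "dist_rivers"], scaler=scaler)
    np.testing.assert_allclose(X2.to_numpy(), X.iloc[:10].to_numpy())


def test_standardize_beta_quadratic_mapping():
    """Raw a*d + b*d^2 maps exactly onto the standardized (z, z^2) basis."""
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 100, 500)
    a, b = 0.03, -2e-4
    m, s = d.mean(), d.std()
    z = (d - m) / s
    raw = a * d + b * d**2
    mapped = standardize_beta({"dist_rivers": a, "dist_rivers_sq": b}, Scaler(mean={"dist_rivers": m}, sd={"dist_rivers": s}))
    rebuilt = mapped["dist_rivers"] * z + mapped["dist_rivers_sq"] * z**2
    np.testing.assert_allclose(rebuilt - rebuilt.mean(), raw - raw.mean(), atol=1e-9)


def test_serialization_roundtrip(small_stack):
    table = _sim_table(small_stack, {"twi": 0.5}, 9, n_animals=3, n_steps=30, ratio=3)
    coef = fit_rsf(table, method="glm")
    back = RSFCoefficients.from_dict(coef.to_dict())
    s1 = predict_suitability(coef, small_stack)
    s2 = predict_suitability(back, small_stack)
    np.testing.assert_array_equal(s1.values, s2.values)
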