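"""Least-squares re-parameterization and OLS validation statistics."""

import numpy as np
import pandas as pd
import pytest

from idpsol import (
    PUBLISHED_PARAMS,
    ExperimentalSeries,
    SolubilityModel,
    SolubilityModelParams,
    fit_parameters,
    predict_solubility,
    validate_predictions,
)
from idpsol.errors import DegenerateDesignError, ZeroVarianceError


def make_design(n, seed=0, sd=0.0, params=PUBLISHED_PARAMS):
    """Direct (L, |Q|) draws spanning the surface, with optional noise."""
    rng = np.random.default_rng(seed)
    lipo = rng.uniform(-1.0, 0.2, n)
    q = rng.uniform(0.0, 95.0, n)
    s = predict_solubility(lipo, q, params) + rng.normal(0.0, sd, n)
    return pd.DataFrame(
        {
            "variant": "sim",
            "ph": np.linspace(2, 12, n),
            "lipophilicity": lipo,
            "abs_net_charge": q,
            "solubility": s,
        }
    )


class TestFitParameters:
    def test_noiseless_data_recovered_exactly(self):
        data = make_design(30)
        res = fit_parameters(data)
        np.testing.assert_allclose(
            res.params.as_array(), PUBLISHED_PARAMS.as_array(), rtol=1e-6
        )
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_observation_order_is_irrelevant(self):
        data = make_design(40, seed=1, sd=1.0)
        shuffled = data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = fit_parameters(data)
        b = fit_parameters(shuffled)
        np.testing.assert_allclose(a.params.as_array(), b.params.as_array(), rtol=1e-7)
        assert a.rss == pytest.approx(b.rss, rel=1e-9)

    def test_iterative_fit_matches_closed_form(self):
        data = make_design(50, seed=2, sd=2.0)
        model = SolubilityModel(data)
        nlls = model.fit(method="nlls")
        linear = model.fit(method="linear")
        np.testing.assert_allclose(
            nlls.params.as_array(), linear.params.as_array(), rtol=1e-8
        )

    def test_init_does_not_change_the_optimum(self):
        data = make_design(40, seed=4, sd=1.5)
        a = fit_parameters(data)
        b = fit_parameters(
            data, init=SolubilityModelParams(alpha=0, beta=0, gamma=0, delta=0)
        )
        np.testing.assert_allclose(a.params.as_array(), b.params.as_array(), rtol=1e-6)

    def test_estimates_fall_within_three_standard_errors(self):
        """Monte-Carlo calibration of the reported standard errors.

        With Gaussian noise the studentized errors are ~N(0,1), so all
        four estimates land within 3 standard errors in at least ~98.9%
        of replicates; the assertion allows for Monte-Carlo error on top.
        """
        n_rep, n = 200, 100
        th0 = PUBLISHED_PARAMS.as_array()
        names = ("alpha", "beta", "gamma", "delta")
        hits = 0
        for k in range(n_rep):
            data = make_design(n, seed=k, sd=2.0)
            res = fit_parameters(data, method="linear")
            err = np.abs(res.params.as_array() - th0)
            se = np.array([res.bse[nm] for nm in names])
            hits += bool(np.all(err <= 3.0 * se))
        assert hits / n_rep >= 0.98

    def test_rss_never_increases_when_adding_on_surface_point(self):
        data = make_design(30, seed=5, sd=1.0)
        res = fit_parameters(data)
        new_point = pd.DataFrame(
            {
                "variant": ["extra"],
                "ph": [7.0],
                "lipophilicity": [-0.3],
                "abs_net_charge": [12.0],
                "solubility": [res.predict(-0.3, 12.0)],
            }
        )
        res2 = fit_parameters(pd.concat([data, new_point], ignore_index=True))
        assert res2.rss <= res.rss + 1e-9

    def test_degenerate_design_raises_naming_columns(self):
        data = make_design(20, seed=6)
        data["abs_net_charge"] = 5.0  # constant charge -> beta/gamma collinear
        with pytest.raises(DegenerateDesignError):
            fit_parameters(data)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters(make_design(4))

    def test_summary_mentions_all_parameters(self):
        res = fit_parameters(make_design(30, seed=7, sd=0.5))
        text = res.summary()
        for name in ("alpha", "beta", "gamma", "delta"):
            assert name in text


class TestValidatePredictions:
    def test_perfectly_collinear_data(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        res = validate_predictions(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_response_errors(self):
        with pytest.raises(ZeroVarianceError):
            validate_predictions([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_matches_textbook_ols_arithmetic(self):
        # n=6 hand-checkable dataset; oracle: explicit OLS formulas
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 9.9, 12.3])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = sxy**2 / (sxx * syy)
        from scipy import stats as ss

        t = np.sqrt(r2) * np.sqrt((6 - 2) / (1 - r2))
        p = 2 * ss.t.sf(t, 6 - 2)
        res = validate_predictions(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.r_squared == pytest.approx(r2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_r2_and_p_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(scale=0.3, size=12)
        a = validate_predictions(x, y)
        b = validate_predictions(7.0 * x - 3.0, y)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_orientation_flag_sets_expected_slope_sign(self):
        pred = np.array([10.0, 20.0, 30.0, 40.0])
        kapp = ExperimentalSeries(
            ph=(3.0, 5.0, 7.0, 9.0),
            values=(8.0, 5.5, 3.0, 1.2),
            label="Kapp",
            aggregation_oriented=True,
        )
        res = validate_predictions(pred, kapp)
        assert res.expected_slope_sign == -1
        assert res.slope_sign_consistent is True

    def test_confidence_band_contains_the_fit_and_widens_at_edges(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 15)
        y = 2 * x + rng.normal(scale=1.0, size=15)
        res = validate_predictions(x, y)
        grid = np.array([0.0, 5.0, 10.0])
        lo, hi = res.confidence_band(grid)
        fit = res.intercept + res.slope * grid
        assert np.all(lo < fit) and np.all(fit < hi)
        width = hi - lo
        assert width[0] > width[1] and width[2] > width[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            validate_predictions([1.0, 2.0], [1.0, 2.0])
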