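"""Logistic occurrence model: scaling, ML fitting, AIC selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from gullcast import (
    DegenerateCovariateError,
    FormatError,
    fit_glm,
    load_occurrence,
    predict,
    save_occurrence,
    scale,
    screen_categories,
    select_model,
)
from gullcast.occurrence import OccurrenceModel, Scaling

from oracles import brute_force_logistic


def logistic_frame(rng, n=200, betas=(-1.0, 1.2, -0.5), cols=("x1", "x2")):
    x = rng.normal(size=(n, len(cols)))
    eta = betas[0] + x @ np.array(betas[1:])
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    df = pd.DataFrame(x, columns=list(cols))
    df["presence"] = y
    return df


class TestScaling:
    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        df = logistic_frame(rng)
        scaled, scaling = scale(df)
        for c in ("x1", "x2"):
            assert scaled[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert scaled[c].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert "presence" not in scaling.mean

    def test_training_mean_maps_to_zero(self):
        scaling = Scaling(mean={"x": 5.0}, sd={"x": 2.0})
        assert scaling.transform_value("x", 5.0) == 0.0

    def test_reuse_is_idempotent_on_training_data(self):
        rng = np.random.default_rng(1)
        df = logistic_frame(rng)
        scaled1, scaling = scale(df)
        scaled2, _ = scale(df, scaling)
        pd.testing.assert_frame_equal(scaled1, scaled2)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [3.0, 3.0, 3.0], "presence": [0, 1, 0]})
        with pytest.raises(DegenerateCovariateError):
            scale(df)


class TestFitGlm:
    def test_intercept_only_matches_sample_logit(self):
        # class counts mirroring the de-duplicated monitoring dataset
        y = np.array([1] * 33 + [0] * 145)
        df = pd.DataFrame({"presence": y})
        model = fit_glm(df, [])
        assert model.coefficients["intercept"] == pytest.approx(
            np.log(33 / 145), abs=1e-6
        )
        assert model.coefficients["intercept"] == pytest.approx(-1.480, abs=5e-4)
        assert model.k == 1

    def test_aic_identity(self):
        rng = np.random.default_rng(2)
        df, _ = scale(logistic_frame(rng))
        model = fit_glm(df, ["x1", "x2"])
        assert model.aic == pytest.approx(
            -2 * model.log_likelihood + 2 * model.k, abs=1e-10
        )
        assert model.k == 3

    def test_agrees_with_nelder_mead_oracle(self):
        rng = np.random.default_rng(3)
        df, _ = scale(logistic_frame(rng, n=30))
        model = fit_glm(df, ["x1", "x2"])
        x = np.column_stack([np.ones(30), df["x1"], df["x2"]])
        y = df["presence"].to_numpy(float)
        start = np.array(
            [model.coefficients["intercept"],
             model.coefficients["x1"], model.coefficients["x2"]]
        )
        beta, ll = brute_force_logistic(x, y, beta0=start + 0.3)
        assert np.max(np.abs(beta - start)) < 1e-4
        assert ll == pytest.approx(model.log_likelihood, abs=1e-8)

    def test_mean_fitted_probability_equals_sample_rate(self):
        rng = np.random.default_rng(4)
        df, scaling = scale(logistic_frame(rng, n=300))
        model = fit_glm(df, ["x1", "x2"], scaling)
        probs = [
            predict(model, x1=row.x1 * scaling.sd["x1"] + scaling.mean["x1"],
                    x2=row.x2 * scaling.sd["x2"] + scaling.mean["x2"])
            for row in df.itertuples()
        ]
        assert np.mean(probs) == pytest.approx(df["presence"].mean(), abs=1e-6)

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x1": [0.1, 0.2, 0.3], "presence": [1, 1, 1]})
        with pytest.raises(FormatError):
            fit_glm(df, ["x1"])

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame(
            {"x1": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0],
             "presence": [0, 0, 0, 1, 1, 1]}
        )
        model = fit_glm(df, ["x1"])
        assert not model.converged

    def test_singular_design_names_terms(self):
        rng = np.random.default_rng(5)
        df, _ = scale(logistic_frame(rng))
        df["x3"] = df["x1"]
        with pytest.raises(FormatError, match="x3"):
            fit_glm(df, ["x1", "x2", "x3"])


class TestSelection:
    @pytest.fixture
    def signal_frame(self):
        """lat24 drives presence; other family members are noisier copies."""
        rng = np.random.default_rng(6)
        n = 1000
        lat24 = rng.normal(48, 3, n)
        df = pd.DataFrame(
            {
                "lat24": lat24,
                "lat48": lat24 + rng.normal(0, 6, n),
                "lat72": rng.normal(48, 3, n),
                "deg24": rng.uniform(0, 360, n),
                "deg48": rng.uniform(0, 360, n),
                "deg72": rng.uniform(0, 360, n),
                "ice_whole": rng.random(n),
                "ice_north": rng.random(n),
                "ice_south": rng.random(n),
                "duration_min": rng.uniform(30, 180, n),
                "date_ordinal": rng.integers(1, 120, n).astype(float),
            }
        )
        eta = -1.0 + 1.5 * (df.lat24 - 48) / 3
        df["presence"] = rng.random(n) < 1 / (1 + np.exp(-eta))
        return df

    def test_lat_family_winner_is_lat24(self, signal_frame):
        winners = screen_categories(signal_frame)
        assert winners["lat"] == "lat24"
        assert set(winners) == {"ice", "lat", "deg"}

    def test_winner_beats_family_losers(self, signal_frame):
        scaled, scaling = scale(signal_frame)
        aics = {
            m: fit_glm(scaled, [m, "duration_min"], scaling).aic
            for m in ("lat24", "lat48", "lat72")
        }
        assert aics["lat24"] <= min(aics.values())

    def test_identical_members_tie_to_family_order(self, signal_frame):
        df = signal_frame.copy()
        df["lat48"] = df["lat24"] + 0.0
        winners = screen_categories(df)
        assert winners["lat"] == "lat24"

    def test_ranked_table_best_row(self, signal_frame):
        table, best = select_model(signal_frame)
        assert table["dAIC"].iloc[0] == 0.0
        assert (table["dAIC"].values >= 0).all()
        assert len(table) == 32
        assert "lat24" in best.terms

    def test_best_model_aic_is_minimum(self, signal_frame):
        table, best = select_model(signal_frame)
        assert best.aic == pytest.approx(table["AIC"].min())


class TestPredict:
    def make_model(self, coefs, scaling=None):
        terms = [t for t in coefs if t != "intercept"]
        k = len(terms) + 1
        return OccurrenceModel(
            terms=terms, coefficients=coefs, log_likelihood=-50.0, k=k,
            aic=100.0 + 2 * k,
            scaling=scaling or Scaling(
                mean={t: 0.0 for t in terms}, sd={t: 1.0 for t in terms}
            ),
        )

    def test_intercept_probability_at_covariate_means(self):
        model = self.make_model(
            {"intercept": -2.38, "lat24": 1.74, "date_ordinal": 0.48,
             "duration_min": 0.59}
        )
        p = predict(model, lat24=0.0, date_ordinal=0.0, duration_min=0.0)
        assert p == pytest.approx(1 / (1 + np.exp(2.38)), abs=1e-12)
        assert p == pytest.approx(0.0847, abs=5e-5)

    def test_all_zero_coefficients_give_half(self):
        model = self.make_model(
            {"intercept": 0.0, "lat24": 0.0, "date_ordinal": 0.0,
             "duration_min": 0.0}
        )
        assert predict(model, lat24=3.0, date_ordinal=50, duration_min=60) == 0.5

    def test_monotone_in_lat24(self):
        model = self.make_model(
            {"intercept": -2.38, "lat24": 1.74, "date_ordinal": 0.48,
             "duration_min": 0.59},
            Scaling(
                mean={"lat24": 46.0, "date_ordinal": 60.0, "duration_min": 77.0},
                sd={"lat24": 2.0, "date_ordinal": 30.0, "duration_min": 60.0},
            ),
        )
        grid = np.linspace(40, 58, 40)
        probs = [predict(model, lat24=g, date_ordinal=60, duration_min=60)
                 for g in grid]
        assert np.all(np.diff(probs) > 0)

    def test_missing_term_rejected(self):
        model = self.make_model({"intercept": 0.0, "lat24": 1.0})
        with pytest.raises(FormatError):
            predict(model, date_ordinal=10)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        df, scaling = scale(logistic_frame(rng))
        model = fit_glm(df, ["x1", "x2"], scaling)
        path = tmp_path / "occ.json"
        save_occurrence(model, path)
        back = load_occurrence(path)
        assert back.coefficients == pytest.approx(model.coefficients)
        assert back.aic == pytest.approx(model.aic)
        assert back.scaling.mean == pytest.approx(model.scaling.mean)
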