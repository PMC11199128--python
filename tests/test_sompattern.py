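"""SOM training, BMU assignment, node probabilities and Method A lookup."""

import numpy as np
import pytest

from gullcast import (
    FormatError,
    GridField,
    NodeProbabilityTable,
    TrainingError,
    assign_node,
    forecast_method_a,
    load_node_table,
    load_som,
    node_probabilities,
    save_node_table,
    save_som,
    train_som,
)
from gullcast.sompattern import _bmus, _pca_init


def cluster_data(rng, n_per=50, dim=20, separation=50.0, spread=1.0):
    a = rng.normal(0.0, spread, (n_per, dim))
    b = rng.normal(0.0, spread, (n_per, dim)) + separation / np.sqrt(dim)
    return a, b


class TestTraining:
    def test_degenerate_identical_inputs(self):
        x = np.tile(np.arange(10.0), (20, 1))
        model = train_som(x, rows=2, cols=2, iterations=30)
        np.testing.assert_allclose(model.codebook, np.tile(np.arange(10.0), (4, 1)))
        assert model.quantization_error == pytest.approx(0.0, abs=1e-9)

    def test_two_clusters_separate(self):
        rng = np.random.default_rng(0)
        a, b = cluster_data(rng)
        x = np.vstack([a, b])
        model = train_som(x, iterations=50)
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        for row in x:
            node, _ = assign_node(model, row)
            code = model.codebook[node]
            own = ma if np.linalg.norm(row - ma) < np.linalg.norm(row - mb) else mb
            other = mb if own is ma else ma
            assert np.linalg.norm(code - own) < np.linalg.norm(code - other)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 30))
        m1 = train_som(x, iterations=20, seed=3)
        m2 = train_som(x, iterations=20, seed=3)
        np.testing.assert_array_equal(m1.codebook, m2.codebook)

    def test_training_reduces_quantization_error(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 25)) * 5.0
        init = _pca_init(x, 4, 4)
        _, d0 = _bmus(init, x)
        model = train_som(x, iterations=60)
        assert model.quantization_error <= d0.mean()

    def test_node_frequency_sums_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(64, 12))
        model = train_som(x, iterations=20)
        assert model.node_frequency.sum() == pytest.approx(1.0)

    def test_too_few_patterns_rejected(self):
        with pytest.raises(TrainingError):
            train_som(np.eye(8), rows=4, cols=4)


class TestAssign:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(4)
        return train_som(rng.normal(size=(60, 16)), iterations=20)

    def test_codebook_vector_maps_to_itself(self, model):
        node, dist = assign_node(model, model.codebook[5])
        assert node == 5 and dist == pytest.approx(0.0, abs=1e-9)

    def test_tie_breaks_to_lowest_id(self, model):
        code = model.codebook.copy()
        code[7] = code[2]  # exact duplicate
        model.codebook = code
        node, _ = assign_node(model, code[7])
        assert node == 2

    def test_translation_invariance(self, model):
        pattern = model.codebook[3] + 0.1
        n1, d1 = assign_node(model, pattern)
        model2 = train_som(
            np.random.default_rng(4).normal(size=(60, 16)), iterations=20
        )
        model2.codebook = model.codebook + 100.0
        n2, d2 = assign_node(model2, pattern + 100.0)
        assert n1 == n2 and d1 == pytest.approx(d2, abs=1e-8)

    def test_length_mismatch(self, model):
        with pytest.raises(FormatError):
            assign_node(model, np.zeros(7))


class TestNodeProbabilities:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(5)
        return train_som(rng.normal(size=(100, 9)) * 3, iterations=30)

    def test_worked_cell_8_of_12(self, model):
        code = model.codebook
        days = [(code[4], True)] * 8 + [(code[4], False)] * 4
        table = node_probabilities(model, days)
        assert table.n_days[4] == 12 and table.n_sighted[4] == 8
        assert table.probability[4] == pytest.approx(8 / 12, abs=1e-12)
        assert round(float(table.probability[4]), 3) == 0.667

    def test_conservation_identities(self, model):
        rng = np.random.default_rng(6)
        patterns = rng.normal(size=(75, 9)) * 3
        sighted = rng.random(75) < 0.3
        table = node_probabilities(model, zip(patterns, sighted))
        assert table.n_days.sum() == 75
        assert table.n_sighted.sum() == sighted.sum()
        # n-weighted mean node probability == overall sighting rate
        p = np.where(table.n_days > 0, table.probability, 0.0)
        weighted = (p * table.n_days).sum() / table.n_days.sum()
        assert weighted == pytest.approx(sighted.mean(), abs=1e-12)

    def test_empty_node_flagged_missing(self, model):
        days = [(model.codebook[0], True)]
        table = node_probabilities(model, days)
        assert table.missing[1] and not table.missing[0]
        assert np.isnan(table.probability[1])

    def test_never_sighted_node_is_zero_not_missing(self, model):
        table = node_probabilities(model, [(model.codebook[2], False)] * 7)
        assert table.probability[2] == 0.0 and not table.missing[2]


def field_from_vector(vec, lats, lons):
    return GridField(
        "slp", "hPa", lats, lons,
        np.array([np.datetime64("2020-01-01")]),
        np.asarray(vec).reshape(1, len(lats), len(lons)),
    )


class TestForecastMethodA:
    @pytest.fixture
    def setup(self):
        lats = np.array([44.0, 45.25, 46.5])
        lons = np.array([144.0, 145.25, 146.5])
        rng = np.random.default_rng(7)
        patterns = 1000.0 + 5.0 * rng.normal(size=(40, 9))
        model = train_som(patterns, iterations=30, latitudes=lats, longitudes=lons)
        days = [(model.codebook[6], True)] * 6 + [(model.codebook[6], False)]
        table = node_probabilities(model, days)
        return model, table, lats, lons

    def test_codebook_snapshot_returns_node_probability(self, setup):
        model, table, lats, lons = setup
        snap = field_from_vector(model.codebook[6], lats, lons)
        prob, node, dist = forecast_method_a(model, table, snap)
        assert node == 6 and dist == pytest.approx(0.0, abs=1e-9)
        assert prob == pytest.approx(6 / 7, abs=1e-12)
        assert round(100 * prob, 1) == 85.7

    def test_unobserved_node_reports_missing(self, setup):
        model, table, lats, lons = setup
        other = next(k for k in range(model.n_nodes) if table.missing[k])
        snap = field_from_vector(model.codebook[other], lats, lons)
        prob, node, _ = forecast_method_a(model, table, snap)
        assert prob is None and node == other

    def test_counts_drive_the_forecast(self, setup):
        model, table, lats, lons = setup
        snap = field_from_vector(model.codebook[6], lats, lons)
        table.n_sighted[6] = 0
        prob, _, _ = forecast_method_a(model, table, snap)
        assert prob == 0.0

    def test_grid_mismatch_rejected(self, setup):
        model, table, lats, lons = setup
        snap = field_from_vector(model.codebook[6], lats + 10.0, lons)
        with pytest.raises(FormatError):
            forecast_method_a(model, table, snap)


class TestPersistence:
    def test_som_round_trip(self, tmp_path):
        lats = np.array([44.0, 45.25])
        lons = np.array([144.0, 145.25, 146.5])
        rng = np.random.default_rng(8)
        model = train_som(
            1000 + rng.normal(size=(30, 6)), iterations=15,
            latitudes=lats, longitudes=lons,
        )
        path = tmp_path / "som.nc"
        save_som(model, path)
        back = load_som(path)
        np.testing.assert_allclose(back.codebook, model.codebook)
        np.testing.assert_allclose(back.node_frequency, model.node_frequency)
        assert back.grid_rows == 4 and back.n_inputs == 30

    def test_table_round_trip(self, tmp_path):
        table = NodeProbabilityTable(
            n_days=np.array([3, 0, 12]), n_sighted=np.array([1, 0, 8])
        )
        path = tmp_path / "t.json"
        save_node_table(table, path)
        back = load_node_table(path)
        np.testing.assert_array_equal(back.n_days, table.n_days)
        assert back.missing[1] and back.probability[2] == pytest.approx(8 / 12)


class TestNodeWindCoupling:
    """Nodes whose composite winds are northerly at the site must carry
    higher sighting probabilities when the truth rewards northerly flow."""

    def test_rank_correlation_node_wind_vs_probability(self, big_season):
        from scipy.stats import spearmanr

        from gullcast import gen_sightings, interp_space_time
        from gullcast.metfields import daily_mean, flatten_pattern

        slp, winds, _ = big_season
        recs = gen_sightings(1000, winds, seed=41)
        patterns, v_site, sighted = [], [], []
        for r in recs:
            patterns.append(flatten_pattern(daily_mean(slp, r.date)))
            t = np.datetime64(r.date.isoformat())
            v_site.append(interp_space_time(winds.v, 45.0, 145.0, t))
            sighted.append(r.presence)
        days = sorted({str(t.astype("datetime64[D]")) for t in slp.times})
        som = train_som(
            [flatten_pattern(daily_mean(slp, d)) for d in days], iterations=40
        )
        table = node_probabilities(som, zip(patterns, sighted))
        nodes = [assign_node(som, p)[0] for p in patterns]
        v_mean, probs = [], []
        for k in range(som.n_nodes):
            members = [v for v, n in zip(v_site, nodes) if n == k]
            if members and table.n_days[k] > 0:
                v_mean.append(np.mean(members))
                probs.append(table.probability[k])
        rho, _ = spearmanr(v_mean, probs)
        assert rho < 0.0  # northerly composite wind (v<0) -> higher probability
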