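"""Tests for occurrence handling, forest ensembles, feature contributions and
threshold extraction."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from metidx import sdm


def _layers(nlat=8, nlon=8, seed=0):
    rng = np.random.default_rng(seed)
    coords = {"lat": np.arange(nlat, dtype=float),
              "lon": np.arange(nlon, dtype=float)}
    return xr.Dataset({
        "min_phi": xr.DataArray(rng.uniform(1, 5, (nlat, nlon)), coords=coords,
                                dims=("lat", "lon")),
        "depth": xr.DataArray(rng.uniform(0, 100, (nlat, nlon)), coords=coords,
                              dims=("lat", "lon"))})


class TestDedupe:
    def test_many_points_one_cell(self):
        pts = pd.DataFrame({"lon": [2.1, 2.2, 1.9, 2.0, 2.3],
                            "lat": [3.0, 3.1, 3.2, 2.9, 2.8]})
        occ = sdm.dedupe_occurrences(pts, np.arange(8.0), np.arange(8.0))
        assert len(occ) == 1 and occ.n_points == 5

    def test_edge_point_assigned_to_one_cell(self):
        # cell centers at integers, so edges fall at half-integers; a point
        # exactly on an edge belongs to the cell whose lower edge it is
        pts = pd.DataFrame({"lon": [2.5], "lat": [3.5]})
        occ = sdm.dedupe_occurrences(pts, np.arange(8.0), np.arange(8.0))
        assert occ.cells.tolist() == [[4, 3]]

    def test_out_of_domain_counted(self):
        pts = pd.DataFrame({"lon": [2.0, 99.0], "lat": [2.0, 2.0]})
        occ = sdm.dedupe_occurrences(pts, np.arange(8.0), np.arange(8.0))
        assert occ.n_out_of_domain == 1 and len(occ) == 1

    def test_synthetic_bookkeeping_matches(self, small_world):
        env = small_world["env"]["contemporary"]
        occ_pts = small_world["occurrences"]
        occ = sdm.dedupe_occurrences(occ_pts, env["lat"].values, env["lon"].values)
        expect = {(a, b) for a, b in
                  occ_pts[["cell_ilat", "cell_ilon"]].itertuples(index=False)}
        assert {tuple(c) for c in occ.cells} == expect


class TestPseudoAbsences:
    def test_exclusion_zone_and_determinism(self):
        dm = np.ones((10, 10), bool)
        presence = np.array([[4, 4], [7, 2]])
        rng = np.random.default_rng(5)
        cells = sdm.generate_pseudo_absences(dm, presence, 30, rng)
        assert len(cells) == 30
        forbidden = {(r + dr, c + dc) for r, c in presence
                     for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
        assert not ({tuple(c) for c in cells} & forbidden)
        again = sdm.generate_pseudo_absences(dm, presence, 30,
                                             np.random.default_rng(5))
        np.testing.assert_array_equal(cells, again)

    def test_insufficient_cells(self):
        dm = np.zeros((4, 4), bool)
        dm[0, :] = True
        with pytest.raises(ValueError, match="eligible"):
            sdm.generate_pseudo_absences(dm, np.array([[0, 0]]), 10,
                                         np.random.default_rng(0))

    def test_balanced_table(self):
        layers = _layers()
        dm = np.ones((8, 8), bool)
        presence = np.array([[1, 1], [2, 5], [6, 6]])
        absences = sdm.generate_pseudo_absences(dm, presence, 3,
                                                np.random.default_rng(1))
        table = sdm.build_training_table(layers, ["min_phi", "depth"],
                                         presence, absences)
        assert table["label"].sum() == 3 and len(table) == 6
        assert table["cell_lin"].is_unique


class TestFeatureContributions:
    def test_single_split_tree_hand_computed(self):
        # one split on feature 0: contribution of feature 0 must be the leaf
        # presence probability minus the root probability; feature 1 untouched
        X = np.array([[0.0, 9.0], [1.0, 9.0], [2.0, 9.0], [3.0, 9.0]])
        y = np.array([0, 0, 1, 1])
        stump = RandomForestClassifier(n_estimators=1, max_depth=1,
                                       bootstrap=False, random_state=0)
        stump.fit(X, y)
        contrib, bias = sdm.feature_contributions(stump, X)
        assert bias == pytest.approx(0.5)
        np.testing.assert_allclose(contrib[:, 1], 0.0)
        np.testing.assert_allclose(contrib[:, 0], [-0.5, -0.5, 0.5, 0.5])

    def test_additivity_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=120) > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=0)
        forest.fit(X, y)
        contrib, bias = sdm.feature_contributions(forest, X)
        pred = forest.predict_proba(X)[:, list(forest.classes_).index(1)]
        np.testing.assert_allclose(bias + contrib.sum(axis=1), pred, atol=1e-10)

    def test_degenerate_tree_contributes_nothing(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 1, 1, 1])
        stump = RandomForestClassifier(n_estimators=3, random_state=0)
        stump.fit(X, y)
        contrib, bias = sdm.feature_contributions(stump, X)
        np.testing.assert_allclose(contrib, 0.0)
        np.testing.assert_allclose(bias, 1.0)

    def test_rejects_non_forest(self):
        with pytest.raises(TypeError):
            sdm.feature_contributions(DecisionTreeClassifier(), np.zeros((2, 2)))


class TestLogisticThreshold:
    def test_deterministic_step_uses_separation_midpoint(self):
        x = np.r_[np.linspace(1.0, 2.98, 40), np.linspace(3.02, 5.0, 40)]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        est = sdm._logistic_threshold(x, y)
        assert est.method == "separation_midpoint"
        assert est.threshold == pytest.approx(3.0, abs=0.02)

    def test_noisy_symmetric_data_recovers_center(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.0, 6.0, 600)
        y = (rng.random(600) < 1 / (1 + np.exp(-4.0 * (x - 3.0)))).astype(int)
        est = sdm._logistic_threshold(x, y)
        assert est.method == "logistic"
        assert est.ci[0] < 3.0 < est.ci[1]
        # brute-force likelihood grid as an independent oracle
        b0g = np.linspace(-20, 0, 120)
        b1g = np.linspace(0.5, 8, 120)
        ll = np.full((120, 120), -np.inf)
        for i, b0 in enumerate(b0g):
            p = 1 / (1 + np.exp(-(b0 + np.outer(b1g, x))))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll[:, i] = (y * np.log(p) + (1 - y) * np.log1p(-p)).sum(axis=1)
        j, i = np.unravel_index(np.argmax(ll), ll.shape)
        assert est.threshold == pytest.approx(-b0g[i] / b1g[j], abs=0.1)


class TestDepthThresholds:
    def _window(self, values, contribs, **kw):
        import unittest.mock as mock
        pooled = pd.DataFrame({"model": 0, "value": values,
                               "contribution": contribs,
                               "label": np.ones(len(values), int)})
        with mock.patch.object(sdm, "pooled_training_contributions",
                               return_value=pooled):
            return sdm.estimate_depth_thresholds(
                sdm.RFEnsemble(predictors=["depth"]), **kw)

    def test_planted_window_zero_crossings(self):
        d = np.linspace(0, 100, 2000)
        c = np.where((d > 13) & (d < 75), 0.1, -0.1)
        win = self._window(d, c)
        assert win.lower == pytest.approx(13.0, abs=2.0)
        assert win.upper == pytest.approx(75.0, abs=2.0)

    def test_all_positive_is_open_window(self):
        d = np.linspace(0, 100, 500)
        with pytest.warns(UserWarning, match="open"):
            win = self._window(d, np.full(500, 0.2))
        assert win.lower is None and win.upper is None

    def test_single_sign_change_one_sided(self):
        d = np.linspace(0, 100, 1000)
        win = self._window(d, np.where(d > 40, 0.1, -0.1))
        assert win.lower == pytest.approx(40.0, abs=2.0)
        assert win.upper is None

    def test_no_positive_region_errors(self):
        d = np.linspace(0, 100, 300)
        with pytest.raises(ValueError, match="positive"):
            self._window(d, np.full(300, -0.1))


class TestEnsembleComparison:
    def test_identical_vectors_t_zero(self):
        a = sdm.RFEnsemble(predictors=["x"])
        b = sdm.RFEnsemble(predictors=["x"])
        for v in (0.9, 0.8, 0.85, 0.95):
            a.models.append(sdm.FittedModel(None, None, v, {}, 0))
            b.models.append(sdm.FittedModel(None, None, v, {}, 0))
        rep = sdm.compare_full_vs_reduced(a, b)
        assert rep.t_statistic == pytest.approx(0.0)
        assert rep.reduced_recommended

    def test_separated_accuracies_significant(self):
        rng = np.random.default_rng(0)
        a = sdm.RFEnsemble(predictors=["x"])
        b = sdm.RFEnsemble(predictors=["x"])
        for _ in range(10):
            a.models.append(sdm.FittedModel(None, None,
                                            0.9 + rng.normal(0, 0.01), {}, 0))
            b.models.append(sdm.FittedModel(None, None,
                                            0.6 + rng.normal(0, 0.01), {}, 0))
        rep = sdm.compare_full_vs_reduced(a, b)
        assert rep.p_value < 0.01
        assert rep.mean_accuracy_full == pytest.approx(0.9, abs=0.02)
        assert rep.mean_accuracy_reduced == pytest.approx(0.6, abs=0.02)


class TestPredictorSetComparison:
    def test_identical_groups_f_zero(self):
        v = [0.8, 0.82, 0.84, 0.86]
        rep = sdm.compare_predictor_sets({"a": v, "b": v, "c": v, "d": v})
        assert rep.f_statistic == pytest.approx(0.0)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        groups = {n: rng.normal(m, 0.03, 10)
                  for n, m in [("phi", 0.93), ("fas", 0.90), ("aas", 0.82),
                               ("temp", 0.91)]}
        rep = sdm.compare_predictor_sets(groups)
        # brute-force one-way ANOVA
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f = (ssb / 3) / (ssw / 36)
        assert rep.f_statistic == pytest.approx(f, rel=1e-10)
        assert rep.df_between == 3 and rep.df_within == 36

    def test_tukey_adjusted_not_below_pairwise(self):
        # Tukey adjusts the pooled-variance pairwise comparison, so its
        # adjusted p can never undercut the unadjusted p computed from the
        # same ANOVA residual variance
        rng = np.random.default_rng(9)
        groups = {n: rng.normal(m, 0.05, 10)
                  for n, m in [("a", 0.9), ("b", 0.88), ("c", 0.8)]}
        rep = sdm.compare_predictor_sets(groups)
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        df = rep.df_within
        for _, row in rep.tukey.iterrows():
            g1, g2 = groups[row["group1"]], groups[row["group2"]]
            t = abs(g1.mean() - g2.mean()) / np.sqrt(mse * 2 / 10)
            raw = 2 * stats.t.sf(t, df)
            assert float(row["p-adj"]) >= raw - 1e-6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sdm.compare_predictor_sets({"a": [0.9, 0.8], "b": [0.7]})


class TestTrainAndProject:
    @pytest.fixture(scope="class")
    def threshold_world(self):
        # planted rule: suitable iff min_phi >= 3 and 20 <= depth <= 70
        rng = np.random.default_rng(12)
        nlat = nlon = 25
        coords = {"lat": np.arange(nlat, dtype=float),
                  "lon": np.arange(nlon, dtype=float)}
        layers = xr.Dataset({
            "min_phi": xr.DataArray(rng.uniform(1.0, 5.0, (nlat, nlon)),
                                    coords=coords, dims=("lat", "lon")),
            "depth": xr.DataArray(rng.uniform(0.0, 100.0, (nlat, nlon)),
                                  coords=coords, dims=("lat", "lon"))})
        suitable = ((layers["min_phi"] >= 3.0) & (layers["depth"] >= 20.0)
                    & (layers["depth"] <= 70.0)).values
        cells = np.column_stack(np.nonzero(suitable))
        presence = cells[rng.choice(len(cells), 60, replace=False)]
        dm = np.ones((nlat, nlon), bool)
        ens = sdm.train_rf_ensemble(layers, presence, ["min_phi", "depth"],
                                    dm, k=5, seed=21, n_estimators=200)
        return layers, presence, dm, ens

    def test_separable_labels_high_accuracy(self, threshold_world):
        *_, ens = threshold_world
        assert ens.accuracies.mean() >= 0.8
        assert np.all((ens.accuracies >= 0) & (ens.accuracies <= 1))

    def test_randomized_labels_chance_accuracy(self):
        layers = _layers(30, 30, seed=4)
        rng = np.random.default_rng(0)
        cells = np.column_stack(np.nonzero(np.ones((30, 30), bool)))
        accs = []
        for s in range(6):
            presence = cells[rng.choice(len(cells), 40, replace=False)]
            with pytest.warns(UserWarning):
                ens = sdm.train_rf_ensemble(layers, presence,
                                            ["min_phi", "depth"],
                                            np.ones((30, 30), bool), k=2,
                                            seed=s, n_estimators=100)
            accs.extend(ens.accuracies)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_agreement_map_properties(self, threshold_world):
        layers, presence, dm, ens = threshold_world
        agreement = sdm.project_distribution(ens, layers, dm)
        vals = agreement.values[np.isfinite(agreement.values)]
        step = 100.0 / ens.k
        assert np.allclose(np.mod(vals, step), 0.0)
        # strongly suitable presence cells project near-unanimously
        strong = (layers["min_phi"].values >= 4.0) \
            & (layers["depth"].values >= 35.0) & (layers["depth"].values <= 55.0)
        assert np.nanmean(agreement.values[strong]) > 80.0
        deep = layers["depth"].values > 85.0
        assert np.nanmean(agreement.values[deep]) < 30.0

    def test_agreement_invariant_to_model_order(self, threshold_world):
        layers, _, dm, ens = threshold_world
        shuffled = sdm.RFEnsemble(predictors=ens.predictors,
                                  models=list(reversed(ens.models)))
        a = sdm.project_distribution(ens, layers, dm)
        b = sdm.project_distribution(shuffled, layers, dm)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_predictor_layer(self, threshold_world):
        layers, _, dm, ens = threshold_world
        with pytest.raises(ValueError, match="missing"):
            sdm.project_distribution(ens, layers[["depth"]], dm)

    def test_importance_ranks_planted_driver(self, threshold_world):
        *_, ens = threshold_world
        table = ens.importance_table()
        # both predictors genuinely drive the planted rule; each model must
        # assign positive importance to min_phi
        assert (table["min_phi"] > 0).all()
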