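"""Ensemble suitability modeling: pruning, background, gating, products."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Point

from wildrice.raster import RasterGrid
from wildrice.sdm_ensemble import (
    CHANGE_CATEGORIES,
    OVERLAP_CATEGORIES,
    CalibrationSet,
    change_map,
    evaluate_ensemble,
    extract_env,
    fit_bioclim,
    fit_ensemble,
    fit_logistic,
    future_consensus,
    geographic_null,
    lgm_consensus,
    make_background,
    overlap_map,
    predict_ensemble,
    threshold_suitability,
    vif_prune,
)
from wildrice.synthetic_data import (
    SuitabilityTruth,
    sample_occurrences,
    simulate_climate_rasters,
)


def grid_of(values, cellsize=1.0, xll=0.0, yll=0.0, name="g"):
    return RasterGrid(values=np.asarray(values, float), xll=xll, yll=yll,
                      cellsize=cellsize, name=name)


@pytest.fixture(scope="module")
def rasters():
    return simulate_climate_rasters(
        extent=(0, 5, 0, 5), resolution=0.05, n_layers=4, seed=21
    )


@pytest.fixture(scope="module")
def truth():
    # niche optimum at env4 = 0.5: eta = 4 - 60 (env4 - 0.5)^2
    return SuitabilityTruth(
        intercept=4.0 - 60.0 * 0.25,
        coefficients={"env4": 60.0},
        quadratic={"env4": -60.0},
    )


@pytest.fixture(scope="module")
def calibration(rasters, truth):
    occ = sample_occurrences(truth, rasters, 150, seed=22)
    return make_background(occ, rasters, max_n=2000, seed=23), occ


class TestVifPrune:
    def test_orthogonal_variables_all_retained(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        assert vif_prune(df) == ["a", "b", "c"]

    def test_duplicate_column_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x.copy(),
                           "c": rng.standard_normal(100)})
        with pytest.warns(UserWarning, match="collinearity"):
            kept = vif_prune(df)
        assert kept == ["b", "c"]  # first of the pair dropped

    def test_linear_combination_matches_stepwise_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(300)
        b = rng.standard_normal(300)
        df = pd.DataFrame(
            {"a": a, "b": b, "c": a + b + 0.05 * rng.standard_normal(300)}
        )
        kept = vif_prune(df, threshold=5)

        def oracle_vif(frame, col):
            import statsmodels.api as sm
            others = [c for c in frame.columns if c != col]
            fit = sm.OLS(frame[col],
                         sm.add_constant(frame[others])).fit()
            return 1.0 / (1.0 - fit.rsquared)

        # stepwise oracle via statsmodels regressions
        cols = list(df.columns)
        while True:
            vifs = {c: oracle_vif(df[cols], c) for c in cols}
            worst = max(cols, key=lambda c: vifs[c])
            if vifs[worst] < 5:
                break
            cols.remove(worst)
        assert kept == cols

    def test_needs_enough_rows(self):
        df = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="rows"):
            vif_prune(df)


class TestBackground:
    def test_background_confined_to_buffered_hull(self, rasters):
        occ = pd.DataFrame(
            {"species": "t", "lon": [0.55, 4.45, 0.55], "lat": [0.55, 0.55, 4.45]}
        )
        cal = make_background(occ, rasters, max_n=400, seed=1)
        hull = MultiPoint(
            [(0.55, 0.55), (4.45, 0.55), (0.55, 4.45)]
        ).convex_hull
        # generous independent bound: hull buffered by its longest side
        wide = hull.buffer(0.7)
        bg = cal.y == 0
        for x, y in zip(cal.lon[bg], cal.lat[bg]):
            assert wide.contains(Point(x, y))
        # and some background lies outside the raw (unbuffered) hull edge
        assert cal.n_background > 0

    def test_all_eligible_cells_when_max_n_large(self, rasters, truth):
        occ = sample_occurrences(truth, rasters, 30, seed=2)
        a = make_background(occ, rasters, max_n=10 ** 6, seed=3)
        b = make_background(occ, rasters, max_n=10 ** 6, seed=4)
        assert a.n_background == b.n_background  # exhaustive, seed-free

    def test_seeded_background_reproducible(self, rasters, truth):
        occ = sample_occurrences(truth, rasters, 30, seed=5)
        a = make_background(occ, rasters, max_n=200, seed=6)
        b = make_background(occ, rasters, max_n=200, seed=6)
        assert np.array_equal(a.lon, b.lon)

    def test_presence_cells_never_background(self, rasters, truth):
        occ = sample_occurrences(truth, rasters, 50, seed=7)
        cal = make_background(occ, rasters, max_n=10 ** 6, seed=8)
        pres = {(x, y) for x, y in zip(cal.lon[cal.y == 1], cal.lat[cal.y == 1])}
        bg = {(x, y) for x, y in zip(cal.lon[cal.y == 0], cal.lat[cal.y == 0])}
        assert not pres & bg

    def test_ecoregion_mode_restricts_categories(self, rasters, truth):
        occ = sample_occurrences(truth, rasters, 40, seed=9)
        eco_vals = np.zeros_like(rasters[0].values)
        eco_vals[:, : rasters[0].ncols // 2] = 1.0  # category 1 west, 0 east
        eco = rasters[0].with_values(eco_vals, name="eco")
        cal = make_background(
            occ, rasters, mode="hull+ecoregion", ecoregions=eco,
            max_n=10 ** 6, seed=10,
        )
        pres_cats = {
            eco.values[eco.cell_index(x, y)]
            for x, y in zip(cal.lon[cal.y == 1], cal.lat[cal.y == 1])
        }
        bg_cats = {
            eco.values[eco.cell_index(x, y)]
            for x, y in zip(cal.lon[cal.y == 0], cal.lat[cal.y == 0])
        }
        assert bg_cats <= pres_cats


class TestBioclim:
    def _cal(self, values):
        X = pd.DataFrame({"v": values})
        y = np.ones(len(values), dtype=int)
        return CalibrationSet(X=X, y=y, lon=np.zeros(len(values)),
                              lat=np.zeros(len(values)))

    def test_median_scores_one(self):
        m = fit_bioclim(self._cal([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert m.predict(pd.DataFrame({"v": [3.0]}))[0] == pytest.approx(1.0)

    def test_outside_range_scores_zero(self):
        m = fit_bioclim(self._cal([1.0, 2.0, 3.0]))
        assert m.predict(pd.DataFrame({"v": [99.0]}))[0] == 0.0

    def test_hand_cdf_evaluation(self):
        # presences 1..5; x=2 has midrank F=0.3 -> score 1-2|0.3-0.5|=0.6
        m = fit_bioclim(self._cal([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert m.predict(pd.DataFrame({"v": [2.0]}))[0] == pytest.approx(0.6)

    def test_needs_two_presences(self):
        from wildrice.sdm_ensemble import ModelFitError
        with pytest.raises(ModelFitError):
            fit_bioclim(self._cal([1.0]))


class TestLogistic:
    def test_recovers_niche_curvature_sign(self, calibration):
        # the truth peaks at intermediate env4, so the fitted quadratic
        # term on env4 must be negative
        cal, _ = calibration
        m = fit_logistic(cal)
        assert m.coefficients["env4^2"] < 0

    def test_predictions_bounded(self, calibration):
        cal, _ = calibration
        m = fit_logistic(cal)
        p = m.predict(cal.X)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_needs_both_classes(self):
        from wildrice.sdm_ensemble import ModelFitError
        X = pd.DataFrame({"v": [1.0, 2.0]})
        cal = CalibrationSet(X=X, y=np.ones(2, dtype=int),
                             lon=np.zeros(2), lat=np.zeros(2))
        with pytest.raises(ModelFitError):
            fit_logistic(cal)


class TestGeographicNull:
    def test_scores_one_at_presence_zero_at_farthest(self):
        X = pd.DataFrame({"v": np.zeros(3)})
        cal = CalibrationSet(
            X=pd.DataFrame({"v": [0.0]}), y=np.array([1]),
            lon=np.array([0.0]), lat=np.array([0.0]),
        )
        null = geographic_null(cal)
        scores = null.predict(X, np.array([0.0, 1.0, 2.0]), np.zeros(3))
        assert scores[0] == pytest.approx(1.0)
        assert scores[2] == pytest.approx(0.0)
        assert scores[1] == pytest.approx(0.5, abs=0.01)


class TestEnsembleGating:
    def test_null_like_model_not_retained(self, calibration):
        cal, _ = calibration
        models = {"decoy_null": geographic_null, "logistic": fit_logistic}
        ev = evaluate_ensemble(models, cal, seed=31)
        assert not ev.retained["decoy_null"]
        assert ev.retained["logistic"]
        assert sum(ev.weights.values()) == pytest.approx(1.0)

    def test_truth_aligned_model_retained_with_weight(self, calibration):
        cal, _ = calibration
        ev = evaluate_ensemble({"logistic": fit_logistic}, cal, seed=32)
        assert ev.weights["logistic"] == pytest.approx(1.0)
        assert ev.used_cauc

    def test_cauc_equals_auc_when_null_uninformative(self):
        # cAUC = AUC + 0.5 - max(0.5, AUC_null) reduces to AUC at null 0.5
        auc, null_auc = 0.93, 0.5
        assert auc + 0.5 - max(0.5, null_auc) == pytest.approx(auc)

    def test_all_models_failing_is_error(self, calibration):
        cal, _ = calibration
        with pytest.raises(ValueError, match="retained"):
            evaluate_ensemble({"decoy_null": geographic_null}, cal, seed=33)


class TestPrediction:
    def test_single_model_identity(self, rasters, calibration):
        cal, occ = calibration
        ens = fit_ensemble(cal, models={"logistic": fit_logistic}, seed=41)
        suit = predict_ensemble(ens, rasters)
        direct = ens.models["logistic"].predict(
            extract_env(rasters, *[
                g[np.isfinite(rasters[0].values)]
                for g in rasters[0].cell_centers()
            ])
        )
        got = suit.values[np.isfinite(rasters[0].values)]
        assert np.allclose(got, direct)

    def test_weighted_mean_hand_check(self):
        class Const:
            def __init__(self, v, cols):
                self.v, self.columns = v, cols
            def predict(self, X, lon=None, lat=None):
                return np.full(len(X), self.v)

        from wildrice.sdm_ensemble import EnsembleModel, ModelEvaluation
        ev = ModelEvaluation(
            table=pd.DataFrame(), retained={"a": True, "b": True},
            weights={"a": 0.75, "b": 0.25}, used_cauc=True, alpha=0.05,
        )
        ens = EnsembleModel(
            models={"a": Const(1.0, ["g"]), "b": Const(0.0, ["g"])},
            evaluation=ev,
        )
        out = predict_ensemble(ens, [grid_of(np.zeros((2, 2)))])
        assert np.allclose(out.values, 0.75)

    def test_missing_variable_named(self, calibration):
        cal, _ = calibration
        ens = fit_ensemble(cal, models={"logistic": fit_logistic}, seed=42)
        with pytest.raises(ValueError, match="env1"):
            predict_ensemble(ens, [grid_of(np.zeros((2, 2)), name="other")])


class TestThreshold:
    def test_toy_grid_threshold_is_presence_minimum(self):
        vals = np.arange(25, dtype=float).reshape(5, 5) / 24.0
        suit = grid_of(vals[::-1], cellsize=1.0)  # row 0 at top
        pres = pd.DataFrame({"lon": [2.5, 4.5], "lat": [2.5, 4.5]})
        binary, thr = threshold_suitability(suit, pres)
        scores = suit.sample(pres["lon"], pres["lat"])
        assert thr == pytest.approx(scores.min())
        assert (suit.sample(pres["lon"], pres["lat"]) >= thr).all()

    def test_presences_at_global_minimum_make_everything_suitable(self):
        vals = np.array([[0.1, 0.5], [0.9, 0.3]])
        suit = grid_of(vals)
        pres = pd.DataFrame({"lon": [0.5], "lat": [1.5]})  # the 0.1 cell
        binary, thr = threshold_suitability(suit, pres)
        assert np.all(binary.values == 1.0)

    def test_presence_on_nodata_excluded_with_warning(self):
        vals = np.array([[np.nan, 0.5], [0.9, 0.3]])
        suit = grid_of(vals)
        pres = pd.DataFrame({"lon": [0.5, 1.5], "lat": [1.5, 1.5]})
        with pytest.warns(UserWarning, match="nodata"):
            _, thr = threshold_suitability(suit, pres)
        assert thr == pytest.approx(0.5)


class TestScenarioProducts:
    def test_lgm_average_of_identical_maps(self):
        m = grid_of([[1.0, 0.0]])
        out = lgm_consensus(m, m)
        assert np.array_equal(out.values, m.values)

    def test_lgm_disagreement_is_half(self):
        a = grid_of([[1.0]])
        b = grid_of([[0.0]])
        assert lgm_consensus(a, b).values[0, 0] == 0.5

    def test_lgm_nodata_propagates(self):
        a = grid_of([[np.nan]])
        b = grid_of([[1.0]])
        assert math.isnan(lgm_consensus(a, b).values[0, 0])

    def test_misaligned_grids_rejected(self):
        a = grid_of([[1.0]])
        b = grid_of([[1.0]], xll=5.0)
        with pytest.raises(ValueError, match="aligned"):
            lgm_consensus(a, b)

    @pytest.mark.parametrize("n_suitable,expected", [(15, 1.0), (14, 0.0)])
    def test_future_majority_rule_on_thirty_maps(self, n_suitable, expected):
        maps = [grid_of([[1.0 if i < n_suitable else 0.0]])
                for i in range(30)]
        assert future_consensus(maps).values[0, 0] == expected

    def test_future_consensus_monotone_in_suitable_replicates(self):
        rng = np.random.default_rng(3)
        base = [grid_of(rng.integers(0, 2, (6, 6)).astype(float))
                for _ in range(9)]
        area_before = future_consensus(base).values.sum()
        more = base + [grid_of(np.ones((6, 6)))]
        area_after = future_consensus(more).values.sum()
        assert area_after >= area_before

    def test_change_map_matches_contingency_table(self):
        rng = np.random.default_rng(4)
        cur = grid_of(rng.integers(0, 2, (8, 8)).astype(float))
        fut = grid_of(rng.integers(0, 2, (8, 8)).astype(float))
        out = change_map(cur, fut).values
        ct = pd.crosstab(cur.values.ravel(), fut.values.ravel())
        assert (out == CHANGE_CATEGORIES["stable-suitable"]).sum() == ct.loc[1, 1]
        assert (out == CHANGE_CATEGORIES["loss"]).sum() == ct.loc[1, 0]
        assert (out == CHANGE_CATEGORIES["gain"]).sum() == ct.loc[0, 1]
        assert (out == CHANGE_CATEGORIES["never-suitable"]).sum() == ct.loc[0, 0]

    def test_overlap_truth_table_all_sixteen_combinations(self):
        combos = list(itertools.product([0.0, 1.0], repeat=4))
        grids = [
            grid_of(np.array([c]).reshape(1, len(combos)) if False else v)
            for c, v in []
        ]
        vals = np.array(combos, dtype=float).T.reshape(4, 1, len(combos))
        cc, cf, wc, wf = (grid_of(v) for v in vals)
        out = overlap_map(cc, cf, wc, wf).values.ravel()
        for k, (a, b, c, d) in enumerate(combos):
            crop_any, cwr_any = a or b, c or d
            if crop_any and cwr_any:
                exp = (OVERLAP_CATEGORIES["overlap-current-both"]
                       if a and c else
                       OVERLAP_CATEGORIES["overlap-future-involved"])
            elif crop_any:
                exp = OVERLAP_CATEGORIES["crop-only"]
            elif cwr_any:
                exp = OVERLAP_CATEGORIES["cwr-only"]
            else:
                exp = OVERLAP_CATEGORIES["neither"]
            assert out[k] == exp, combos[k]

    def test_crop_nowhere_no_overlap_classes(self):
        zero = grid_of(np.zeros((3, 3)))
        one = grid_of(np.ones((3, 3)))
        out = overlap_map(zero, zero, one, one).values
        assert set(np.unique(out)) == {OVERLAP_CATEGORIES["cwr-only"]}
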