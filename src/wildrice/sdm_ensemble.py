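"""Ensemble habitat-suitability modeling with null-model gating.

The workflow mirrors standard presence/background distribution modeling:
collinear environmental layers are pruned by iterated variance-inflation
factors; background points are drawn from a buffered convex hull around
the presences (optionally intersected with ecoregions holding at least one
presence); candidate algorithms are evaluated by repeated split testing
against a geographic null model using calibrated AUC
(cAUC = AUC + 0.5 - max(0.5, AUC_null), which discounts the part of the
AUC attainable from spatial sorting alone); only algorithms whose cAUCs
beat the null's by a one-sided Mann-Whitney test are retained, weighted by
mean cAUC; projections are truncated at the minimum suitability observed
at any presence cell; and multi-scenario products (two-model palaeoclimate
average, majority consensus of future projections, change and crop/CWR
overlap maps) are simple cellwise rules on the thresholded maps.

Two suitability algorithms are built in — a percentile-envelope score
(BIOCLIM-style) and a logistic presence/background regression with linear
and quadratic terms — and arbitrary learners can join the ensemble through
the same factory contract.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point
from shapely.prepared import prep
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from scipy.stats import mannwhitneyu

from .genetic_structure import haversine_km
from .raster import RasterGrid, require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationSet",
    "ModelEvaluation",
    "EnsembleModel",
    "vif_prune",
    "extract_env",
    "make_background",
    "fit_bioclim",
    "fit_logistic",
    "geographic_null",
    "evaluate_ensemble",
    "fit_ensemble",
    "predict_ensemble",
    "threshold_suitability",
    "lgm_consensus",
    "future_consensus",
    "change_map",
    "overlap_map",
    "CHANGE_CATEGORIES",
    "OVERLAP_CATEGORIES",
]

MAX_BACKGROUND = 10_000

CHANGE_CATEGORIES = {
    "never-suitable": 0, "loss": 1, "gain": 2, "stable-suitable": 3,
}
OVERLAP_CATEGORIES = {
    "neither": 0, "crop-only": 1, "cwr-only": 2,
    "overlap-current-both": 3, "overlap-future-involved": 4,
}


# -- collinearity pruning ---------------------------------------------

def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from regressing it on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("inf")
    r2 = 1.0 - ss_res / ss_tot
    return float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_prune(env_table: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the variable with the largest VIF until all are
    below ``threshold``; ties and perfect collinearity drop the first
    variable in column order (with a warning for exact collinearity)."""
    cols = list(env_table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    if len(env_table) < len(cols) + 2:
        raise ValueError("need at least n_variables + 2 rows")
    while len(cols) > 1:
        X = env_table[cols].to_numpy(dtype=float)
        vifs = np.array([_vif(X, j) for j in range(len(cols))])
        worst = int(np.argmax(vifs))  # argmax takes the first on ties
        if vifs[worst] < threshold:
            break
        if np.isinf(vifs[worst]):
            warnings.warn(
                f"perfect collinearity; dropping {cols[worst]!r}"
            )
        logger.info("vif_prune: dropping %s (VIF=%.2f)", cols[worst], vifs[worst])
        cols.pop(worst)
    return cols


# -- calibration data -------------------------------------------------

@dataclass
class CalibrationSet:
    """Presence and background rows with extracted environmental values."""

    X: pd.DataFrame  # environmental values, presence rows first
    y: np.ndarray  # 1 presence, 0 background
    lon: np.ndarray
    lat: np.ndarray

    @property
    def n_presence(self) -> int:
        return int(self.y.sum())

    @property
    def n_background(self) -> int:
        return int((1 - self.y).sum())


def extract_env(rasters: list[RasterGrid], lon, lat) -> pd.DataFrame:
    """Sample every raster at point locations into a variables DataFrame."""
    return pd.DataFrame({r.name: r.sample(lon, lat) for r in rasters})


def _thin_to_cells(grid: RasterGrid, lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Keep at most one point per grid cell, returning cell-center coords."""
    seen = {}
    for x, y in zip(lon, lat):
        try:
            rc = grid.cell_index(x, y)
        except ValueError:
            continue
        seen.setdefault(rc, (x, y))
    if len(seen) < len(lon):
        logger.info(
            "presence thinning: %d points -> %d cells", len(lon), len(seen)
        )
    clon, clat = grid.cell_centers()
    xs = np.array([clon[r, c] for r, c in seen])
    ys = np.array([clat[r, c] for r, c in seen])
    return xs, ys


def make_background(
    presences: pd.DataFrame,
    rasters: list[RasterGrid],
    mode: str = "hull",
    ecoregions: RasterGrid | None = None,
    max_n: int = MAX_BACKGROUND,
    buffer_frac: float = 0.10,
    seed: int = 0,
) -> CalibrationSet:
    """Build a presence/background calibration set.

    Background cells are drawn at random (one per cell, at most ``max_n``)
    from the convex hull of the presences extended by a buffer of
    ``buffer_frac`` times the hull's largest axis (the maximum
    vertex-to-vertex great-circle distance, converted to degrees at the
    hull centroid latitude). ``mode="hull+ecoregion"`` additionally
    restricts background to ecoregion categories containing at least one
    presence cell. Presence cells are never used as background.
    """
    require_aligned(*rasters)
    grid = rasters[0]
    lon = presences["lon"].to_numpy(dtype=float)
    lat = presences["lat"].to_numpy(dtype=float)
    plon, plat = _thin_to_cells(grid, lon, lat)
    if len(plon) == 0:
        raise ValueError("no presence falls inside the raster extent")

    pts = MultiPoint(list(zip(plon, plat)))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        logger.info("presences are (nearly) collinear; using bounding box hull")
        hull = pts.envelope
        if hull.geom_type != "Polygon":  # still degenerate: buffer the line/point
            hull = pts.buffer(grid.cellsize)
    verts = np.asarray(hull.exterior.coords)
    vx, vy = verts[:, 0], verts[:, 1]
    axis_km = float(
        haversine_km(vx[:, None], vy[:, None], vx[None, :], vy[None, :]).max()
    )
    lat_c = float(hull.centroid.y)
    km_per_deg = 111.32 * max(math.cos(math.radians(lat_c)), 0.1)
    buffered = hull.buffer(buffer_frac * axis_km / km_per_deg)
    region = prep(buffered)

    clon, clat = grid.cell_centers()
    flat_lon, flat_lat = clon.ravel(), clat.ravel()
    has_data = np.ones(flat_lon.shape, dtype=bool)
    for r in rasters:
        has_data &= np.isfinite(r.values.ravel())
    inside = np.array(
        [has_data[i] and region.contains(Point(flat_lon[i], flat_lat[i]))
         for i in range(flat_lon.size)]
    )
    pres_cells = {grid.cell_index(x, y) for x, y in zip(plon, plat)}
    pres_flat = {r * grid.ncols + c for r, c in pres_cells}
    inside[list(pres_flat)] = False

    if mode == "hull+ecoregion":
        if ecoregions is None:
            raise ValueError("hull+ecoregion mode needs an ecoregion raster")
        eco = ecoregions.values.ravel()
        pres_cats = {
            ecoregions.values[rc] for rc in pres_cells
            if np.isfinite(ecoregions.values[rc])
        }
        inside &= np.isin(eco, list(pres_cats))
    elif mode != "hull":
        raise ValueError(f"unknown background mode {mode!r}")

    eligible = np.flatnonzero(inside)
    if eligible.size == 0:
        raise ValueError("no eligible background cells inside the buffered hull")
    rng = np.random.default_rng(seed)
    if eligible.size > max_n:
        eligible = rng.choice(eligible, size=max_n, replace=False)
    blon, blat = flat_lon[eligible], flat_lat[eligible]

    all_lon = np.concatenate([plon, blon])
    all_lat = np.concatenate([plat, blat])
    X = extract_env(rasters, all_lon, all_lat)
    y = np.concatenate([np.ones(len(plon)), np.zeros(len(blon))]).astype(int)
    return CalibrationSet(X=X, y=y, lon=all_lon, lat=all_lat)


# -- component models -------------------------------------------------

class ModelFitError(RuntimeError):
    pass


class _BioclimModel:
    """Percentile-envelope score: per variable, 1 - 2|F(x) - 0.5| with F the
    presence empirical CDF (midrank convention); cell score is the minimum
    over variables. Values outside the presence range score 0."""

    def __init__(self, presence_X: pd.DataFrame):
        if len(presence_X) < 2:
            raise ModelFitError("BIOCLIM needs at least two presences")
        self.columns = list(presence_X.columns)
        self.sorted_vals = {
            c: np.sort(presence_X[c].to_numpy(dtype=float)) for c in self.columns
        }

    def predict(self, X: pd.DataFrame, lon=None, lat=None) -> np.ndarray:
        score = np.ones(len(X))
        for c in self.columns:
            v = self.sorted_vals[c]
            x = X[c].to_numpy(dtype=float)
            if v[0] == v[-1]:
                s = np.where(x == v[0], 1.0, 0.0)
            else:
                lo = np.searchsorted(v, x, side="left")
                hi = np.searchsorted(v, x, side="right")
                F = (lo + hi) / (2.0 * len(v))
                s = 1.0 - 2.0 * np.abs(F - 0.5)
                s = np.where((x < v[0]) | (x > v[-1]), 0.0, s)
            score = np.minimum(score, s)
        return score


def fit_bioclim(calibration: CalibrationSet) -> _BioclimModel:
    return _BioclimModel(calibration.X[calibration.y == 1])


class _LogisticModel:
    """Presence-vs-background logistic regression on standardized linear +
    quadratic terms."""

    def __init__(self, X: pd.DataFrame, y: np.ndarray):
        import statsmodels.api as sm

        self.columns = list(X.columns)
        Z = X.to_numpy(dtype=float)
        self.mean = Z.mean(axis=0)
        self.std = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        design = self._design(Z)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(y, design, family=sm.families.Binomial())
                self.result = model.fit(maxiter=100)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            raise ModelFitError(f"logistic model failed: {exc}") from exc
        if not np.all(np.isfinite(self.result.params)):
            raise ModelFitError("logistic model did not converge")

    def _design(self, Z: np.ndarray) -> np.ndarray:
        Zs = (Z - self.mean) / self.std
        return np.column_stack([np.ones(len(Zs)), Zs, Zs ** 2])

    @property
    def coefficients(self) -> dict[str, float]:
        p = np.asarray(self.result.params)
        out = {"intercept": float(p[0])}
        for i, c in enumerate(self.columns):
            out[c] = float(p[1 + i])
            out[f"{c}^2"] = float(p[1 + len(self.columns) + i])
        return out

    def predict(self, X: pd.DataFrame, lon=None, lat=None) -> np.ndarray:
        Z = X[self.columns].to_numpy(dtype=float)
        return np.clip(self.result.predict(self._design(Z)), 0.0, 1.0)


def fit_logistic(calibration: CalibrationSet) -> _LogisticModel:
    if len(set(calibration.y)) < 2:
        raise ModelFitError("both presence and background rows are required")
    return _LogisticModel(calibration.X, calibration.y)


class _GeographicNull:
    """Suitability decays linearly with great-circle distance to the
    nearest calibration presence: score = 1 - d/d_max over the points being
    scored (1 at a presence, 0 at the farthest evaluated location)."""

    def __init__(self, plon: np.ndarray, plat: np.ndarray):
        if len(plon) == 0:
            raise ModelFitError("geographic null needs at least one presence")
        self.plon = np.asarray(plon, dtype=float)
        self.plat = np.asarray(plat, dtype=float)

    def predict(self, X, lon=None, lat=None) -> np.ndarray:
        if lon is None or lat is None:
            raise ValueError("geographic null needs point coordinates")
        d = haversine_km(
            np.asarray(lon)[:, None], np.asarray(lat)[:, None],
            self.plon[None, :], self.plat[None, :],
        ).min(axis=1)
        dmax = d.max()
        return 1.0 - d / dmax if dmax > 0 else np.ones_like(d)


def geographic_null(calibration: CalibrationSet) -> _GeographicNull:
    pres = calibration.y == 1
    return _GeographicNull(calibration.lon[pres], calibration.lat[pres])


# default ensemble: factory contract CalibrationSet -> fitted model with
# .predict(X, lon, lat) -> scores in [0, 1]
DEFAULT_MODELS: dict[str, Callable[[CalibrationSet], object]] = {
    "bioclim": fit_bioclim,
    "logistic": fit_logistic,
}


# -- evaluation and gating --------------------------------------------

@dataclass
class ModelEvaluation:
    """Per-algorithm evaluation across split iterations."""

    table: pd.DataFrame  # columns: model, iteration, auc, null_auc, cauc
    retained: dict[str, bool]
    weights: dict[str, float]  # retained models only, sum to 1
    used_cauc: bool
    alpha: float


@dataclass
class EnsembleModel:
    models: dict[str, object]  # fitted retained models
    evaluation: ModelEvaluation
    threshold: float | None = None

    @property
    def weights(self) -> dict[str, float]:
        return self.evaluation.weights


def _subset(cal: CalibrationSet, idx: np.ndarray) -> CalibrationSet:
    return CalibrationSet(
        X=cal.X.iloc[idx].reset_index(drop=True),
        y=cal.y[idx],
        lon=cal.lon[idx],
        lat=cal.lat[idx],
    )


def evaluate_ensemble(
    models: dict[str, Callable[[CalibrationSet], object]],
    calibration: CalibrationSet,
    k_folds: int = 5,
    n_iterations: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> ModelEvaluation:
    """Repeated stratified split evaluation gated by the geographic null.

    Each of ``n_iterations`` iterations holds out 1/k_folds of the data,
    refits every candidate and the null on the training part, and computes
    the test AUC, the null's AUC on the same test points, and
    cAUC = AUC + 0.5 - max(0.5, AUC_null). A candidate is retained when
    its cAUCs exceed the null's own cAUCs by a one-sided Mann-Whitney test
    at ``alpha``; retained weights are mean cAUCs normalised to 1. When
    fewer than 10 test presences are available the plain AUC is used
    instead and every candidate with mean AUC >= the null's is retained.
    """
    splitter = StratifiedShuffleSplit(
        n_splits=n_iterations, test_size=1.0 / k_folds, random_state=seed
    )
    records = []
    failed: set[str] = set()
    min_test_presences = np.inf
    for it, (train_idx, test_idx) in enumerate(
        splitter.split(calibration.X, calibration.y)
    ):
        train = _subset(calibration, train_idx)
        test = _subset(calibration, test_idx)
        min_test_presences = min(min_test_presences, test.y.sum())
        null = geographic_null(train)
        null_scores = null.predict(test.X, test.lon, test.lat)
        null_auc = roc_auc_score(test.y, null_scores)
        null_cauc = null_auc + 0.5 - max(0.5, null_auc)
        records.append(
            {"model": "__null__", "iteration": it, "auc": null_auc,
             "null_auc": null_auc, "cauc": null_cauc}
        )
        for name, factory in models.items():
            if name in failed:
                continue
            try:
                fitted = factory(train)
                scores = fitted.predict(test.X, test.lon, test.lat)
                auc = roc_auc_score(test.y, scores)
            except ModelFitError as exc:
                logger.warning("model %s failed and is excluded: %s", name, exc)
                failed.add(name)
                continue
            cauc = auc + 0.5 - max(0.5, null_auc)
            records.append(
                {"model": name, "iteration": it, "auc": auc,
                 "null_auc": null_auc, "cauc": cauc}
            )
    table = pd.DataFrame(records)
    use_cauc = min_test_presences >= 10
    null_rows = table[table["model"] == "__null__"]
    retained: dict[str, bool] = {}
    raw_weights: dict[str, float] = {}
    for name in models:
        rows = table[table["model"] == name]
        if name in failed or len(rows) < n_iterations:
            retained[name] = False
            continue
        if use_cauc:
            stat = mannwhitneyu(
                rows["cauc"], null_rows["cauc"], alternative="greater"
            )
            keep = bool(stat.pvalue < alpha)
            weight = float(rows["cauc"].mean())
        else:
            keep = bool(rows["auc"].mean() >= null_rows["auc"].mean())
            weight = float(rows["auc"].mean())
        retained[name] = keep
        if keep:
            raw_weights[name] = max(weight, 0.0)
    total = sum(raw_weights.values())
    if total <= 0 or not raw_weights:
        raise ValueError(
            "no model was retained against the geographic null; consider the "
            "plain-AUC fallback (fewer presences) or different algorithms"
        )
    weights = {k: v / total for k, v in raw_weights.items()}
    logger.info("retained models and weights: %s", weights)
    return ModelEvaluation(
        table=table, retained=retained, weights=weights,
        used_cauc=bool(use_cauc), alpha=alpha,
    )


def fit_ensemble(
    calibration: CalibrationSet,
    models: dict[str, Callable[[CalibrationSet], object]] | None = None,
    k_folds: int = 5,
    n_iterations: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnsembleModel:
    """Evaluate, gate and refit the retained models on all calibration data."""
    models = dict(models or DEFAULT_MODELS)
    evaluation = evaluate_ensemble(
        models, calibration, k_folds=k_folds, n_iterations=n_iterations,
        alpha=alpha, seed=seed,
    )
    fitted = {
        name: models[name](calibration) for name in evaluation.weights
    }
    return EnsembleModel(models=fitted, evaluation=evaluation)


# -- projection -------------------------------------------------------

def predict_ensemble(ensemble: EnsembleModel, rasters: list[RasterGrid]) -> RasterGrid:
    """cAUC-weighted average of component predictions over a raster stack."""
    require_aligned(*rasters)
    grid = rasters[0]
    names = {r.name for r in rasters}
    needed = set()
    for m in ensemble.models.values():
        needed |= set(getattr(m, "columns", []))
    missing = needed - names
    if missing:
        raise ValueError(f"missing raster variables: {sorted(missing)}")
    lon, lat = grid.cell_centers()
    valid = np.ones(grid.values.shape, dtype=bool)
    for r in rasters:
        valid &= np.isfinite(r.values)
    X = pd.DataFrame(
        {r.name: r.values[valid] for r in rasters}
    )
    out = np.full(grid.values.shape, np.nan)
    acc = np.zeros(int(valid.sum()))
    for name, model in ensemble.models.items():
        w = ensemble.weights[name]
        acc += w * model.predict(X, lon[valid], lat[valid])
    out[valid] = acc
    return grid.with_values(out, name="suitability")


def threshold_suitability(
    suit: RasterGrid, presences: pd.DataFrame
) -> tuple[RasterGrid, float]:
    """Binary map at the minimum suitability over presence cells.

    Every usable presence cell is suitable by construction; presences on
    nodata cells are excluded with a warning.
    """
    scores = suit.sample(
        presences["lon"].to_numpy(dtype=float),
        presences["lat"].to_numpy(dtype=float),
    )
    usable = np.isfinite(scores)
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} presences on nodata cells were excluded "
            "from thresholding"
        )
    if not usable.any():
        raise ValueError("no presence falls on a data cell")
    thr = float(scores[usable].min())
    binary = np.where(
        np.isnan(suit.values), np.nan, (suit.values >= thr).astype(float)
    )
    return suit.with_values(binary, name="suitable"), thr


def lgm_consensus(map_a: RasterGrid, map_b: RasterGrid) -> RasterGrid:
    """Cellwise mean of the two palaeoclimate threshold-limited maps."""
    require_aligned(map_a, map_b)
    vals = (map_a.values + map_b.values) / 2.0
    return map_a.with_values(vals, name="lgm_consensus")


def future_consensus(maps: list[RasterGrid]) -> RasterGrid:
    """Suitable where at least half (ceil(n/2)) of the binary projections
    agree; nodata in any projection propagates."""
    if len(maps) < 2:
        raise ValueError("need at least two projections")
    require_aligned(*maps)
    stack = np.stack([m.values for m in maps])
    need = math.ceil(len(maps) / 2)
    count = (stack > 0).sum(axis=0)
    vals = (count >= need).astype(float)
    vals[np.isnan(stack).any(axis=0)] = np.nan
    return maps[0].with_values(vals, name="future_consensus")


def change_map(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Categorical suitability change: never/loss/gain/stable."""
    require_aligned(current, future)
    cur = current.values > 0
    fut = future.values > 0
    vals = np.select(
        [cur & fut, cur & ~fut, ~cur & fut],
        [CHANGE_CATEGORIES["stable-suitable"], CHANGE_CATEGORIES["loss"],
         CHANGE_CATEGORIES["gain"]],
        default=CHANGE_CATEGORIES["never-suitable"],
    ).astype(float)
    vals[np.isnan(current.values) | np.isnan(future.values)] = np.nan
    return current.with_values(vals, name="change")


def overlap_map(
    crop_current: RasterGrid,
    crop_future: RasterGrid,
    cwr_current: RasterGrid,
    cwr_future: RasterGrid,
) -> RasterGrid:
    """Crop/CWR overlap categories on binary suitability maps.

    Cells suitable for both groups split into overlap-current-both (both
    suitable now) and overlap-future-involved (the three combinations in
    which at least one of the two is only suitable in the future, merged
    into one class).
    """
    require_aligned(crop_current, crop_future, cwr_current, cwr_future)
    cc = crop_current.values > 0
    cf = crop_future.values > 0
    wc = cwr_current.values > 0
    wf = cwr_future.values > 0
    crop_any = cc | cf
    cwr_any = wc | wf
    vals = np.select(
        [crop_any & cwr_any & cc & wc, crop_any & cwr_any,
         crop_any & ~cwr_any, ~crop_any & cwr_any],
        [OVERLAP_CATEGORIES["overlap-current-both"],
         OVERLAP_CATEGORIES["overlap-future-involved"],
         OVERLAP_CATEGORIES["crop-only"], OVERLAP_CATEGORIES["cwr-only"]],
        default=OVERLAP_CATEGORIES["neither"],
    ).astype(float)
    nan_mask = (
        np.isnan(crop_current.values) | np.isnan(crop_future.values)
        | np.isnan(cwr_current.values) | np.isnan(cwr_future.values)
    )
    vals[nan_mask] = np.nan
    return crop_current.with_values(vals, name="overlap")
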