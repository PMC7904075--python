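"""Presence / pseudo-absence distribution modelling on predictor grids.

The workflow follows the random-forest species-distribution-model recipe
for a benthic fish: occurrence points are collapsed to unique grid cells,
combined with an equal number of pseudo-absence cells drawn away from
presences, split 80/20, and classified by an ensemble of k = 10 forests,
each trained on an independently regenerated pseudo-absence draw.  The
habitat-limiting thresholds are then read off the ensemble itself: each
training row's prediction is decomposed into per-predictor *feature
contributions* along the tree decision paths (an exactly additive
decomposition: bias + sum of contributions = predicted presence
probability), the contribution sign for the focal predictor is binarized,
and a logistic regression of that binary outcome on the predictor gives the
critical value at probability 0.5 (phi_crit for the minimum metabolic
index; interpolated zero crossings of binned mean contributions for the
depth window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr
from scipy import stats, ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "OccurrenceSet",
    "RFEnsemble",
    "ThresholdEstimate",
    "DepthWindow",
    "dedupe_occurrences",
    "generate_pseudo_absences",
    "build_training_table",
    "train_rf_ensemble",
    "compare_full_vs_reduced",
    "feature_contributions",
    "estimate_phi_crit",
    "estimate_depth_thresholds",
    "project_distribution",
    "compare_predictor_sets",
]


# ---------------------------------------------------------------------------
# grid bookkeeping


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    d = np.diff(centers)
    if len(d) == 0:
        raise ValueError("grid needs >= 2 cells per axis")
    if not np.allclose(d, d[0], rtol=1e-6):
        raise ValueError("irregular coordinate spacing")
    step = d[0]
    return np.concatenate([centers - step / 2, [centers[-1] + step / 2]])


@dataclass
class OccurrenceSet:
    """Unique presence cells on the analysis grid.

    ``cells`` holds (ilat, ilon) index pairs; ``n_points`` the raw point
    count, ``n_out_of_domain`` how many points fell outside the grid or the
    domain mask.
    """

    cells: np.ndarray
    n_points: int
    n_out_of_domain: int
    lat: np.ndarray
    lon: np.ndarray

    def __len__(self):
        return len(self.cells)


def dedupe_occurrences(points: pd.DataFrame, lat: np.ndarray, lon: np.ndarray,
                       domain_mask: np.ndarray | None = None) -> OccurrenceSet:
    """Assign lon/lat points to grid cells and drop duplicates.

    Cells are half-open intervals [west, east) x [south, north) around the
    cell centers, lower edge inclusive, so a point on a shared edge lands in
    exactly one cell.  Points outside the grid extent, or outside
    ``domain_mask`` if given, are counted but excluded.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat_e = _cell_edges(lat)
    lon_e = _cell_edges(lon)
    plat = points["lat"].to_numpy(float)
    plon = points["lon"].to_numpy(float)
    ilat = np.searchsorted(lat_e, plat, side="right") - 1
    ilon = np.searchsorted(lon_e, plon, side="right") - 1
    ok = (ilat >= 0) & (ilat < len(lat)) & (ilon >= 0) & (ilon < len(lon))
    if domain_mask is not None:
        dm = np.asarray(domain_mask, bool)
        ok &= np.where(ok, dm[np.clip(ilat, 0, len(lat) - 1),
                              np.clip(ilon, 0, len(lon) - 1)], False)
    lin = ilat[ok] * len(lon) + ilon[ok]
    uniq = np.unique(lin)
    cells = np.column_stack(np.divmod(uniq, len(lon)))
    return OccurrenceSet(cells=cells, n_points=len(points),
                         n_out_of_domain=int((~ok).sum()), lat=lat, lon=lon)


def generate_pseudo_absences(domain_mask: np.ndarray, presence_cells: np.ndarray,
                             n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` background cells uniformly without replacement from the
    domain, excluding presence cells and their 8-neighbors (queen adjacency).
    """
    dm = np.asarray(domain_mask, bool)
    presence = np.zeros_like(dm)
    presence[presence_cells[:, 0], presence_cells[:, 1]] = True
    excluded = ndimage.binary_dilation(presence, structure=np.ones((3, 3)))
    eligible = dm & ~excluded
    idx = np.flatnonzero(eligible)
    if len(idx) < n:
        raise ValueError(f"only {len(idx)} eligible cells for {n} pseudo-absences")
    pick = rng.choice(idx, size=n, replace=False)
    return np.column_stack(np.divmod(pick, dm.shape[1]))


def _predictor_matrix(layers: xr.Dataset, predictors: list[str],
                      cells: np.ndarray) -> np.ndarray:
    cols = [layers[p].values[cells[:, 0], cells[:, 1]] for p in predictors]
    return np.column_stack(cols).astype(float)


def build_training_table(layers: xr.Dataset, predictors: list[str],
                         presence_cells: np.ndarray, absence_cells: np.ndarray,
                         ) -> pd.DataFrame:
    """Balanced presence/pseudo-absence table with predictor values per cell."""
    if len(presence_cells) != len(absence_cells):
        raise ValueError("presence and pseudo-absence counts must be equal")
    cells = np.vstack([presence_cells, absence_cells])
    lin = cells[:, 0] * layers.sizes["lon"] + cells[:, 1]
    if len(np.unique(lin)) != len(lin):
        raise ValueError("a cell appears twice in the training table")
    X = _predictor_matrix(layers, predictors, cells)
    table = pd.DataFrame(X, columns=predictors)
    table.insert(0, "cell_lin", lin)
    table.insert(1, "label", np.r_[np.ones(len(presence_cells), int),
                                   np.zeros(len(absence_cells), int)])
    if table[predictors].isna().any().any():
        raise ValueError("NaN predictor values in training table")
    return table


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class FittedModel:
    model: RandomForestClassifier
    table: pd.DataFrame  # training table with split tag
    accuracy: float
    importance: dict  # predictor -> mean accuracy drop under permutation
    seed: int


@dataclass
class RFEnsemble:
    predictors: list
    models: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.models)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.models])

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame([m.importance for m in self.models])


def train_rf_ensemble(layers: xr.Dataset, presence_cells: np.ndarray,
                      predictors: list[str], domain_mask: np.ndarray,
                      k: int = 10, test_fraction: float = 0.2,
                      seed: int = 0, n_estimators: int = 500,
                      importance_repeats: int = 5) -> RFEnsemble:
    """Train ``k`` presence/pseudo-absence forests, each with its own
    pseudo-absence draw and stratified train/test split.

    Forest hyperparameters: ``n_estimators`` trees, sqrt(p) features per
    split, unlimited depth.  Test accuracy is the fraction of held-out cells
    classified correctly at the majority vote; permutation importance is the
    mean test-accuracy drop over ``importance_repeats`` random permutations
    of each predictor column (a "mean decrease in accuracy" analogue on
    test data).
    """
    if len(presence_cells) < 50:
        warnings.warn(f"only {len(presence_cells)} presence cells; ensemble "
                      "statistics will be unstable", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    ensemble = RFEnsemble(predictors=list(predictors))
    for child in ss.spawn(k):
        rng = np.random.default_rng(child)
        model_seed = int(child.generate_state(1)[0] % (2 ** 31))
        absences = generate_pseudo_absences(domain_mask, presence_cells,
                                            len(presence_cells), rng)
        table = build_training_table(layers, predictors, presence_cells, absences)
        y = table["label"].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training data")
        idx_train, idx_test = train_test_split(
            np.arange(len(table)), test_size=test_fraction, stratify=y,
            random_state=model_seed)
        table = table.copy()
        table["split"] = "train"
        table.loc[idx_test, "split"] = "test"
        X = table[predictors].to_numpy(float)
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", max_depth=None,
            random_state=model_seed, n_jobs=1)
        rf.fit(X[idx_train], y[idx_train])
        acc = float(np.mean(rf.predict(X[idx_test]) == y[idx_test]))
        importance = {}
        for j, p in enumerate(predictors):
            drops = []
            for _ in range(importance_repeats):
                Xp = X[idx_test].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(acc - np.mean(rf.predict(Xp) == y[idx_test]))
            importance[p] = float(np.mean(drops))
        ensemble.models.append(FittedModel(
            model=rf, table=table, accuracy=acc, importance=importance,
            seed=model_seed))
    return ensemble


@dataclass
class EnsembleComparison:
    mean_accuracy_full: float
    mean_accuracy_reduced: float
    t_statistic: float
    p_value: float

    @property
    def reduced_recommended(self) -> bool:
        """Prefer the simpler predictor set when accuracies are
        statistically indistinguishable (p > 0.05)."""
        return self.p_value > 0.05


def compare_full_vs_reduced(full: RFEnsemble, reduced: RFEnsemble
                            ) -> EnsembleComparison:
    """Two-sample Student t test on the per-model test accuracies."""
    if full.k < 2 or reduced.k < 2:
        raise ValueError("need >= 2 models per ensemble for a t test")
    t, p = stats.ttest_ind(full.accuracies, reduced.accuracies)
    return EnsembleComparison(
        mean_accuracy_full=float(full.accuracies.mean()),
        mean_accuracy_reduced=float(reduced.accuracies.mean()),
        t_statistic=float(t), p_value=float(p))


# ---------------------------------------------------------------------------
# feature contributions (tree-path decomposition)


def _node_presence_prob(tree, presence_col: int) -> np.ndarray:
    v = tree.value[:, 0, :]  # (n_nodes, n_classes) counts or frequencies
    return v[:, presence_col] / v.sum(axis=1)


def feature_contributions(model: RandomForestClassifier, X: np.ndarray):
    """Decompose forest presence probabilities into per-predictor contributions.

    For every tree the row's decision path is walked; each split on
    predictor f moves the node presence probability, and that change is
    credited to f.  Averaged over trees this yields ``(contributions,
    bias)`` with the exact identity ``bias + contributions.sum(axis=1) ==
    predict_proba(X)[:, presence]`` for every row.
    """
    if not hasattr(model, "estimators_"):
        raise TypeError("model is not a fitted tree ensemble")
    X = np.asarray(X, float)
    n, p = X.shape
    presence_col = int(np.flatnonzero(model.classes_ == 1)[0])
    contrib = np.zeros((n, p))
    bias = 0.0
    for est in model.estimators_:
        tree = est.tree_
        prob = _node_presence_prob(tree, presence_col)
        n_nodes = tree.node_count
        parent = np.full(n_nodes, -1)
        for node in range(n_nodes):
            for child in (tree.children_left[node], tree.children_right[node]):
                if child != -1:
                    parent[child] = node
        delta = np.zeros(n_nodes)
        feat_of_parent = np.zeros(n_nodes, int)
        non_root = parent >= 0
        delta[non_root] = prob[non_root] - prob[parent[non_root]]
        feat_of_parent[non_root] = tree.feature[parent[non_root]]
        indicator = est.decision_path(X)  # CSR (n, n_nodes)
        for f in range(p):
            w = delta * ((feat_of_parent == f) & non_root)
            contrib[:, f] += indicator @ w
        bias += prob[0]
    return contrib / len(model.estimators_), np.full(n, bias / len(model.estimators_))


def pooled_training_contributions(ensemble: RFEnsemble, predictor: str,
                                  split: str | None = None) -> pd.DataFrame:
    """Feature contributions of ``predictor`` for the training rows of every
    model in the ensemble, pooled into one table (model, value, contribution).
    """
    j = ensemble.predictors.index(predictor)
    frames = []
    for i, fm in enumerate(ensemble.models):
        rows = fm.table if split is None else fm.table[fm.table["split"] == split]
        X = rows[ensemble.predictors].to_numpy(float)
        contrib, _ = feature_contributions(fm.model, X)
        frames.append(pd.DataFrame({
            "model": i, "value": X[:, j], "contribution": contrib[:, j],
            "label": rows["label"].to_numpy()}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class ThresholdEstimate:
    """Critical predictor value where the sign of its feature contribution
    flips, from a logistic regression of the binarized contribution."""

    threshold: float
    beta0: float | None
    beta1: float | None
    ci: tuple | None  # 95% Wald interval
    method: str  # "logistic" or "separation_midpoint"
    n_rows: int


def _logistic_threshold(x: np.ndarray, y: np.ndarray) -> ThresholdEstimate:
    x0_max = x[y == 0].max()
    x1_min = x[y == 1].min()
    if x1_min >= x0_max:
        # complete separation: the MLE diverges; the 0.5 crossing is only
        # localized to the empty interval between the classes — take its
        # midpoint and flag it
        mid = 0.5 * (x0_max + x1_min)
        return ThresholdEstimate(threshold=float(mid), beta0=None, beta1=None,
                                 ci=None, method="separation_midpoint",
                                 n_rows=len(x))
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    b0, b1 = fit.params
    if not np.all(np.isfinite(fit.params)) or b1 == 0:
        raise RuntimeError("logistic fit degenerate")
    thr = -b0 / b1
    # delta-method Wald CI for -b0/b1
    grad = np.array([-1.0 / b1, b0 / b1 ** 2])
    var = float(grad @ fit.cov_params() @ grad)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ThresholdEstimate(threshold=float(thr), beta0=float(b0),
                             beta1=float(b1), ci=(float(thr - half),
                                                  float(thr + half)),
                             method="logistic", n_rows=len(x))


def estimate_phi_crit(ensemble: RFEnsemble, predictor: str = "min_phi",
                      split: str | None = None) -> ThresholdEstimate:
    """Critical metabolic index below which the species cannot persist.

    Pools the ``predictor`` feature contributions of all training rows from
    all k models, binarizes their sign (positive -> 1, otherwise 0) and fits
    a maximum-likelihood logistic regression of the binary outcome on the
    predictor value; the threshold is where the fitted probability is 0.5.
    """
    pooled = pooled_training_contributions(ensemble, predictor, split=split)
    y = (pooled["contribution"] > 0).to_numpy(int)
    if y.min() == y.max():
        raise ValueError("contributions all of one sign; no threshold to locate")
    return _logistic_threshold(pooled["value"].to_numpy(float), y)


@dataclass
class DepthWindow:
    lower: float | None  # m below sea level; None = open end
    upper: float | None
    bin_width: float
    n_rows: int


def estimate_depth_thresholds(ensemble: RFEnsemble, predictor: str = "depth",
                              bin_width: float = 2.0,
                              split: str | None = None,
                              min_bin_count: int = 5) -> DepthWindow:
    """Suitable-depth window from the sign structure of depth contributions.

    Depths are binned (default 2 m) and the mean contribution per bin
    computed.  The window bounds are the interpolated zero crossings
    bracketing the positive region: when noise produces multiple sign
    changes, the outermost pair around the global-maximum bin is taken
    (bins with fewer than ``min_bin_count`` rows do not extend the positive
    region).  A side with no crossing is reported as open (None).
    """
    pooled = pooled_training_contributions(ensemble, predictor, split=split)
    v = pooled["value"].to_numpy(float)
    c = pooled["contribution"].to_numpy(float)
    lo = np.floor(v.min() / bin_width) * bin_width
    edges = np.arange(lo, v.max() + bin_width, bin_width)
    which = np.clip(np.digitize(v, edges) - 1, 0, len(edges) - 2)
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            centers.append(edges[b] + bin_width / 2)
            means.append(c[sel].mean())
            counts.append(int(sel.sum()))
    centers = np.array(centers)
    means = np.array(means)
    counts = np.array(counts)
    if means.max() <= 0:
        raise ValueError("no depth bin with positive mean contribution")
    positive = (means > 0) & (counts >= min_bin_count)
    if not positive.any():
        positive = means > 0  # tiny pooled samples: ignore the count floor
    pos_idx = np.flatnonzero(positive)

    def _interp(inner: int, outer: int) -> float:
        x0, y0 = centers[inner], means[inner]
        x1, y1 = centers[outer], means[outer]
        if y1 > 0:  # outer bin positive but too sparse to extend the region
            return float(0.5 * (x0 + x1))
        return float(x0 + (x1 - x0) * y0 / (y0 - y1))

    first, last = pos_idx[0], pos_idx[-1]
    lower = _interp(first, first - 1) if first > 0 else None
    upper = _interp(last, last + 1) if last < len(means) - 1 else None
    if lower is None and upper is None:
        warnings.warn("contributions positive across all depth bins; "
                      "open window on both sides", stacklevel=2)
    return DepthWindow(lower=lower, upper=upper, bin_width=bin_width,
                       n_rows=len(pooled))


# ---------------------------------------------------------------------------
# projection and predictor-set comparison


def project_distribution(ensemble: RFEnsemble, layers: xr.Dataset,
                         domain_mask: np.ndarray) -> xr.DataArray:
    """Ensemble agreement map: per cell, the number of models whose majority
    vote is presence, scaled to 0-100 (100 = all k models agree suitable)."""
    missing = [p for p in ensemble.predictors if p not in layers]
    if missing:
        raise ValueError(f"missing predictor layers {missing}")
    dm = np.asarray(domain_mask, bool)
    cells = np.column_stack(np.nonzero(dm))
    X = _predictor_matrix(layers, ensemble.predictors, cells)
    valid = np.all(np.isfinite(X), axis=1)
    votes = np.zeros(valid.sum())
    for fm in ensemble.models:
        votes += (fm.model.predict(X[valid]) == 1)
    agreement = np.full(dm.shape, np.nan)
    agreement[cells[valid, 0], cells[valid, 1]] = votes * (100.0 / ensemble.k)
    ref = layers[ensemble.predictors[0]]
    out = xr.DataArray(agreement, coords={"lat": ref["lat"], "lon": ref["lon"]},
                       dims=("lat", "lon"), name="agreement")
    out.attrs = {"units": "%", "long_name": "ensemble agreement (suitable)"}
    return out


@dataclass
class PredictorSetComparison:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict
    tukey: pd.DataFrame  # pairwise Tukey HSD adjusted comparisons


def compare_predictor_sets(accuracy_vectors: dict) -> PredictorSetComparison:
    """One-way ANOVA across per-model accuracy vectors of competing predictor
    sets (e.g. phi vs FAS vs AAS vs temperature), with Tukey HSD pairwise
    adjusted p values."""
    names = list(accuracy_vectors)
    if len(names) < 2:
        raise ValueError("need >= 2 predictor sets")
    vecs = [np.asarray(accuracy_vectors[n], float) for n in names]
    if len({len(v) for v in vecs}) != 1:
        raise ValueError("accuracy vectors must have equal length")
    f, p = stats.f_oneway(*vecs)
    values = np.concatenate(vecs)
    groups = np.repeat(names, [len(v) for v in vecs])
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return PredictorSetComparison(
        f_statistic=float(f), df_between=len(names) - 1,
        df_within=len(values) - len(names), p_value=float(p),
        group_means={n: float(v.mean()) for n, v in zip(names, vecs)},
        tukey=tukey)
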