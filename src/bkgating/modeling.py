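"""Model selection, random-forest training, and bagged prediction uncertainty.

The regression target is the squashed ΔV1/2 (mV). Candidate model families
(ridge, SVR, KNN, random forest, Gaussian process, MLP) are compared by
grid-search with k-fold cross-validation on the training split; the random
forest is the production family and the only one carrying uncertainty
machinery. Production hyperparameters (500 trees, max depth 20, at most 100
leaf nodes, cost-complexity pruning alpha 0.01, bootstrap with out-of-bag
scoring):

Per-prediction uncertainty uses the infinitesimal-jackknife-for-bagging
variance estimator with the finite-ensemble bias correction (Wager,
Hastie & Efron 2014):

    V_IJ(x)   = Σ_i Cov_b[N_bi, t_b(x)]²
    V_IJ-U(x) = V_IJ(x) − (n/B) · mean_b[(t_b(x) − t̄(x))²]

where N_bi counts how often training sample i entered tree b's bootstrap
sample and t_b(x) is tree b's prediction. A tree-spread fallback (SD across
trees) is available behind a flag for diagnostics.

A control model omits every physics-derived descriptor (energetics and
dynamics blocks) and substitutes per-mutation changes in generic amino-acid
physicochemical properties, quantifying what the physics features add.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFECV
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import make_scorer, mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .features import FeatureMatrix

#: production random-forest hyperparameters
FOREST_HYPERPARAMETERS: dict = {
    "n_estimators": 500,
    "min_samples_split": 2,
    "max_leaf_nodes": 100,
    "max_depth": 20,
    "max_features": 1.0,
    "ccp_alpha": 0.01,
    "bootstrap": True,
    "oob_score": True,
    "max_samples": 1.0,
    "min_samples_leaf": 1,
}

MODEL_FAMILIES: dict[str, type] = {
    "ridge": Ridge,
    "svr": SVR,
    "knn": KNeighborsRegressor,
    "random_forest": RandomForestRegressor,
    "gaussian_process": GaussianProcessRegressor,
    "mlp": MLPRegressor,
}

#: families whose constructor accepts random_state
_SEEDED = {"random_forest", "gaussian_process", "mlp"}

#: classical physicochemical amino-acid properties used by the control model
#: (hydropathy: Kyte & Doolittle; volume: Zamyatnin, Å³; mass: residue Da;
#: pI: isoelectric point; polarity: Grantham; flexibility: Bhaskaran & Ponnuswamy;
#: bulkiness: Zimmerman; helix/sheet propensity: Chou & Fasman Pα/Pβ)
AA_PROPERTY_TABLE = pd.DataFrame(
    {
        "hydropathy": {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
                       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
                       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
                       "Y": -1.3, "V": 4.2},
        "volume_A3": {"A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
                      "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
                      "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
                      "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0},
        "mass_Da": {"A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
                    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
                    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
                    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13},
        "pI": {"A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
               "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
               "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
               "Y": 5.66, "V": 5.96},
        "polarity": {"A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
                     "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
                     "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
                     "Y": 6.2, "V": 5.9},
        "flexibility": {"A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
                        "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
                        "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
                        "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386},
        "bulkiness": {"A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
                      "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
                      "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
                      "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57},
        "helix_propensity": {"A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
                             "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
                             "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
                             "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06},
        "sheet_propensity": {"A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
                             "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
                             "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
                             "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70},
    }
)


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    split_seed: int
    fraction: float = 0.8

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class GatingModel:
    """A fitted regressor plus the bookkeeping needed downstream."""

    family: str
    hyperparameters: dict
    estimator: object
    feature_names: list[str]
    inbag: np.ndarray | None = None  # (n_train, n_trees) bootstrap counts
    n_train: int = 0
    seed: int | None = None

    @property
    def oob_score(self) -> float | None:
        return getattr(self.estimator, "oob_score_", None)

    def _check_features(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "feature columns do not match the training feature list "
                f"(expected {self.feature_names}, got {list(X.columns)})"
            )
        return X.to_numpy(float)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(self.estimator.predict(self._check_features(X)),
                         index=X.index, name="predicted_dV_mV")


@dataclass
class PredictionSet:
    """Per-mutation predicted ΔV1/2 (squashed scale, mV) with error estimate."""

    table: pd.DataFrame  # columns: predicted_dV_mV, error_mV
    model_family: str
    method: str

    @property
    def predictions(self) -> pd.Series:
        return self.table["predicted_dV_mV"]

    @property
    def errors(self) -> pd.Series:
        return self.table["error_mV"]


def make_splits(
    ids: Sequence[str], n_splits: int = 5, fraction: float = 0.8,
    seeds: Sequence[int] | None = None,
) -> list[SplitPlan]:
    """Independent random train/test splits of the mutation IDs."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(ids) < 10:
        raise ValueError("need at least 10 rows to split")
    if seeds is None:
        seeds = list(range(n_splits))
    if len(seeds) != n_splits:
        raise ValueError("need one seed per split")
    plans = []
    for s in seeds:
        tr, te = train_test_split(list(ids), train_size=fraction, random_state=int(s),
                                  shuffle=True)
        plans.append(SplitPlan(tuple(tr), tuple(te), int(s), fraction))
    return plans


def _pearson_score(y_true, y_pred):
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return 0.0
    return float(stats.pearsonr(y_true, y_pred)[0])


def make_model(family: str, params: Mapping | None = None, seed: int | None = None):
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {sorted(MODEL_FAMILIES)}")
    kwargs = dict(params or {})
    if family == "random_forest" and not kwargs:
        kwargs = dict(FOREST_HYPERPARAMETERS)
    if family in _SEEDED and seed is not None:
        kwargs.setdefault("random_state", seed)
    if family == "mlp":
        kwargs.setdefault("max_iter", 2000)
    return MODEL_FAMILIES[family](**kwargs)


def grid_search(
    X: pd.DataFrame, y: pd.Series, family: str, grid: Mapping[str, Sequence],
    k: int = 5, seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search with k-fold CV on the training data.

    Selection metric is mean validation RMSE; per-cell train/validation RMSE
    and Pearson R are all returned. Cells that fail to fit score NaN rather
    than aborting the search.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    base = make_model(family, params={}, seed=seed) if family != "random_forest" \
        else make_model(family, params={"n_estimators": 100}, seed=seed)
    cv = KFold(n_splits=min(k, len(X)), shuffle=True, random_state=seed)
    gs = GridSearchCV(
        base, param_grid=dict(grid), cv=cv,
        scoring={
            "rmse": "neg_root_mean_squared_error",
            "r": make_scorer(_pearson_score),
        },
        refit=False, return_train_score=True, error_score=np.nan,
    )
    gs.fit(X.to_numpy(float), y.to_numpy(float))
    res = pd.DataFrame(gs.cv_results_)
    best_idx = int(res["mean_test_rmse"].idxmax())  # scores are negated RMSE
    best = dict(res.loc[best_idx, "params"])
    return best, res


def train_forest(
    X: pd.DataFrame, y: pd.Series,
    hyperparameters: Mapping | None = None, seed: int = 0,
) -> GatingModel:
    """Fit the production random forest and record per-tree in-bag counts."""
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(X.to_numpy(float)).all() or not np.isfinite(y.to_numpy(float)).all():
        raise ValueError("features/labels contain non-finite values")
    params = dict(FOREST_HYPERPARAMETERS if hyperparameters is None else hyperparameters)
    est = RandomForestRegressor(random_state=seed, **params)
    est.fit(X.to_numpy(float), y.to_numpy(float))
    inbag = None
    if params.get("bootstrap", True):
        n = len(X)
        inbag = np.zeros((n, len(est.estimators_)), dtype=np.int64)
        for b, idx in enumerate(est.estimators_samples_):
            inbag[:, b] = np.bincount(idx, minlength=n)
    return GatingModel(
        family="random_forest", hyperparameters=params, estimator=est,
        feature_names=list(X.columns), inbag=inbag, n_train=len(X), seed=seed,
    )


def _jackknife_variance(tree_preds: np.ndarray, inbag: np.ndarray) -> np.ndarray:
    """Infinitesimal-jackknife-for-bagging variance with finite-B correction.

    ``tree_preds``: (B, m) per-tree predictions; ``inbag``: (n, B) counts.
    Returns the bias-corrected variance per prediction, clipped at zero.
    """
    n, B = inbag.shape
    centered_pred = tree_preds - tree_preds.mean(axis=0, keepdims=True)  # (B, m)
    centered_N = inbag - inbag.mean(axis=1, keepdims=True)  # (n, B)
    cov = centered_N @ centered_pred / B  # (n, m)
    v_ij = np.sum(cov**2, axis=0)  # (m,)
    boot_var = np.mean(centered_pred**2, axis=0)  # (m,)
    return np.clip(v_ij - n * boot_var / B, 0.0, None)


def predict_with_error(model: GatingModel, X: pd.DataFrame,
                       method: str = "jackknife") -> PredictionSet:
    """Ensemble-mean prediction with a per-point error estimate (SD, mV).

    ``method="jackknife"`` uses the bias-corrected infinitesimal jackknife;
    ``method="tree_spread"`` reports the SD across trees (diagnostic only).
    """
    if model.family != "random_forest":
        raise ValueError("error estimation requires a random forest; use model.predict")
    if method not in ("jackknife", "tree_spread"):
        raise ValueError("method must be 'jackknife' or 'tree_spread'")
    Xa = model._check_features(X)
    tree_preds = np.stack([t.predict(Xa) for t in model.estimator.estimators_])  # (B, m)
    mean = tree_preds.mean(axis=0)
    if method == "tree_spread":
        err = tree_preds.std(axis=0, ddof=0)
    else:
        if model.inbag is None:
            raise ValueError("model carries no in-bag counts (bootstrap disabled?)")
        err = np.sqrt(_jackknife_variance(tree_preds, model.inbag))
    table = pd.DataFrame({"predicted_dV_mV": mean, "error_mV": err}, index=X.index)
    return PredictionSet(table=table, model_family=model.family, method=method)


def feature_importance(model: GatingModel) -> list[tuple[str, float]]:
    """Impurity-decrease importances, normalized to sum 1, descending."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError("model is not a fitted tree ensemble")
    imp = np.asarray(est.feature_importances_, float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp)
    return [(model.feature_names[i], float(imp[i])) for i in order]


def control_features(
    dataset: pd.DataFrame,
    fm: FeatureMatrix,
    aa_property_matrix: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Feature matrix for the no-physics control model.

    Drops every energetics- and dynamics-derived column and appends the
    change (mutant − WT) in each generic amino-acid property. Structure and
    sequence annotations are retained.
    """
    props = AA_PROPERTY_TABLE if aa_property_matrix is None else aa_property_matrix
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(props.index)
    if missing:
        raise ValueError(f"property matrix missing residues: {sorted(missing)}")
    keep = fm.columns_from("structure", "sequence", "hydrophobicity")
    ds = dataset.set_index("mutation").loc[fm.X.index]
    deltas = pd.DataFrame(
        {f"d_{c}": props.loc[ds["mut_aa"], c].to_numpy() - props.loc[ds["wt_aa"], c].to_numpy()
         for c in props.columns},
        index=fm.X.index,
    )
    X = pd.concat([fm.X[keep], deltas], axis=1)
    prov = {c: fm.provenance[c] for c in keep}
    prov.update({c: "aaindex-control" for c in deltas.columns})
    return FeatureMatrix(X=X, provenance=prov, y=fm.y)


def train_control(
    dataset: pd.DataFrame, fm: FeatureMatrix, y: pd.Series,
    aa_property_matrix: pd.DataFrame | None = None,
    hyperparameters: Mapping | None = None, seed: int = 0,
) -> tuple[GatingModel, FeatureMatrix]:
    """Train the no-physics control forest with the production hyperparameters."""
    cfm = control_features(dataset, fm, aa_property_matrix)
    model = train_forest(cfm.X, y.loc[cfm.X.index], hyperparameters, seed)
    return model, cfm


def recursive_feature_elimination(
    X: pd.DataFrame, y: pd.Series, family: str = "random_forest",
    step: int = 1, k: int = 5, seed: int = 0,
    params: Mapping | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop the least-important feature one step at a time, scoring each size
    by k-fold CV RMSE; return the size minimizing it plus the full trace."""
    if X.shape[1] == 1:
        return list(X.columns), pd.DataFrame({"n_features": [1], "cv_rmse": [np.nan]})
    if step >= X.shape[1]:
        raise ValueError("step must be smaller than the number of features")
    est_params = dict(params or {})
    if family == "random_forest":
        est_params.setdefault("n_estimators", 100)
        est_params.setdefault("ccp_alpha", 0.01)
    est = make_model(family, est_params, seed=seed)
    if not (hasattr(est, "feature_importances_") or hasattr(est, "coef_")
            or family in ("random_forest", "ridge", "svr")):
        raise ValueError(f"family {family!r} exposes neither importances nor coefficients")
    if family == "svr":
        est.set_params(kernel="linear")  # RFE needs coefficients
    cv = KFold(n_splits=min(k, len(X)), shuffle=True, random_state=seed)
    rfe = RFECV(est, step=step, cv=cv, scoring="neg_root_mean_squared_error",
                min_features_to_select=1)
    rfe.fit(X.to_numpy(float), y.to_numpy(float))
    retained = [c for c, s in zip(X.columns, rfe.support_) if s]
    res = rfe.cv_results_
    trace = pd.DataFrame({
        "n_features": res["n_features"],
        "cv_rmse": -np.asarray(res["mean_test_score"]),
    })
    return retained, trace
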