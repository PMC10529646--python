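"""Evaluation: correlation, RMSE, enrichment factor, robustness, hotspot maps.

Three goodness-of-fit metrics summarize a model's usefulness:

* Pearson R between predicted and measured ΔV1/2;
* RMSE in mV;
* the enrichment factor (EF): the fraction of the ``top_n`` highest
  predictions whose true shift exceeds +50 mV, plus the fraction of the
  ``top_n`` lowest predictions whose true shift falls below −50 mV, divided
  by f50, the dataset's overall fraction of |ΔV1/2| > 50 mV. Under random
  ranking the expectation is exactly 1; a model that concentrates true
  large-shift mutations at the extremes of its ranking scores well above 1.

The multi-split report re-runs the leakage-safe pipeline (prune →
standardize → train → predict → score) on independent 80/20 splits, with
and without physics-derived features, which is how the value of the physics
descriptors is quantified. Per-residue hotspot maps reduce a full
single-mutation scan to the signed maximum-magnitude shift at each position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix, prune_features, standardize
from .modeling import (
    GatingModel,
    SplitPlan,
    control_features,
    make_splits,
    predict_with_error,
    train_forest,
)

#: large-shift threshold for EF and dataset-balance diagnostics, mV
LARGE_SHIFT_MV = 50.0


@dataclass(frozen=True)
class EvalReport:
    split_id: int
    pearson_r: float
    rmse: float
    ef: float
    n_train: int
    n_test: int
    frac_large_train: float
    frac_large_test: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r out of [-1, 1]")
        if self.rmse < 0 or self.ef < 0:
            raise ValueError("rmse and ef must be nonnegative")


def pearson_r(pred: Sequence[float], true: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on degenerate input."""
    p = np.asarray(pred, float)
    t = np.asarray(true, float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    if p.std() == 0 or t.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(p, t)[0])


def rmse(pred: Sequence[float], true: Sequence[float]) -> float:
    p = np.asarray(pred, float)
    t = np.asarray(true, float)
    if p.shape != t.shape or p.size < 1:
        raise ValueError("need equal-length nonempty arrays")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def enrichment_factor(
    pred: Sequence[float], true: Sequence[float],
    top_n: int = 10, threshold: float = LARGE_SHIFT_MV,
    f_large: float | None = None,
) -> float:
    """EF = (hit rate in top_n + hit rate in bottom_n) / f_large.

    Hits in the top are true shifts > +threshold; in the bottom, < −threshold.
    ``f_large`` defaults to the fraction of |true| > threshold in the data.
    Ranking ties are broken by stable input order.
    """
    p = np.asarray(pred, float)
    t = np.asarray(true, float)
    if p.shape != t.shape:
        raise ValueError("pred and true must have equal length")
    if p.size < 2 * top_n:
        raise ValueError(f"need at least {2 * top_n} points for top/bottom {top_n}")
    if f_large is None:
        f_large = float(np.mean(np.abs(t) > threshold))
    if f_large == 0:
        raise ValueError("f_large is zero: EF undefined")
    order = np.argsort(p, kind="stable")
    bottom = order[:top_n]
    top = order[-top_n:]
    frac_top = float(np.mean(t[top] > threshold))
    frac_bottom = float(np.mean(t[bottom] < -threshold))
    return (frac_top + frac_bottom) / f_large


def evaluate_split(
    fm: FeatureMatrix,
    plan: SplitPlan,
    dataset: pd.DataFrame | None = None,
    with_physics: bool = True,
    hyperparameters=None,
    seed: int = 0,
    top_n: int = 10,
    threshold: float = LARGE_SHIFT_MV,
    r_max: float = 0.7,
) -> tuple[EvalReport, GatingModel]:
    """Run the leakage-safe pipeline on one split and score the test set.

    Pruning decisions and scaler moments are learned on the training rows
    only. ``with_physics=False`` swaps in the no-physics control features
    (requires ``dataset`` for the WT/mutant residue identities).
    """
    if fm.y is None:
        raise ValueError("feature matrix carries no labels")
    work = fm
    if not with_physics:
        if dataset is None:
            raise ValueError("control mode needs the curated dataset for residue identities")
        work = control_features(dataset, fm)
    train_ids, test_ids = list(plan.train_ids), list(plan.test_ids)
    train_fm = work.subset_rows(train_ids)
    pruned, _ = prune_features(train_fm, r_max=r_max)
    cols = pruned.feature_names
    scaled_train = standardize(pruned)
    model = train_forest(scaled_train.X, work.y.loc[train_ids], hyperparameters, seed)
    # transform test rows with train moments
    test_X = (work.X.loc[test_ids, cols] - scaled_train.scaler_mean) / scaled_train.scaler_sd
    pred = model.predict(test_X)
    true = work.y.loc[test_ids]
    report = EvalReport(
        split_id=plan.split_seed,
        pearson_r=pearson_r(pred, true),
        rmse=rmse(pred, true),
        ef=enrichment_factor(pred.to_numpy(), true.to_numpy(), top_n=top_n,
                             threshold=threshold,
                             f_large=float(np.mean(np.abs(work.y) > threshold))),
        n_train=len(train_ids), n_test=len(test_ids),
        frac_large_train=float(np.mean(np.abs(work.y.loc[train_ids]) > threshold)),
        frac_large_test=float(np.mean(np.abs(true) > threshold)),
    )
    return report, model


def multi_split_report(
    fm: FeatureMatrix,
    dataset: pd.DataFrame | None = None,
    n_splits: int = 5,
    with_physics: bool = True,
    seed: int = 0,
    hyperparameters=None,
    top_n: int = 10,
    threshold: float = LARGE_SHIFT_MV,
) -> pd.DataFrame:
    """Score ``n_splits`` independent 80/20 splits; one report row per split."""
    seeds = [seed + i for i in range(n_splits)]
    plans = make_splits(list(fm.X.index), n_splits=n_splits, seeds=seeds)
    rows = []
    for plan in plans:
        rep, _ = evaluate_split(fm, plan, dataset=dataset, with_physics=with_physics,
                                hyperparameters=hyperparameters, seed=seed,
                                top_n=top_n, threshold=threshold)
        rows.append(rep.__dict__)
    return pd.DataFrame(rows)


def per_residue_max_shift(
    predictions: pd.Series, positions: pd.Series, signed: bool = True,
) -> pd.Series:
    """Per-position maximum-magnitude predicted shift (sign retained by default).

    ``predictions`` and ``positions`` are aligned on mutation ID.
    """
    df = pd.DataFrame({"pred": predictions, "position": positions.loc[predictions.index]})

    def pick(g: pd.Series) -> float:
        v = g.to_numpy()
        i = int(np.argmax(np.abs(v)))
        return float(v[i]) if signed else float(abs(v[i]))

    out = df.groupby("position")["pred"].apply(pick)
    out.name = "max_shift_mV"
    return out
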