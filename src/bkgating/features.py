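"""Descriptor assembly: merge, prune, and standardize the feature matrix.

Mutation-level descriptors (per-term ΔΔΔG, hydrophobicity change) are joined
with position-level descriptors (RMSF, anchor covariances, SASA fraction,
exposure and secondary-structure classes, pore-lining flag, conservation)
broadcast to every mutation at that position. Categorical classes are
one-hot encoded over their full category set so each class group sums to 1
per row.

Before modeling, constant columns and one member of every feature pair with
|Pearson r| above 0.7 are discarded (greedy, in declared column order,
dropping the later column), and the survivors are standardized to zero mean
and unit variance. Standardization moments are learned on the training rows
only and applied to all rows — a leakage-safe refinement of standardizing
the full table up front; a ``fit_rows=None`` call reproduces the
whole-table variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Kyte-Doolittle hydropathy index (the packaged default hydrophobicity scale)
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SS_CLASSES = ("H", "E", "C")
EXPOSURE_CLASSES = ("WATER", "LIPID", "BORDER", "BURIED")


def hydrophobicity_change(wt_aa: str, mut_aa: str,
                          scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """scale[mut] − scale[wt]; antisymmetric in its arguments."""
    for aa in (wt_aa, mut_aa):
        if aa not in scale:
            raise KeyError(f"residue {aa!r} not in hydrophobicity scale")
    return float(scale[mut_aa] - scale[wt_aa])


@dataclass
class FeatureMatrix:
    """Mutation × descriptor table with provenance and (optional) scaler state."""

    X: pd.DataFrame  # rows: mutation IDs, columns: named features
    provenance: dict[str, str]  # column -> energetics|dynamics|structure|sequence|hydrophobicity|aaindex-control
    y: pd.Series | None = None  # squashed ΔV1/2 labels, aligned to X
    scaler_mean: pd.Series | None = None
    scaler_sd: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        unknown = set(self.X.columns) - set(self.provenance)
        if unknown:
            raise ValueError(f"columns without provenance: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def columns_from(self, *sources: str) -> list[str]:
        return [c for c in self.X.columns if self.provenance[c] in sources]

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        y = self.y.loc[list(ids)] if self.y is not None else None
        return replace(self, X=self.X.loc[list(ids)], y=y)

    # -- persistence (CSV + JSON sidecar) ------------------------------------
    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        out = self.X.copy()
        if self.y is not None:
            out["__label_dV_mV"] = self.y
        out.to_csv(csv_path, index_label="mutation")
        side = {
            "provenance": self.provenance,
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.to_dict(),
            "scaler_sd": None if self.scaler_sd is None else self.scaler_sd.to_dict(),
            "has_label": self.y is not None,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(side, indent=2, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path) -> "FeatureMatrix":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, index_col="mutation")
        side = json.loads(csv_path.with_suffix(".json").read_text())
        y = None
        if side["has_label"]:
            y = df.pop("__label_dV_mV")
        mean = side["scaler_mean"]
        sd = side["scaler_sd"]
        return cls(
            X=df, provenance=side["provenance"], y=y,
            scaler_mean=None if mean is None else pd.Series(mean).loc[df.columns],
            scaler_sd=None if sd is None else pd.Series(sd).loc[df.columns],
        )


def _one_hot(series: pd.Series, classes: Sequence[str], prefix: str) -> pd.DataFrame:
    cat = pd.Categorical(series, categories=list(classes))
    if cat.isna().any():
        bad = sorted(set(series) - set(classes))
        raise ValueError(f"unknown {prefix} classes: {bad}")
    dummies = pd.get_dummies(cat, prefix=prefix).astype(float)
    dummies.index = series.index
    return dummies


def assemble(
    dddg_table: pd.DataFrame,
    dynamic_features: pd.DataFrame,
    annotations: pd.DataFrame,
    dataset: pd.DataFrame,
    hydro_scale: Mapping[str, float] = KYTE_DOOLITTLE,
    allow_drop: bool = False,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Merge every descriptor source into one matrix over the labeled dataset.

    ``dddg_table``: wide ΔΔΔG (index mutation, term columns + total).
    ``dynamic_features``: per-position block (rmsf, cov_*), index position.
    ``annotations``: per-position table with ss_class, exposure_class,
    pore_lining, sasa_pct, conservation.
    ``dataset``: curated table with mutation, wt_aa, position, mut_aa and a
    ``dV_squashed_mV`` label column.

    Mutations missing any source are an error unless ``allow_drop``; the
    join report (second return value) lists them either way.
    """
    ds = dataset.set_index("mutation", drop=False)
    ann = annotations.set_index("position")
    report_rows = []
    keep = []
    for mid, row in ds.iterrows():
        missing = []
        if mid not in dddg_table.index:
            missing.append("energetics")
        if row["position"] not in dynamic_features.index:
            missing.append("dynamics")
        if row["position"] not in ann.index:
            missing.append("annotations")
        if missing:
            report_rows.append({"mutation": mid, "missing": "+".join(missing)})
        else:
            keep.append(mid)
    report = pd.DataFrame(report_rows, columns=["mutation", "missing"])
    if len(report) and not allow_drop:
        raise ValueError(
            f"{len(report)} mutations missing a feature source "
            f"(e.g. {report.iloc[0].to_dict()}); pass allow_drop=True to drop them"
        )

    ds = ds.loc[keep]
    pos = ds["position"]

    energ = dddg_table.loc[keep]
    dyn = dynamic_features.loc[pos].set_index(ds.index)
    sasa = ann.loc[pos, "sasa_pct"].set_axis(ds.index)
    cons = ann.loc[pos, "conservation"].set_axis(ds.index)
    pore = ann.loc[pos, "pore_lining"].astype(float).set_axis(ds.index)
    ss = _one_hot(ann.loc[pos, "ss_class"].set_axis(ds.index), SS_CLASSES, "ss")
    expo = _one_hot(ann.loc[pos, "exposure_class"].set_axis(ds.index), EXPOSURE_CLASSES, "exposure")
    dhydro = pd.Series(
        [hydrophobicity_change(w, m, hydro_scale) for w, m in zip(ds["wt_aa"], ds["mut_aa"])],
        index=ds.index, name="d_hydrophobicity",
    )

    X = pd.concat([energ, dyn, sasa, cons, pore, ss, expo, dhydro], axis=1)
    X.index.name = "mutation"
    provenance: dict[str, str] = {}
    for c in energ.columns:
        provenance[c] = "energetics"
    for c in dyn.columns:
        provenance[c] = "dynamics"
    provenance["sasa_pct"] = "dynamics"
    provenance["conservation"] = "sequence"
    provenance["pore_lining"] = "structure"
    for c in ss.columns:
        provenance[c] = "structure"
    for c in expo.columns:
        provenance[c] = "structure"
    provenance["d_hydrophobicity"] = "hydrophobicity"

    y = ds["dV_squashed_mV"] if "dV_squashed_mV" in ds.columns else None
    return FeatureMatrix(X=X.astype(float), provenance=provenance, y=y), report


def prune_features(fm: FeatureMatrix, r_max: float = 0.7) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Drop constant columns, then greedily decorrelate.

    Columns are visited in declared order; when a pair exceeds ``|r| >
    r_max`` the *later* column is dropped. The removal log records each drop
    and its trigger. Raises if nothing survives.
    """
    if len(fm.X) < 2:
        raise ValueError("need at least 2 rows to prune")
    X = fm.X
    log = []
    keep = []
    for c in X.columns:
        if X[c].nunique() <= 1:
            log.append({"column": c, "reason": "constant", "partner": ""})
        else:
            keep.append(c)
    corr = X[keep].corr().abs()
    surviving: list[str] = []
    for c in keep:
        partner = next((s for s in surviving if corr.loc[c, s] > r_max), None)
        if partner is None:
            surviving.append(c)
        else:
            log.append({"column": c, "reason": f"|r|>{r_max}", "partner": partner})
    if not surviving:
        raise ValueError("pruning removed every column")
    pruned = replace(
        fm,
        X=X[surviving],
        provenance={c: fm.provenance[c] for c in surviving},
        scaler_mean=None, scaler_sd=None,
    )
    return pruned, pd.DataFrame(log, columns=["column", "reason", "partner"])


def standardize(fm: FeatureMatrix, fit_rows: Sequence[str] | None = None) -> FeatureMatrix:
    """Standardize all rows using moments learned from ``fit_rows`` only.

    ``fit_rows=None`` fits on every row (whole-table mode). Population SD
    (ddof=0) is used, matching the usual preprocessing-scaler convention.
    """
    rows = list(fm.X.index) if fit_rows is None else list(fit_rows)
    if not rows:
        raise ValueError("fit_rows is empty")
    fit = fm.X.loc[rows]
    mean = fit.mean()
    sd = fit.std(ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero SD on fit rows for column(s): {list(zero.index)}")
    return replace(fm, X=(fm.X - mean) / sd, scaler_mean=mean, scaler_sd=sd)


def inverse_standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Undo :func:`standardize` using the stored moments."""
    if fm.scaler_mean is None or fm.scaler_sd is None:
        raise ValueError("matrix carries no scaler moments")
    return replace(fm, X=fm.X * fm.scaler_sd + fm.scaler_mean,
                   scaler_mean=None, scaler_sd=None)
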