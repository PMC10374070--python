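"""Per-timepoint gradient-boosted regression under nested cross-validation.

Glucose and insulin concentrations (or mechanistic-model residuals) at
each OGTT timepoint are regressed on a shared phenotype feature set with
gradient boosting.  A nested 5x5 cross-validation scheme keeps the
performance estimate unbiased: the outer folds are held out entirely,
while the inner folds tune a limited hyperparameter grid on training
data only.  Feature standardization, imputation and dummy coding are
fitted within each training fold, so no test-row statistic ever enters
the model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

__all__ = [
    "FeatureTable",
    "HyperparameterGrid",
    "EncoderStats",
    "NestedCVResult",
    "DEFAULT_GRID",
    "fast_grid",
    "fit_encoder",
    "encode_features",
    "tune_and_fit",
    "nested_cv_predict",
    "relative_importances",
]

MISSING_LEVEL = "__missing__"


@dataclass
class FeatureTable:
    """Per-subject phenotype features with a numeric/categorical schema."""

    data: pd.DataFrame          # must contain a subject_id column
    schema: dict[str, str]      # column -> "numeric" | "categorical"

    def __post_init__(self) -> None:
        if "subject_id" not in self.data.columns:
            raise ValueError("feature table requires a subject_id column")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate subject ids in feature table")
        cols = [c for c in self.data.columns if c != "subject_id"]
        untagged = set(cols) - set(self.schema)
        if untagged:
            raise ValueError(f"columns missing from schema: {sorted(untagged)}")
        bad = {c: k for c, k in self.schema.items() if k not in ("numeric", "categorical")}
        if bad:
            raise ValueError(f"invalid schema tags: {bad}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "subject_id"]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search grid for the boosted-tree regressor, iterated in a fixed order."""

    n_estimators: tuple[int, ...] = (100, 300)
    max_depth: tuple[int, ...] = (2, 3, 4)
    learning_rate: tuple[float, ...] = (0.05, 0.1)
    subsample: tuple[float, ...] = (0.8, 1.0)

    def __post_init__(self) -> None:
        for name in ("n_estimators", "max_depth", "learning_rate", "subsample"):
            if not getattr(self, name):
                raise ValueError(f"empty grid dimension {name}")

    def configurations(self) -> list[dict]:
        return [
            {"n_estimators": n, "max_depth": d, "learning_rate": lr, "subsample": s}
            for n, d, lr, s in itertools.product(
                self.n_estimators, self.max_depth, self.learning_rate, self.subsample)
        ]


DEFAULT_GRID = HyperparameterGrid()


def fast_grid() -> HyperparameterGrid:
    """A 4-point grid for desk-scale runs (varies depth and shrinkage only)."""
    return HyperparameterGrid(n_estimators=(100,), max_depth=(2, 3),
                              learning_rate=(0.05, 0.1), subsample=(1.0,))


@dataclass
class EncoderStats:
    """Per-column statistics fitted on training rows only."""

    numeric: dict[str, tuple[float, float, float]]   # median, mean, sd
    levels: dict[str, list[str]]                     # categorical -> training levels
    warnings: list[str] = field(default_factory=list)


def fit_encoder(table: FeatureTable, train_ids: Sequence[str]) -> EncoderStats:
    """Compute imputation/standardization statistics from training rows."""
    df = table.data.set_index("subject_id").loc[list(train_ids)]
    numeric: dict[str, tuple[float, float, float]] = {}
    levels: dict[str, list[str]] = {}
    warns: list[str] = []
    for col in table.feature_columns:
        if table.schema[col] == "numeric":
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            med = float(vals.median()) if len(vals) else 0.0
            mean = float(vals.mean()) if len(vals) else 0.0
            sd = float(vals.std(ddof=0)) if len(vals) else 0.0
            if sd <= 1e-12 * max(1.0, abs(mean)):
                sd = 0.0
                warns.append(f"zero-variance numeric column {col!r}")
            numeric[col] = (med, mean, sd)
        else:
            lv = sorted(df[col].dropna().astype(str).unique())
            if df[col].isna().any():
                lv.append(MISSING_LEVEL)
            levels[col] = lv
    return EncoderStats(numeric=numeric, levels=levels, warnings=warns)


def encode_features(table: FeatureTable, stats: EncoderStats,
                    ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Numeric design matrix for the given subjects using training statistics.

    Numeric columns: training-median imputation then z-scoring with the
    training mean/sd (zero-variance columns become all zeros).
    Categorical columns: one indicator per training level; missing values
    get an explicit level; unseen test levels map to all-zeros.
    """
    df = table.data.set_index("subject_id")
    if ids is not None:
        df = df.loc[list(ids)]
    blocks: list[pd.DataFrame] = []
    for col in table.feature_columns:
        if table.schema[col] == "numeric":
            med, mean, sd = stats.numeric[col]
            x = pd.to_numeric(df[col], errors="coerce").fillna(med)
            z = (x - mean) / sd if sd > 0 else x * 0.0
            blocks.append(z.to_frame(col))
        else:
            raw = df[col].astype(object).where(df[col].notna(), MISSING_LEVEL).astype(str)
            sub = pd.DataFrame(index=df.index)
            for lv in stats.levels[col]:
                sub[f"{col}={lv}"] = (raw == lv).astype(float)
            blocks.append(sub)
    out = pd.concat(blocks, axis=1)
    out.columns = [str(c) for c in out.columns]
    return out


def _parent_feature(column: str) -> str:
    return column.split("=", 1)[0]


def tune_and_fit(X: pd.DataFrame, y: np.ndarray,
                 grid: HyperparameterGrid = DEFAULT_GRID,
                 inner_k: int = 5, seed: int = 0):
    """Inner-CV hyperparameter search minimizing mean MSE, then refit.

    Ties go to the first configuration in the grid's deterministic order.
    Returns ``(model, chosen, inner_mse)``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * inner_k:
        raise ValueError(f"need at least {2 * inner_k} rows for {inner_k}-fold tuning")
    configs = grid.configurations()
    if np.std(y) == 0:
        warnings.warn("constant target: model will predict the constant", RuntimeWarning)
    kf = KFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    Xv = X.to_numpy()
    mse = np.zeros(len(configs))
    for ci, cfgd in enumerate(configs):
        errs = []
        for tr, te in splits:
            m = GradientBoostingRegressor(random_state=seed, **cfgd)
            m.fit(Xv[tr], y[tr])
            pred = m.predict(Xv[te])
            errs.append(float(np.mean((pred - y[te]) ** 2)))
        mse[ci] = float(np.mean(errs))
    best = int(np.argmin(mse))  # argmin takes the first minimum: deterministic tie-break
    chosen = configs[best]
    model = GradientBoostingRegressor(random_state=seed, **chosen)
    model.fit(Xv, y)
    return model, chosen, mse


def relative_importances(model, feature_columns: Sequence[str]) -> dict[str, float]:
    """Normalized gain importances aggregated to the original features.

    The regressor reports, per design-matrix column, the MSE reduction
    weighted by the fraction of samples reaching each split.  Indicator
    columns of one categorical feature are summed into their parent, and
    the result is normalized to sum to 1 (all-zeros with no splits).
    """
    raw = np.asarray(model.feature_importances_, dtype=float)
    agg: dict[str, float] = {}
    for col, v in zip(feature_columns, raw):
        parent = _parent_feature(col)
        agg[parent] = agg.get(parent, 0.0) + float(v)
    total = sum(agg.values())
    if total <= 0:
        warnings.warn("model has no splits: importances are all zero", RuntimeWarning)
        return {k: 0.0 for k in agg}
    return {k: v / total for k, v in agg.items()}


@dataclass
class NestedCVResult:
    """Out-of-fold predictions and per-fold metadata of one nested CV run."""

    fold_of_subject: dict[str, int]
    oof_predictions: pd.DataFrame            # index subject_id, one column per target
    chosen_params: dict[str, list[dict]]     # target -> per-outer-fold winner
    importances_mean: pd.DataFrame           # index feature, columns targets
    importances_sd: pd.DataFrame
    targets: list[str]


def nested_cv_predict(table: FeatureTable, targets: Mapping[str, pd.Series],
                      outer_k: int = 5, inner_k: int = 5, seed: int = 0,
                      grid: HyperparameterGrid = DEFAULT_GRID) -> NestedCVResult:
    """Nested cross-validated predictions for every target.

    One outer partition of subjects is shared by all targets; subjects
    with a missing value for a target are dropped for that target only.
    Encoding and tuning see training rows exclusively.  The feature set
    is shared across targets and no interaction columns are engineered.
    """
    ids = np.array(table.subject_ids)
    n = len(ids)
    if n < outer_k:
        raise ValueError(f"need at least {outer_k} subjects")
    for name, s in targets.items():
        if not s.index.equals(pd.Index(ids)):
            raise ValueError(f"target {name!r} index must match the feature table ids")

    outer = KFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_of_subject: dict[str, int] = {}
    oof = pd.DataFrame(index=pd.Index(ids, name="subject_id"),
                       columns=list(targets), dtype=float)
    chosen: dict[str, list[dict]] = {t: [] for t in targets}
    imp_folds: dict[str, list[dict[str, float]]] = {t: [] for t in targets}

    for fold, (tr_idx, te_idx) in enumerate(outer.split(ids)):
        tr_ids, te_ids = ids[tr_idx], ids[te_idx]
        for sid in te_ids:
            fold_of_subject[sid] = fold
        stats = fit_encoder(table, tr_ids)
        X_tr_full = encode_features(table, stats, tr_ids)
        X_te_full = encode_features(table, stats, te_ids)
        for tname, series in targets.items():
            y_tr = series.loc[tr_ids]
            keep = y_tr.notna().to_numpy()
            if keep.sum() < 2 * inner_k:
                continue
            model, cfgd, _ = tune_and_fit(
                X_tr_full.loc[keep], y_tr[keep].to_numpy(),
                grid=grid, inner_k=inner_k, seed=seed + fold,
            )
            chosen[tname].append(cfgd)
            imp_folds[tname].append(
                relative_importances(model, list(X_tr_full.columns)))
            y_te = series.loc[te_ids]
            te_keep = y_te.notna().to_numpy()
            if te_keep.any():
                preds = model.predict(X_te_full.loc[te_keep].to_numpy())
                oof.loc[te_ids[te_keep], tname] = preds

    feat_names = sorted({f for t in targets for d in imp_folds[t] for f in d})
    imp_mean = pd.DataFrame(index=feat_names, columns=list(targets), dtype=float)
    imp_sd = pd.DataFrame(index=feat_names, columns=list(targets), dtype=float)
    for t in targets:
        if imp_folds[t]:
            mat = pd.DataFrame(imp_folds[t]).reindex(columns=feat_names).fillna(0.0)
            imp_mean[t] = mat.mean(axis=0)
            imp_sd[t] = mat.std(axis=0, ddof=0)
    return NestedCVResult(
        fold_of_subject=fold_of_subject, oof_predictions=oof,
        chosen_params=chosen, importances_mean=imp_mean,
        importances_sd=imp_sd, targets=list(targets),
    )
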