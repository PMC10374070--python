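"""The five modeling scenarios and the sequential hybrid combination.

* ``REF_EDES`` — one mechanistic parameter set, fitted on the median
  response of the normoglycemic subjects, simulated for everyone.
* ``REF_GBR`` — per-timepoint gradient boosting predicting glucose and
  insulin directly from phenotype features (nested CV).
* ``HYBRID_I`` — gradient boosting predicts the residuals of
  ``REF_EDES``; the final prediction subtracts the predicted residual
  from the mechanistic one.
* ``PERS_EDES`` — the mechanistic model fitted per subject.
* ``HYBRID_II`` — as ``HYBRID_I`` but on the residuals of ``PERS_EDES``.

The mechanistic simulations are anchored at each subject's own t = 0
measurements (initial values and set-points), so for the personalized
scenarios t = 0 is an input rather than a prediction and is excluded
from the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edes import ModelParameters, SubjectContext
from .fitting import FitConfig, FitResult, OGTTResponse, fit_cohort, fit_individual, median_response
from .metrics import ADAThresholds, classify_glucometabolic, mse_r2_per_timepoint
from .regression import (
    DEFAULT_GRID,
    FeatureTable,
    HyperparameterGrid,
    NestedCVResult,
    nested_cv_predict,
)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "ScenarioResult",
    "SharedArtifacts",
    "mechanistic_predictions",
    "residual_targets",
    "hybrid_combine",
    "run_scenario",
    "run_all_scenarios",
    "measurement_tables",
]

SCENARIOS = ("REF_EDES", "REF_GBR", "HYBRID_I", "PERS_EDES", "HYBRID_II")


@dataclass
class ScenarioConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    grid: HyperparameterGrid = field(default_factory=lambda: DEFAULT_GRID)
    outer_k: int = 5
    inner_k: int = 5
    analytes: tuple[str, ...] = ("glucose", "insulin")
    thresholds: ADAThresholds = field(default_factory=ADAThresholds)


@dataclass
class ScenarioResult:
    scenario: str
    t0_anchored: bool                       # True: t=0 is a supplied input, excluded from metrics
    predictions: dict[str, pd.DataFrame]    # analyte -> wide table (subjects x times)
    mechanistic: dict[str, pd.DataFrame] | None
    predicted_residuals: dict[str, pd.DataFrame] | None
    measurements: dict[str, pd.DataFrame]
    metrics: pd.DataFrame                   # analyte, time_min, mse, r2, n, note
    importances_mean: pd.DataFrame | None = None
    importances_sd: pd.DataFrame | None = None
    n_floored: int = 0                      # negative hybrid outputs clipped to 0
    flagged_subjects: list[str] = field(default_factory=list)


def measurement_tables(responses: list[OGTTResponse]) -> dict[str, pd.DataFrame]:
    """Wide per-analyte measurement tables (index subject, columns minutes)."""
    times = responses[0].times
    idx = pd.Index([r.subject_id for r in responses], name="subject_id")
    g = pd.DataFrame([r.glucose for r in responses], index=idx, columns=times)
    i = pd.DataFrame([r.insulin for r in responses], index=idx, columns=times)
    return {"glucose": g, "insulin": i}


def ngm_reference_fit(responses: list[OGTTResponse], cfg: ScenarioConfig,
                      params0: ModelParameters, ctx: SubjectContext) -> FitResult:
    """Fit the personal parameters on the NGM-median reference curve.

    NGM membership is decided from the measured fasting and 2-h glucose
    with the configured diagnostic thresholds.
    """
    mask = []
    for r in responses:
        try:
            lab = classify_glucometabolic(float(r.glucose[0]), float(r.glucose[-1]),
                                          cfg.thresholds)
        except ValueError:
            lab = None
        mask.append(lab == "NGM")
    if not any(mask):
        raise ValueError("no NGM subjects found for the reference curve")
    med = median_response(responses, mask, subject_id="NGM_MEDIAN")
    return fit_individual(med, cfg.fit, params0, ctx)


def mechanistic_predictions(mode: str, responses: list[OGTTResponse],
                            cfg: ScenarioConfig, params0: ModelParameters,
                            ctx: SubjectContext,
                            ref_fit: FitResult | None = None,
                            pers_fits: list[FitResult] | None = None,
                            ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-subject mechanistic glucose/insulin predictions.

    ``REF_EDES`` simulates every subject with the reference estimates but
    the subject's own t = 0 values as initial values and set-points;
    ``PERS_EDES`` uses each subject's own estimates.  Subjects without a
    usable fit or simulation are flagged and left as NaN rows.
    """
    from .edes import simulate

    times = responses[0].times
    idx = pd.Index([r.subject_id for r in responses], name="subject_id")
    g_pred = pd.DataFrame(np.nan, index=idx, columns=times)
    i_pred = pd.DataFrame(np.nan, index=idx, columns=times)
    flagged: list[str] = []
    if mode == "REF_EDES":
        if ref_fit is None:
            raise ValueError("REF_EDES requires the reference fit")
        p_ref = params0.replace(**ref_fit.estimates)
        for r in responses:
            if np.isnan(r.glucose[0]) or np.isnan(r.insulin[0]):
                flagged.append(r.subject_id)
                continue
            sim = simulate(p_ref, ctx, float(r.glucose[0]), float(r.insulin[0]),
                           times, rtol=cfg.fit.sim_rtol, atol=cfg.fit.sim_atol)
            if not sim.success:
                flagged.append(r.subject_id)
                continue
            g_pred.loc[r.subject_id] = sim.g_traj
            i_pred.loc[r.subject_id] = sim.i_traj
    elif mode == "PERS_EDES":
        if pers_fits is None:
            raise ValueError("PERS_EDES requires per-subject fits")
        by_id = {f.subject_id: f for f in pers_fits}
        for r in responses:
            f = by_id.get(r.subject_id)
            if f is None or not f.estimates or not np.all(np.isfinite(f.pred_glucose)):
                flagged.append(r.subject_id)
                continue
            g_pred.loc[r.subject_id] = f.pred_glucose
            i_pred.loc[r.subject_id] = f.pred_insulin
    else:
        raise ValueError(f"unknown mechanistic mode {mode!r}")
    return {"glucose": g_pred, "insulin": i_pred}, flagged


def residual_targets(predictions: dict[str, pd.DataFrame],
                     measurements: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Residual = prediction - measurement; missing measurements propagate."""
    out = {}
    for analyte, pred in predictions.items():
        meas = measurements[analyte]
        if not pred.index.equals(meas.index):
            raise ValueError("prediction/measurement subject mismatch")
        out[analyte] = pred - meas
    return out


def hybrid_combine(mechanistic: dict[str, pd.DataFrame],
                   predicted_residuals: dict[str, pd.DataFrame],
                   ) -> tuple[dict[str, pd.DataFrame], int]:
    """Final hybrid prediction: mechanistic minus predicted residual.

    Negative concentrations are floored at 0; the count of floored cells
    is returned alongside.
    """
    final = {}
    n_floored = 0
    for analyte, mech in mechanistic.items():
        resid = predicted_residuals[analyte]
        if mech.shape != resid.shape or not mech.index.equals(resid.index):
            raise ValueError("shape mismatch between mechanistic and residual tables")
        f = mech - resid
        neg = (f < 0).to_numpy()
        n_floored += int(np.nansum(neg))
        final[analyte] = f.clip(lower=0.0)
    return final, n_floored


def _targets_from_tables(tables: dict[str, pd.DataFrame], analytes,
                         feature_ids: pd.Index, skip_t0: bool = False
                         ) -> dict[str, pd.Series]:
    targets: dict[str, pd.Series] = {}
    for analyte in analytes:
        tab = tables[analyte].reindex(feature_ids)
        for t in tab.columns:
            if skip_t0 and float(t) == 0.0:
                continue
            targets[f"{analyte}_t{int(t)}"] = tab[t]
    return targets


def _oof_to_tables(cv: NestedCVResult, analytes, times, feature_ids) -> dict[str, pd.DataFrame]:
    out = {}
    for analyte in analytes:
        df = pd.DataFrame(np.nan, index=feature_ids, columns=times)
        for t in times:
            name = f"{analyte}_t{int(t)}"
            if name in cv.oof_predictions.columns:
                df[t] = cv.oof_predictions[name]
        out[analyte] = df
    return out


def _metrics_table(predictions, measurements, analytes, t0_anchored,
                   degenerate_t0: bool = False) -> pd.DataFrame:
    frames = []
    for analyte in analytes:
        m = mse_r2_per_timepoint(predictions[analyte], measurements[analyte],
                                 exclude_t0=t0_anchored)
        m.insert(0, "analyte", analyte)
        if degenerate_t0:
            at_t0 = m["time_min"] == 0.0
            m.loc[at_t0, "note"] = "degenerate: predictions anchored at the measurement"
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SharedArtifacts:
    """Expensive intermediates reusable across scenarios."""

    ref_fit: FitResult | None = None
    pers_fits: list[FitResult] | None = None


def run_scenario(scenario: str, responses: list[OGTTResponse],
                 features: FeatureTable, cfg: ScenarioConfig | None = None,
                 params0: ModelParameters | None = None,
                 ctx: SubjectContext | None = None, seed: int = 0,
                 shared: SharedArtifacts | None = None) -> ScenarioResult:
    """Run one of the five scenarios on an exclusion-filtered cohort.

    ``shared`` caches the reference fit and per-subject fits so that
    running several scenarios does not refit the mechanistic model.
    Regression-based scenarios compute all reported predictions
    out-of-fold under nested CV (no test-fold leakage into encoding,
    tuning or residual models).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cfg = cfg or ScenarioConfig()
    params0 = params0 or ModelParameters()
    ctx = ctx or SubjectContext()
    shared = shared if shared is not None else SharedArtifacts()

    order = [r.subject_id for r in responses]
    feat_ids = features.subject_ids
    if set(order) != set(feat_ids):
        raise ValueError("responses and feature table must cover the same subjects")
    # align responses to the feature table's subject order
    by_id = {r.subject_id: r for r in responses}
    responses = [by_id[s] for s in feat_ids]
    meas = measurement_tables(responses)
    times = responses[0].times
    feature_index = meas["glucose"].index

    def need_ref() -> FitResult:
        if shared.ref_fit is None:
            shared.ref_fit = ngm_reference_fit(responses, cfg, params0, ctx)
        return shared.ref_fit

    def need_pers() -> list[FitResult]:
        if shared.pers_fits is None:
            shared.pers_fits = fit_cohort(responses, cfg.fit, params0, ctx)
        return shared.pers_fits

    if scenario in ("REF_EDES", "PERS_EDES"):
        mech, flagged = mechanistic_predictions(
            scenario, responses, cfg, params0, ctx,
            ref_fit=need_ref() if scenario == "REF_EDES" else None,
            pers_fits=need_pers() if scenario == "PERS_EDES" else None)
        anchored = scenario == "PERS_EDES"
        metrics = _metrics_table(mech, meas, cfg.analytes, anchored,
                                 degenerate_t0=(scenario == "REF_EDES"))
        return ScenarioResult(scenario, anchored, mech, mech, None, meas,
                              metrics, flagged_subjects=flagged)

    if scenario == "REF_GBR":
        targets = _targets_from_tables(meas, cfg.analytes, feature_index)
        cv = nested_cv_predict(features, targets, cfg.outer_k, cfg.inner_k,
                               seed=seed, grid=cfg.grid)
        preds = _oof_to_tables(cv, cfg.analytes, times, feature_index)
        metrics = _metrics_table(preds, meas, cfg.analytes, t0_anchored=False)
        return ScenarioResult(scenario, False, preds, None, None, meas, metrics,
                              importances_mean=cv.importances_mean,
                              importances_sd=cv.importances_sd)

    # hybrid scenarios
    mech_mode = "REF_EDES" if scenario == "HYBRID_I" else "PERS_EDES"
    mech, flagged = mechanistic_predictions(
        mech_mode, responses, cfg, params0, ctx,
        ref_fit=need_ref() if mech_mode == "REF_EDES" else None,
        pers_fits=need_pers() if mech_mode == "PERS_EDES" else None)
    resid = residual_targets(mech, meas)
    # t=0 residuals vanish identically (anchoring), so no model is trained there
    targets = _targets_from_tables(resid, cfg.analytes, feature_index, skip_t0=True)
    cv = nested_cv_predict(features, targets, cfg.outer_k, cfg.inner_k,
                           seed=seed, grid=cfg.grid)
    pred_resid = _oof_to_tables(cv, cfg.analytes, times, feature_index)
    for analyte in cfg.analytes:
        pred_resid[analyte][times[0]] = 0.0
    mech = {a: mech[a] for a in cfg.analytes}
    final, n_floored = hybrid_combine(mech, pred_resid)
    anchored = scenario == "HYBRID_II"
    metrics = _metrics_table(final, meas, cfg.analytes, anchored,
                             degenerate_t0=(scenario == "HYBRID_I"))
    return ScenarioResult(scenario, anchored, final, mech, pred_resid, meas,
                          metrics, importances_mean=cv.importances_mean,
                          importances_sd=cv.importances_sd,
                          n_floored=n_floored, flagged_subjects=flagged)


def run_all_scenarios(responses: list[OGTTResponse], features: FeatureTable,
                      cfg: ScenarioConfig | None = None,
                      params0: ModelParameters | None = None,
                      ctx: SubjectContext | None = None,
                      seed: int = 0) -> dict[str, ScenarioResult]:
    """Run the five scenarios with shared mechanistic fits."""
    shared = SharedArtifacts()
    return {s: run_scenario(s, responses, features, cfg, params0, ctx,
                            seed=seed, shared=shared)
            for s in SCENARIOS}
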