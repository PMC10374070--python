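"""Performance metrics, cohort filters, clinical indices and summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult, OGTTResponse

__all__ = [
    "ADAThresholds",
    "mse_r2_per_timepoint",
    "matsuda_index",
    "classify_glucometabolic",
    "exclusion_filter",
    "parameter_pca",
    "ParameterPCA",
    "MMOL_TO_MGDL",
]

#: mmol/L -> mg/dL conversion for glucose
MMOL_TO_MGDL = 18.016


@dataclass(frozen=True)
class ADAThresholds:
    """Configurable diagnostic cut-points (mmol/L), ADA defaults."""

    ifg_lo: float = 5.6      # fasting glucose floor for IFG
    t2dm_fast: float = 7.0   # fasting glucose for diabetes
    igt_lo: float = 7.8      # 2-h glucose floor for IGT
    t2dm_2h: float = 11.1    # 2-h glucose for diabetes


def mse_r2_per_timepoint(predictions: pd.DataFrame, measurements: pd.DataFrame,
                         exclude_t0: bool = False) -> pd.DataFrame:
    """Per-timepoint MSE and R-squared across subjects.

    Both inputs are wide tables (index: subject_id, columns: timepoints in
    minutes).  R-squared is ``1 - SS_res/SS_tot`` with ``SS_tot`` about the
    measurement mean at that timepoint; it may be negative when the
    predictor is worse than the mean (a sign of mis-specification).
    Cells with fewer than two complete pairs, or zero measurement
    variance, are reported as NaN with a reason.
    """
    if not predictions.index.equals(measurements.index):
        raise ValueError("prediction and measurement tables must share subjects")
    rows = []
    for t in measurements.columns:
        if exclude_t0 and float(t) == 0.0:
            rows.append({"time_min": float(t), "mse": np.nan, "r2": np.nan,
                         "n": 0, "note": "t0 excluded (anchored input)"})
            continue
        y = measurements[t].to_numpy(dtype=float)
        yhat = predictions[t].to_numpy(dtype=float) if t in predictions.columns else np.full_like(y, np.nan)
        ok = ~np.isnan(y) & ~np.isnan(yhat)
        n = int(ok.sum())
        if n < 2:
            rows.append({"time_min": float(t), "mse": np.nan, "r2": np.nan,
                         "n": n, "note": "fewer than 2 complete pairs"})
            continue
        res = yhat[ok] - y[ok]
        mse = float(np.mean(res ** 2))
        ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        if ss_tot == 0:
            rows.append({"time_min": float(t), "mse": mse, "r2": np.nan,
                         "n": n, "note": "zero measurement variance"})
            continue
        r2 = 1.0 - float(np.sum(res ** 2)) / ss_tot
        rows.append({"time_min": float(t), "mse": mse, "r2": r2, "n": n, "note": ""})
    return pd.DataFrame(rows)


def matsuda_index(resp: OGTTResponse) -> float:
    """Whole-body insulin sensitivity index from the OGTT.

    ``10000 / sqrt(G0 * I0 * Gmean * Imean)`` with glucose in mg/dL and
    insulin in mU/L; the means run over all present timepoints.  Returns
    NaN unless both the t = 0 and t = 120 measurements are available.
    """
    i_t0 = 0
    i_2h = int(np.argmin(np.abs(resp.times - 120.0)))
    if resp.times[i_2h] != 120.0:
        raise ValueError("response grid lacks the 120 min timepoint")
    needed = [resp.glucose[i_t0], resp.insulin[i_t0], resp.glucose[i_2h], resp.insulin[i_2h]]
    if any(np.isnan(v) for v in needed):
        return math.nan
    g0 = resp.glucose[0] * MMOL_TO_MGDL
    i0 = resp.insulin[0]
    g_mean = float(np.mean(resp.glucose[resp.glucose_mask])) * MMOL_TO_MGDL
    i_mean = float(np.mean(resp.insulin[resp.insulin_mask]))
    if g0 <= 0 or i0 <= 0 or g_mean <= 0 or i_mean <= 0:
        raise ValueError("Matsuda index requires strictly positive inputs")
    return 10000.0 / math.sqrt(g0 * i0 * g_mean * i_mean)


def classify_glucometabolic(fasting_g: float, two_hour_g: float,
                            thresholds: ADAThresholds = ADAThresholds()) -> str:
    """Glucometabolic class from fasting and 2-h plasma glucose (mmol/L)."""
    th = thresholds
    if fasting_g is None or two_hour_g is None or math.isnan(fasting_g) or math.isnan(two_hour_g):
        raise ValueError("classification requires both fasting and 2-h glucose")
    if fasting_g >= th.t2dm_fast or two_hour_g >= th.t2dm_2h:
        return "T2DM"
    ifg = th.ifg_lo <= fasting_g < th.t2dm_fast
    igt = th.igt_lo <= two_hour_g < th.t2dm_2h
    if ifg and igt:
        return "IFG&IGT"
    if ifg:
        return "IFG"
    if igt:
        return "IGT"
    return "NGM"


def exclusion_filter(responses: Sequence[OGTTResponse], *,
                     max_missing: int = 2, strict: bool = False
                     ) -> tuple[list[OGTTResponse], list[tuple[OGTTResponse, str]]]:
    """Split a cohort into included responses and excluded ones with reasons.

    A subject is excluded if the baseline (t = 0) or 2-h sample is missing
    for either analyte, or if more than ``max_missing`` timepoints have a
    missing sample (``strict=True`` switches to the harsher
    "``max_missing`` or more" reading).  A timepoint counts as missing when
    either analyte is absent there.
    """
    included: list[OGTTResponse] = []
    excluded: list[tuple[OGTTResponse, str]] = []
    for r in responses:
        i_2h = int(np.argmin(np.abs(r.times - 120.0)))
        reasons = []
        if np.isnan(r.glucose[0]) or np.isnan(r.insulin[0]):
            reasons.append("baseline missing")
        if np.isnan(r.glucose[i_2h]) or np.isnan(r.insulin[i_2h]):
            reasons.append("2h post-load missing")
        n_miss = r.n_missing_timepoints()
        if (strict and n_miss >= max_missing) or (not strict and n_miss > max_missing):
            reasons.append(f"{n_miss} missing timepoints")
        if reasons:
            excluded.append((r, "; ".join(reasons)))
        else:
            included.append(r)
    return included, excluded


@dataclass
class ParameterPCA:
    """PCA of the log-standardized personal parameter estimates."""

    subject_ids: list[str]
    parameters: list[str]
    scores: np.ndarray                 # subjects x components
    loadings: np.ndarray               # parameters x components, orthonormal
    explained_variance_ratio: np.ndarray
    standardized: np.ndarray           # the log->z matrix the PCA decomposed


def parameter_pca(fit_results: Sequence[FitResult]) -> ParameterPCA:
    """Log-transform, z-score and decompose the estimated parameter cloud.

    Each estimated parameter is log-transformed and normalized to zero
    mean and unit standard deviation across subjects before a full PCA
    (via SVD of the standardized matrix).
    """
    fits = [f for f in fit_results if f.estimates]
    if len(fits) < 3:
        raise ValueError("parameter PCA needs at least 3 fitted subjects")
    names = sorted(fits[0].estimates)
    mat = np.array([[f.estimates[n] for n in names] for f in fits], dtype=float)
    if np.any(mat <= 0):
        raise ValueError("all estimated parameters must be strictly positive")
    logm = np.log(mat)
    mean = logm.mean(axis=0)
    sd = logm.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"parameter {names[j]!r} has zero across-subject variance")
    z = (logm - mean) / sd
    u, svals, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * svals
    var = svals ** 2
    return ParameterPCA(
        subject_ids=[f.subject_id for f in fits], parameters=names,
        scores=scores, loadings=vt.T,
        explained_variance_ratio=var / var.sum(), standardized=z,
    )
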