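"""Subject-level parameter estimation against 7-point OGTT responses.

A subject's response is fitted by bounded nonlinear least squares on a
small personal parameter subset (default ``{k1, k5, k6, k8}``: gastric
emptying, insulin sensitivity, proportional and derivative insulin
secretion), with every other model constant fixed.  The t = 0 glucose
and insulin measurements are supplied to the simulator as initial values
and set-points, so the model is anchored at the fasting state and t = 0
is an input rather than a prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .edes import (
    OGTT_TIMES,
    ModelParameters,
    SimulationResult,
    SubjectContext,
    simulate,
)

__all__ = [
    "OGTTResponse",
    "FitConfig",
    "FitResult",
    "joint_residuals",
    "fit_individual",
    "fit_cohort",
    "median_response",
]


@dataclass
class OGTTResponse:
    """One subject's timed glucose/insulin measurements.

    Missing samples are stored as NaN; ``glucose_mask``/``insulin_mask``
    report which entries are present.
    """

    subject_id: str
    times: np.ndarray = field(default_factory=lambda: np.array(OGTT_TIMES))
    glucose: np.ndarray = field(default_factory=lambda: np.full(7, np.nan))
    insulin: np.ndarray = field(default_factory=lambda: np.full(7, np.nan))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.subject_id}: times must be strictly increasing")
        if len(self.glucose) != len(self.times) or len(self.insulin) != len(self.times):
            raise ValueError(f"{self.subject_id}: analyte arrays must match times")
        g = self.glucose[~np.isnan(self.glucose)]
        if np.any((g <= 0) | (g >= 50)):
            raise ValueError(f"{self.subject_id}: glucose values must lie in (0, 50) mmol/L")
        i = self.insulin[~np.isnan(self.insulin)]
        if np.any(i < 0):
            raise ValueError(f"{self.subject_id}: insulin values must be nonnegative")

    @property
    def glucose_mask(self) -> np.ndarray:
        """True where glucose is present."""
        return ~np.isnan(self.glucose)

    @property
    def insulin_mask(self) -> np.ndarray:
        return ~np.isnan(self.insulin)

    def n_missing_timepoints(self) -> int:
        """Count of timepoints where either analyte is missing."""
        return int(np.sum(~(self.glucose_mask & self.insulin_mask)))


@dataclass
class FitConfig:
    """Configuration of the per-subject least-squares fit.

    Bounds default to ``[1e-4, 1e2]`` times each parameter's population
    default; optimization runs on log10-parameters, which conditions the
    problem well for rate constants spanning decades.
    """

    params_to_fit: tuple[str, ...] = ("k1", "k5", "k6", "k8")
    bound_factors: tuple[float, float] = (1e-4, 1e2)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weighting: str = "mean_scaled"  # or "unit"
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 400
    n_starts: int = 1
    seed: int = 0
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-10

    def __post_init__(self) -> None:
        valid = {f for f in ModelParameters().to_dict()}
        bad = set(self.params_to_fit) - valid
        if bad:
            raise ValueError(f"unknown parameters to fit: {sorted(bad)}")
        if self.weighting not in ("mean_scaled", "unit"):
            raise ValueError(f"unknown weighting scheme {self.weighting!r}")
        lo, hi = self.bound_factors
        if not (0 < lo < hi):
            raise ValueError("bound_factors must satisfy 0 < lo < hi")

    def bounds_for(self, name: str, default: float) -> tuple[float, float]:
        if name in self.bounds:
            lo, hi = self.bounds[name]
        else:
            lo, hi = self.bound_factors[0] * default, self.bound_factors[1] * default
        if not (0 < lo < hi) or not math.isfinite(hi):
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        return lo, hi


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    subject_id: str
    estimates: dict[str, float]
    ssr: float
    residuals_glucose: np.ndarray   # prediction - measurement, mmol/L (NaN if missing)
    residuals_insulin: np.ndarray   # mU/L
    n_obs: int
    converged: bool
    n_iter: int
    pred_glucose: np.ndarray
    pred_insulin: np.ndarray
    message: str = ""


def _scales(resp: OGTTResponse, weighting: str) -> tuple[float, float]:
    if weighting == "unit":
        return 1.0, 1.0
    gm, im = resp.glucose_mask, resp.insulin_mask
    if not gm.any():
        raise ValueError(f"{resp.subject_id}: all glucose values missing")
    if not im.any():
        raise ValueError(f"{resp.subject_id}: all insulin values missing")
    return float(np.mean(resp.glucose[gm])), float(np.mean(resp.insulin[im]))


def joint_residuals(sim: SimulationResult, resp: OGTTResponse,
                    weighting: str = "mean_scaled") -> np.ndarray:
    """Weighted residual vector (glucose entries first, then insulin).

    Each entry is ``(prediction - measurement) / scale`` where the scale is
    the subject's mean of the present values for that analyte, so the two
    analytes (differing by an order of magnitude in units) contribute
    comparably to the SSR.  Missing measurements are skipped.
    """
    if len(sim.times) != len(resp.times) or np.any(sim.times != resp.times):
        raise ValueError("simulation not evaluated at the response times")
    sg, si = _scales(resp, weighting)
    gm, im = resp.glucose_mask, resp.insulin_mask
    rg = (sim.g_traj[gm] - resp.glucose[gm]) / sg
    ri = (sim.i_traj[im] - resp.insulin[im]) / si
    return np.concatenate([rg, ri])


def _make_objective(resp, cfg, params0, ctx, names, g0, i0):
    lo = np.array([math.log10(cfg.bounds_for(n, getattr(params0, n))[0]) for n in names])
    hi = np.array([math.log10(cfg.bounds_for(n, getattr(params0, n))[1]) for n in names])
    n_res = int(resp.glucose_mask.sum() + resp.insulin_mask.sum())

    def fun(x_log: np.ndarray) -> np.ndarray:
        p = params0.replace(**{n: 10.0 ** v for n, v in zip(names, x_log)})
        sim = simulate(p, ctx, g0, i0, resp.times, rtol=cfg.sim_rtol, atol=cfg.sim_atol)
        if not sim.success:
            return np.full(n_res, 1e6)
        return joint_residuals(sim, resp, cfg.weighting)

    return fun, lo, hi


def fit_individual(resp: OGTTResponse, cfg: FitConfig, params0: ModelParameters,
                   ctx: SubjectContext) -> FitResult:
    """Estimate ``cfg.params_to_fit`` for one subject by bounded least squares.

    Requires the t = 0 glucose and insulin measurements (used as initial
    values and set-points).  The returned SSR never exceeds the SSR at the
    initial guess; if the solver fails to improve, the initial guess is
    returned with ``converged=False``.
    """
    if np.isnan(resp.glucose[0]) or np.isnan(resp.insulin[0]):
        raise ValueError(f"{resp.subject_id}: t=0 glucose and insulin are required")
    g0, i0 = float(resp.glucose[0]), float(resp.insulin[0])
    names = list(cfg.params_to_fit)
    fun, lo, hi = _make_objective(resp, cfg, params0, ctx, names, g0, i0)

    x0 = np.array([math.log10(getattr(params0, n)) for n in names])
    x0 = np.clip(x0, lo, hi)
    r0 = fun(x0)
    ssr0 = float(r0 @ r0)

    starts = [x0]
    if cfg.n_starts > 1:
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_starts - 1):
            starts.append(rng.uniform(lo, hi))

    best_x, best_ssr, best_nit, ok, msg = x0, ssr0, 0, False, "no improvement over initial guess"
    for xs in starts:
        try:
            sol = least_squares(fun, xs, bounds=(lo, hi), method="trf",
                                xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol,
                                max_nfev=cfg.max_nfev)
        except Exception as exc:
            msg = str(exc)
            continue
        ssr = float(2 * sol.cost)
        if ssr <= best_ssr:
            best_x, best_ssr, best_nit = sol.x, ssr, int(sol.nfev)
            ok, msg = bool(sol.status > 0), sol.message

    estimates = {n: float(10.0 ** v) for n, v in zip(names, best_x)}
    p_hat = params0.replace(**estimates)
    sim = simulate(p_hat, ctx, g0, i0, resp.times, rtol=cfg.sim_rtol, atol=cfg.sim_atol)
    res_g = np.where(resp.glucose_mask, sim.g_traj - resp.glucose, np.nan)
    res_i = np.where(resp.insulin_mask, sim.i_traj - resp.insulin, np.nan)
    n_obs = int(resp.glucose_mask.sum() + resp.insulin_mask.sum())
    return FitResult(
        subject_id=resp.subject_id, estimates=estimates, ssr=best_ssr,
        residuals_glucose=res_g, residuals_insulin=res_i, n_obs=n_obs,
        converged=ok, n_iter=best_nit,
        pred_glucose=sim.g_traj.copy(), pred_insulin=sim.i_traj.copy(),
        message=str(msg),
    )


def fit_cohort(responses: Iterable[OGTTResponse], cfg: FitConfig,
               params0: ModelParameters, ctx: SubjectContext) -> list[FitResult]:
    """Independent per-subject fits; failures are collected, not raised.

    A subject whose fit raises (e.g. missing t = 0) yields a FitResult with
    ``converged=False``, NaN predictions and the error message.
    """
    out: list[FitResult] = []
    for resp in responses:
        try:
            out.append(fit_individual(resp, cfg, params0, ctx))
        except Exception as exc:
            n = len(resp.times)
            out.append(FitResult(
                subject_id=resp.subject_id, estimates={}, ssr=math.inf,
                residuals_glucose=np.full(n, np.nan),
                residuals_insulin=np.full(n, np.nan),
                n_obs=0, converged=False, n_iter=0,
                pred_glucose=np.full(n, np.nan), pred_insulin=np.full(n, np.nan),
                message=str(exc),
            ))
    return out


def median_response(responses: Sequence[OGTTResponse],
                    group_mask: Sequence[bool] | None = None,
                    subject_id: str = "MEDIAN") -> OGTTResponse:
    """Per-timepoint, per-analyte median over the present values of a group.

    This builds the population reference curve (e.g. the median response
    across normoglycemic subjects).
    """
    if group_mask is not None:
        responses = [r for r, keep in zip(responses, group_mask) if keep]
    responses = list(responses)
    if not responses:
        raise ValueError("median_response: empty selection")
    times = responses[0].times
    for r in responses[1:]:
        if len(r.times) != len(times) or np.any(r.times != times):
            raise ValueError("median_response: inconsistent time grids")
    g = np.vstack([r.glucose for r in responses])
    i = np.vstack([r.insulin for r in responses])
    with np.errstate(all="ignore"):
        g_med = np.nanmedian(g, axis=0)
        i_med = np.nanmedian(i, axis=0)
    return OGTTResponse(subject_id=subject_id, times=times.copy(),
                        glucose=g_med, insulin=i_med)
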