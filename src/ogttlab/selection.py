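"""Parsimonious-model workflow: sensitivity, AIC selection, identifiability.

The workflow reduces the set of personal parameters to one that is
sensitive, parsimonious and identifiable from a 7-point OGTT:

1. local parameter sensitivity analysis (LPSA) ranks candidate
   parameters by the relative change they induce in the simulated
   glucose/insulin outputs;
2. all subsets of size >= 3 of the sensitive candidates are fitted on a
   set of representative curves spanning the glucometabolic spectrum;
3. the subset with the lowest aggregate Akaike Information Criterion
   (least-squares form, AIC = n ln(SSR/n) + 2k) wins;
4. profile likelihood analysis (PLA) checks each winning parameter for
   practical identifiability: the parameter is fixed on a grid, the
   remaining ones re-optimized, and the profile must cross the
   chi-square threshold on both sides of the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .archetypes import CLASS_ARCHETYPES, CLASS_ORDER
from .edes import ModelParameters, OGTT_TIMES, SubjectContext, simulate
from .fitting import FitConfig, FitResult, OGTTResponse, fit_individual

__all__ = [
    "SensitivityReport",
    "CandidateModel",
    "SelectionResult",
    "ProfileLikelihood",
    "local_sensitivity",
    "candidate_sets",
    "representative_curves",
    "aic_score",
    "select_parsimonious",
    "profile_likelihood",
    "DEFAULT_LPSA_CANDIDATES",
]

#: parameters screened by the sensitivity analysis by default
DEFAULT_LPSA_CANDIDATES = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10", "u_b", "c1",
)


@dataclass
class SensitivityReport:
    scores: dict[str, float]
    rel_perturbation: float
    ranking: list[str]                  # descending score, ties alphabetical
    selected_sensitive: list[str]       # top-k above the cutoff
    failed: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CandidateModel:
    subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subset) < 3:
            raise ValueError("candidate subsets must have size >= 3")


@dataclass
class SelectionResult:
    candidates: list[CandidateModel]
    curve_ids: list[str]
    aic_matrix: np.ndarray              # candidates x curves
    ssr_matrix: np.ndarray
    aggregate_aic: np.ndarray
    winner: CandidateModel
    failures: list[tuple[int, int, str]] = field(default_factory=list)


@dataclass
class ProfileLikelihood:
    parameter: str
    grid: np.ndarray
    ssr: np.ndarray
    profile: np.ndarray                 # chi-square-scaled excess over the minimum
    threshold: float
    verdict: str                        # identifiable | practically_non_identifiable | structurally_non_identifiable
    crosses_left: bool
    crosses_right: bool
    failed_points: list[int] = field(default_factory=list)


def local_sensitivity(params: ModelParameters, ctx: SubjectContext,
                      archetype: OGTTResponse, rel_perturbation: float = 0.05,
                      candidates: Sequence[str] = DEFAULT_LPSA_CANDIDATES,
                      top_k: int = 6) -> SensitivityReport:
    """Central-difference local sensitivity of the simulated OGTT outputs.

    For each candidate parameter p the score is the mean over the 14
    outputs (glucose and insulin at the 7 sampling times) of
    ``|y(p(1+d)) - y(p(1-d))| / |y(p)| / (2d)`` — the mean absolute
    relative output change per unit relative parameter change.  The
    relative formulation makes scores invariant to output unit rescaling.
    """
    if not (0 < rel_perturbation <= 0.5):
        raise ValueError("rel_perturbation must lie in (0, 0.5]")
    if np.isnan(archetype.glucose).any() or np.isnan(archetype.insulin).any():
        raise ValueError("archetype response must be complete (no missing values)")
    g0, i0 = float(archetype.glucose[0]), float(archetype.insulin[0])
    base = simulate(params, ctx, g0, i0, archetype.times)
    if not base.success:
        raise RuntimeError("baseline simulation failed")
    y0 = np.concatenate([base.g_traj, base.i_traj])

    scores: dict[str, float] = {}
    failed: list[str] = []
    for name in candidates:
        v = getattr(params, name)
        if v == 0:
            scores[name] = 0.0
            continue
        hi = simulate(params.replace(**{name: v * (1 + rel_perturbation)}), ctx,
                      g0, i0, archetype.times)
        lo = simulate(params.replace(**{name: v * (1 - rel_perturbation)}), ctx,
                      g0, i0, archetype.times)
        if not (hi.success and lo.success):
            failed.append(name)
            continue
        y_hi = np.concatenate([hi.g_traj, hi.i_traj])
        y_lo = np.concatenate([lo.g_traj, lo.i_traj])
        scores[name] = float(np.mean(np.abs(y_hi - y_lo) / np.abs(y0)) / (2 * rel_perturbation))

    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    return SensitivityReport(
        scores=scores, rel_perturbation=rel_perturbation, ranking=ranking,
        selected_sensitive=ranking[:top_k], failed=failed,
    )


def candidate_sets(sensitive: Sequence[str], min_size: int = 3) -> list[CandidateModel]:
    """All subsets of the sensitive parameters with size >= ``min_size``.

    Deterministic order: by size, then lexicographically.
    """
    names = sorted(sensitive)
    if len(names) < min_size:
        raise ValueError(f"need at least {min_size} sensitive parameters, got {len(names)}")
    out = []
    for size in range(min_size, len(names) + 1):
        for combo in combinations(names, size):
            out.append(CandidateModel(subset=combo))
    return out


def glucose_auc(resp: OGTTResponse) -> float:
    """Trapezoidal area under the glucose curve (present values only)."""
    m = resp.glucose_mask
    if m.sum() < 2:
        raise ValueError(f"{resp.subject_id}: need >= 2 glucose values for AUC")
    return float(np.trapezoid(resp.glucose[m], resp.times[m]))


def representative_curves(cohort: Sequence[OGTTResponse],
                          params0: ModelParameters | None = None,
                          ctx: SubjectContext | None = None) -> list[OGTTResponse]:
    """Seven representative responses spanning the glucometabolic spectrum.

    One noiseless archetype per class (NGM, IFG, IGT, IFG&IGT, T2DM),
    simulated from the class's median parameters and basal values, plus
    the cohort's minimal and maximal responses by trapezoidal glucose AUC.
    """
    ctx = ctx or SubjectContext()
    params0 = params0 or ModelParameters()
    curves: list[OGTTResponse] = []
    times = np.array(OGTT_TIMES)
    for label in CLASS_ORDER:
        arch = CLASS_ARCHETYPES[label]
        p = params0.replace(**arch.median_params())
        g0 = arch.basal_glucose[0]
        i0 = arch.basal_insulin[0]
        sim = simulate(p, ctx, g0, i0, times)
        if not sim.success:
            raise RuntimeError(f"archetype simulation failed for {label}")
        curves.append(OGTTResponse(subject_id=f"ARCH_{label}", times=times,
                                   glucose=sim.g_traj, insulin=sim.i_traj))
    complete = [r for r in cohort if r.glucose_mask.sum() >= 2]
    if len(complete) < 2:
        raise ValueError("cohort mode requires >= 2 subjects with glucose curves")
    aucs = [glucose_auc(r) for r in complete]
    lo = complete[int(np.argmin(aucs))]
    hi = complete[int(np.argmax(aucs))]
    curves.append(OGTTResponse(subject_id=f"MIN_{lo.subject_id}", times=lo.times.copy(),
                               glucose=lo.glucose.copy(), insulin=lo.insulin.copy()))
    curves.append(OGTTResponse(subject_id=f"MAX_{hi.subject_id}", times=hi.times.copy(),
                               glucose=hi.glucose.copy(), insulin=hi.insulin.copy()))
    return curves


def aic_score(ssr: float, n_obs: int, n_params: int) -> float:
    """Least-squares AIC: ``n_obs * ln(ssr/n_obs) + 2 * n_params``."""
    if n_obs <= n_params or n_params < 1:
        raise ValueError("require n_obs > n_params >= 1")
    if ssr < 0:
        raise ValueError("ssr must be nonnegative")
    if ssr == 0:
        warnings.warn("AIC of a perfect fit (ssr=0) is -inf", RuntimeWarning)
        return -math.inf
    return n_obs * math.log(ssr / n_obs) + 2 * n_params


def select_parsimonious(candidates: Sequence[CandidateModel],
                        curves: Sequence[OGTTResponse],
                        cfg: FitConfig, params0: ModelParameters,
                        ctx: SubjectContext) -> SelectionResult:
    """Fit every candidate subset on every representative curve; pick the
    lowest aggregate (summed) AIC.  Ties go to the smaller subset, then
    lexicographic order.  Candidates with any failed cell cannot win.
    """
    if not candidates or not curves:
        raise ValueError("need at least one candidate and one curve")
    cands = sorted(candidates, key=lambda c: (len(c.subset), c.subset))
    aic = np.full((len(cands), len(curves)), np.nan)
    ssr = np.full_like(aic, np.nan)
    failures: list[tuple[int, int, str]] = []
    for i, cand in enumerate(cands):
        sub_cfg = FitConfig(**{**cfg.__dict__, "params_to_fit": cand.subset})
        for j, curve in enumerate(curves):
            try:
                fr = fit_individual(curve, sub_cfg, params0, ctx)
                if not math.isfinite(fr.ssr):
                    raise RuntimeError(fr.message or "non-finite SSR")
                ssr[i, j] = fr.ssr
                aic[i, j] = aic_score(max(fr.ssr, 1e-300), fr.n_obs, len(cand.subset))
            except Exception as exc:
                failures.append((i, j, str(exc)))
    aggregate = aic.sum(axis=1)
    eligible = [i for i in range(len(cands)) if np.isfinite(aic[i]).all()]
    if not eligible:
        raise RuntimeError("every candidate had at least one failed fit")
    winner_idx = min(eligible, key=lambda i: (aggregate[i], len(cands[i].subset), cands[i].subset))
    return SelectionResult(
        candidates=list(cands), curve_ids=[c.subject_id for c in curves],
        aic_matrix=aic, ssr_matrix=ssr, aggregate_aic=aggregate,
        winner=cands[winner_idx], failures=failures,
    )


def profile_likelihood(resp: OGTTResponse, fit: FitResult, param: str,
                       cfg: FitConfig, params0: ModelParameters,
                       ctx: SubjectContext, *, n_points: int = 41,
                       span_decades: float = 1.0,
                       threshold: float | None = None,
                       flat_tol: float = 0.5,
                       sigma2_floor: float = 1e-12) -> ProfileLikelihood:
    """Profile-likelihood identifiability of one fitted parameter.

    The parameter is fixed on a log-spaced grid spanning
    ``span_decades`` decades either side of its estimate; the remaining
    fitted parameters are re-optimized at each grid point (warm-started
    from the neighbouring point).  The SSR profile is scaled by
    ``sigma^2 = ssr_min / (n_obs - n_params)`` so that the default
    threshold — the 95% chi-square quantile with 1 dof, 3.84 — marks a
    pointwise confidence bound.  ``sigma2_floor`` guards the scaling when
    the fit is numerically perfect (noiseless data).

    Verdicts: ``identifiable`` if the scaled profile crosses the
    threshold on both sides; ``structurally_non_identifiable`` if the
    profile stays within ``flat_tol`` of the minimum everywhere (flat);
    otherwise ``practically_non_identifiable``.
    """
    if param not in fit.estimates:
        raise ValueError(f"{param!r} was not estimated in the supplied fit")
    if threshold is None:
        threshold = float(chi2.ppf(0.95, 1))  # 3.8415
    others = tuple(n for n in fit.estimates if n != param)
    center = fit.estimates[param]
    grid = np.logspace(math.log10(center) - span_decades,
                       math.log10(center) + span_decades, n_points)
    g0, i0 = float(resp.glucose[0]), float(resp.insulin[0])

    def profiled_ssr(value: float, warm: dict[str, float]) -> tuple[float, dict[str, float]]:
        fixed = params0.replace(**{**fit.estimates, param: value})
        if not others:
            from .edes import simulate as _sim
            sim = _sim(fixed, ctx, g0, i0, resp.times,
                       rtol=cfg.sim_rtol, atol=cfg.sim_atol)
            if not sim.success:
                raise RuntimeError("simulation failed")
            from .fitting import joint_residuals
            r = joint_residuals(sim, resp, cfg.weighting)
            return float(r @ r), {}
        start = fixed.replace(**warm)
        sub_cfg = FitConfig(**{**cfg.__dict__, "params_to_fit": others})
        fr = fit_individual(resp, sub_cfg, start, ctx)
        return fr.ssr, fr.estimates

    ssr_prof = np.full(n_points, np.nan)
    failed: list[int] = []
    mid = n_points // 2
    order = list(range(mid, n_points)) + list(range(mid - 1, -1, -1))
    warm_right = {n: fit.estimates[n] for n in others}
    warm_left = dict(warm_right)
    for idx in order:
        warm = warm_right if idx >= mid else warm_left
        try:
            s, est = profiled_ssr(float(grid[idx]), warm)
            ssr_prof[idx] = s
            if others:
                if idx >= mid:
                    warm_right = est
                else:
                    warm_left = est
        except Exception:
            failed.append(idx)

    valid = np.isfinite(ssr_prof)
    if not valid.any():
        raise RuntimeError("profile failed at every grid point")
    ssr_min = min(float(np.nanmin(ssr_prof)), fit.ssr)
    dof = max(fit.n_obs - len(fit.estimates), 1)
    sigma2 = max(ssr_min / dof, sigma2_floor)
    profile = (ssr_prof - ssr_min) / sigma2

    argmin = int(np.nanargmin(ssr_prof))
    left = profile[: argmin + 1]
    right = profile[argmin:]
    crosses_left = bool(np.nanmax(left) >= threshold) if len(left) else False
    crosses_right = bool(np.nanmax(right) >= threshold) if len(right) else False
    if crosses_left and crosses_right:
        verdict = "identifiable"
    elif float(np.nanmax(profile)) < flat_tol:
        verdict = "structurally_non_identifiable"
    else:
        verdict = "practically_non_identifiable"
    return ProfileLikelihood(
        parameter=param, grid=grid, ssr=ssr_prof, profile=profile,
        threshold=threshold, verdict=verdict,
        crosses_left=crosses_left, crosses_right=crosses_right,
        failed_points=failed,
    )
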