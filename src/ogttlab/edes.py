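"""Compartmental glucose-insulin model of the postprandial OGTT response.

The model tracks an oral glucose bolus through a gut compartment into
plasma, where glucose is cleared by insulin-independent uptake,
insulin-dependent uptake, hepatic balance and (above a renal threshold)
urinary excretion.  Pancreatic insulin secretion responds to the glucose
excursion through proportional, integral and derivative terms — a
PID-style controller around the basal set-points ``g_b`` (Gbpl) and
``i_b`` (Ibpl).  Units are fixed throughout: minutes, mmol/L for glucose,
mU/L for insulin.

State vector: ``(m_gut, g, z, i, q)`` where ``m_gut`` is glucose mass in
the gut [mmol], ``g`` plasma glucose [mmol/L], ``z`` the integral of
``g - g_b`` [mmol.min/L], ``i`` plasma insulin [mU/L] and ``q`` remote
(interstitial) insulin [mU/L].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "SubjectContext",
    "ModelParameters",
    "SimulationResult",
    "meal_appearance_rate",
    "derive_basal_production",
    "system_rhs",
    "simulate",
    "GLUCOSE_MOLAR_MASS",
    "standard_dose_mmol",
    "OGTT_TIMES",
]

#: molar mass of glucose, g/mol
GLUCOSE_MOLAR_MASS = 180.16

#: the 7-point OGTT sampling grid, minutes
OGTT_TIMES = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)


def standard_dose_mmol(grams: float = 75.0) -> float:
    """Glucose load in mmol for a given oral dose in grams (default 75 g)."""
    return grams * 1000.0 / GLUCOSE_MOLAR_MASS


@dataclass(frozen=True)
class SubjectContext:
    """Physiological context of one subject taking the glucose drink.

    Parameters
    ----------
    dose : float
        Oral glucose load, mmol.  75 g corresponds to ~416.3 mmol.
    body_weight : float
        Body weight, kg.
    bioavailability_f : float
        Fraction of the dose reaching plasma, in (0, 1].
    v_g : float
        Glucose distribution volume per kg body weight, L/kg.
    """

    dose: float = field(default_factory=standard_dose_mmol)
    body_weight: float = 75.0
    bioavailability_f: float = 1.0
    v_g: float = 0.25

    def __post_init__(self) -> None:
        for name in ("dose", "body_weight", "bioavailability_f", "v_g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                if name == "dose" and v == 0:
                    continue  # dose 0 = fasted simulation, allowed
                raise ValueError(f"SubjectContext.{name} must be positive, got {v!r}")
        if self.bioavailability_f > 1:
            raise ValueError("bioavailability_f must be <= 1")

    @property
    def distribution_volume(self) -> float:
        """Total glucose distribution volume, L."""
        return self.v_g * self.body_weight


# Parameter names that may be estimated per subject in the parsimonious model.
PERSONAL_PARAMS = ("k1", "k5", "k6", "k8")


@dataclass
class ModelParameters:
    """Rate constants, set-points and physiological constants of the model.

    Defaults describe a normoglycemic (NGM) archetype calibrated so that a
    75 g load peaks at ~7-9 mmol/L glucose between 30 and 60 min and
    returns toward baseline by 120 min.  ``egp_b`` (basal endogenous
    glucose production) is derived from the steady-state closure, see
    :func:`derive_basal_production`.
    """

    k1: float = 0.015       # gastric-emptying rate, 1/min
    sigma: float = 1.34     # gastric-emptying shape (Weibull), dimensionless
    k2: float = 0.28        # gut absorption rate, 1/min
    k3: float = 0.005       # glucose-dependent hepatic suppression, 1/min
    k4: float = 1e-4        # insulin-dependent hepatic suppression, mmol/(mU.min)
    k5: float = 0.02        # insulin-dependent tissue uptake, mmol/(mU.min)
    k6: float = 0.5         # proportional insulin secretion, mU/(mmol.min)
    k7: float = 0.05        # integral insulin secretion, mU/(mmol.min)
    k8: float = 4.0         # derivative insulin secretion, mU/mmol (with tau_d)
    k9: float = 0.05        # plasma insulin clearance, 1/min
    k10: float = 0.05       # plasma<->remote insulin exchange, 1/min
    u_b: float = 0.04       # basal non-insulin-dependent uptake, mmol/(L.min)
    k_m: float = 13.2       # Michaelis constant, mmol/L
    g_th: float = 9.0       # renal glucose threshold, mmol/L
    c1: float = 0.05        # renal clearance coefficient, L/min
    tau_i: float = 31.0     # integral time constant, min
    tau_d: float = 3.0      # derivative time constant, min
    beta: float = 1.0       # pancreatic responsiveness scale, dimensionless
    g_b: float = 5.0        # basal plasma glucose set-point (Gbpl), mmol/L
    i_b: float = 10.0       # basal plasma insulin set-point (Ibpl), mU/L
    egp_b: float | None = None  # basal endogenous glucose production, mmol/(L.min)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "egp_b":
                if v is not None and (not np.isfinite(v) or v < 0):
                    raise ValueError(f"egp_b must be nonnegative, got {v!r}")
                continue
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"ModelParameters.{f.name} must be a nonnegative finite number, got {v!r}")
        if self.k_m <= 0:
            raise ValueError("k_m must be strictly positive")
        if self.tau_i <= 0:
            raise ValueError("tau_i must be strictly positive")

    def replace(self, **updates: float) -> "ModelParameters":
        """Return a copy with some fields replaced (re-validated)."""
        return replace(self, **updates)

    def with_basal(self, g_b: float, i_b: float) -> "ModelParameters":
        """Re-anchor the set-points and re-derive ``egp_b`` accordingly."""
        p = self.replace(g_b=g_b, i_b=i_b, egp_b=None)
        p.egp_b = derive_basal_production(p)
        return p

    # --- flat-JSON serialization -------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


@dataclass
class SimulationResult:
    """Trajectory of one simulated OGTT.

    ``fluxes`` breaks the plasma-glucose balance into its pathways at each
    requested time (all in mmol/(L.min) except ``secretion``, mU/(L.min)).
    """

    times: np.ndarray
    states: np.ndarray          # shape (n_times, 5): m_gut, g, z, i, q
    fluxes: dict[str, np.ndarray]
    success: bool
    message: str = ""

    @property
    def g_traj(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def i_traj(self) -> np.ndarray:
        return self.states[:, 3]


def meal_appearance_rate(t, k1: float, sigma: float, dose: float):
    """Rate of glucose appearance in the gut, mmol/min.

    Weibull-shaped gastric emptying:
    ``m(t) = dose * sigma * k1**sigma * t**(sigma-1) * exp(-(k1*t)**sigma)``,
    which integrates to ``dose`` over [0, inf).  ``sigma = 1`` recovers
    first-order (exponential) emptying; ``sigma > 1`` delays the peak.
    """
    if k1 <= 0 or sigma <= 0:
        raise ValueError("k1 and sigma must be strictly positive")
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = dose * sigma * k1**sigma * t_arr ** (sigma - 1.0) * np.exp(-((k1 * t_arr) ** sigma))
    # t=0 limit: 0 for sigma>1, dose*k1 for sigma==1, +inf for sigma<1
    if sigma == 1.0:
        out = np.where(t_arr == 0, dose * k1, out)
    elif sigma > 1.0:
        out = np.where(t_arr == 0, 0.0, out)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def derive_basal_production(params: ModelParameters) -> float:
    """Basal endogenous glucose production closing the basal steady state.

    ``egp_b = u_b + i_b*(k4 + k5*g_b/(k_m + g_b))`` — with this value and
    no meal, ``(m_gut=0, g=g_b, z=0, i=i_b, q=i_b)`` is an equilibrium of
    the system (at basal glucose the normalized non-insulin uptake term
    equals ``u_b`` and renal excretion is inactive for ``g_b < g_th``).
    """
    p = params
    return p.u_b + p.i_b * (p.k4 + p.k5 * p.g_b / (p.k_m + p.g_b))


def _rhs_scalar(y, t, k1, sigma, k2, k3, k4, k5, k6, k7, k8, k9, k10, u_b,
                k_m, g_th, c1, tau_i, tau_d, beta, g_b, i_b, egp_b,
                dose, f, v):
    # hot path: plain-float arithmetic, called thousands of times per fit
    m_gut, g, z, i, q = y
    if dose > 0.0 and t > 0.0:
        appear = dose * sigma * k1**sigma * t ** (sigma - 1.0) * math.exp(-((k1 * t) ** sigma))
    else:
        appear = 0.0
    dm_gut = appear - k2 * m_gut
    gut_in = f * k2 * m_gut / v
    hepatic = egp_b - k3 * (g - g_b) - k4 * q
    # non-insulin-dependent uptake, normalized so it equals u_b at basal glucose
    ni_uptake = u_b * (g / (k_m + g)) / (g_b / (k_m + g_b))
    ins_uptake = k5 * q * g / (k_m + g)
    renal = c1 * (g - g_th) / v if g > g_th else 0.0
    dg = gut_in + hepatic - ni_uptake - ins_uptake - renal
    dz = g - g_b
    secretion = beta * (k6 * (g - g_b) + (k7 / tau_i) * z + k8 * tau_d * dg)
    if secretion < 0.0:
        secretion = 0.0  # no negative pancreatic output
    di = secretion - k9 * (i - i_b) - k10 * (i - q)
    dq = k10 * (i - q)
    return [dm_gut, dg, dz, di, dq]


def _rhs_args(p: ModelParameters, ctx: SubjectContext, egp_b: float) -> tuple:
    return (p.k1, p.sigma, p.k2, p.k3, p.k4, p.k5, p.k6, p.k7, p.k8, p.k9,
            p.k10, p.u_b, p.k_m, p.g_th, p.c1, p.tau_i, p.tau_d, p.beta,
            p.g_b, p.i_b, egp_b, ctx.dose, ctx.bioavailability_f,
            ctx.distribution_volume)


def _rhs(t: float, y: np.ndarray, p: ModelParameters, ctx: SubjectContext, egp_b: float) -> np.ndarray:
    return np.array(_rhs_scalar(y, t, *_rhs_args(p, ctx, egp_b)))


def system_rhs(state: Sequence[float], t: float, params: ModelParameters,
               ctx: SubjectContext) -> np.ndarray:
    """Time derivative of the model state ``(m_gut, g, z, i, q)``.

    ``egp_b`` is taken from ``params`` if set, else derived on the fly.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    egp_b = params.egp_b if params.egp_b is not None else derive_basal_production(params)
    return _rhs(float(t), y, params, ctx, egp_b)


def _flux_breakdown(times: np.ndarray, states: np.ndarray, p: ModelParameters,
                    ctx: SubjectContext, egp_b: float) -> dict[str, np.ndarray]:
    m_gut, g, z = states[:, 0], states[:, 1], states[:, 2]
    q = states[:, 4]
    v = ctx.distribution_volume
    appear = np.array([
        meal_appearance_rate(t, p.k1, p.sigma, ctx.dose) if ctx.dose > 0 else 0.0
        for t in times
    ])
    gut_in = ctx.bioavailability_f * p.k2 * m_gut / v
    hepatic = egp_b - p.k3 * (g - p.g_b) - p.k4 * q
    ni_uptake = p.u_b * (g / (p.k_m + g)) / (p.g_b / (p.k_m + p.g_b))
    ins_uptake = p.k5 * q * g / (p.k_m + g)
    renal = np.where(g > p.g_th, p.c1 * (g - p.g_th) / v, 0.0)
    dg = gut_in + hepatic - ni_uptake - ins_uptake - renal
    secretion = np.maximum(
        0.0, p.beta * (p.k6 * (g - p.g_b) + (p.k7 / p.tau_i) * z + p.k8 * p.tau_d * dg)
    )
    return {
        "gut_appearance": gut_in,
        "hepatic": hepatic,
        "non_insulin_uptake": ni_uptake,
        "insulin_uptake": ins_uptake,
        "renal": renal,
        "secretion": secretion,
    }


def simulate(params: ModelParameters, ctx: SubjectContext, g0: float, i0: float,
             times: Sequence[float], *, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimulationResult:
    """Integrate the model from the subject's fasting state.

    The t = 0 glucose and insulin measurements serve both as initial
    values and as the set-points ``g_b``/``i_b`` (the model is anchored at
    the fasting state); ``egp_b`` is re-derived accordingly.  Integration
    uses a stiff-capable adaptive method (LSODA).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    if g0 <= 0 or i0 <= 0:
        raise ValueError("g0 and i0 must be strictly positive")
    p = params.with_basal(g0, i0)
    egp_b = p.egp_b
    y0 = [0.0, g0, 0.0, i0, i0]
    try:
        states, info = odeint(
            _rhs_scalar, y0, times, args=_rhs_args(p, ctx, egp_b),
            rtol=rtol, atol=atol, full_output=True, printmessg=False,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return SimulationResult(times, np.full((len(times), 5), np.nan), {},
                                success=False, message=str(exc))
    if info["message"] != "Integration successful." or not np.all(np.isfinite(states)):
        return SimulationResult(times, np.full((len(times), 5), np.nan), {},
                                success=False, message=str(info["message"]))
    fluxes = _flux_breakdown(times, states, p, ctx, egp_b)
    return SimulationResult(times, states, fluxes, success=True)
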