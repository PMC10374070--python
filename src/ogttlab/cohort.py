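"""Synthetic OGTT cohort generator with known ground truth.

The study cohort this package is designed around is an observational
population and is not publicly deposited, so every pipeline stage is
exercised on generated cohorts instead: each subject draws a
glucometabolic class, class-conditional personal parameters
``{k1, k5, k6, k8}`` (log-normal) and basal glucose/insulin (truncated
normal inside the class's diagnostic band), is simulated noiselessly on
the 7-point grid, and then receives multiplicative measurement noise,
optional missing samples, and a phenotype feature row statistically
coupled to the generating parameters.  The ground truth travels in a
separate block that no fitting or regression API accepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archetypes import CLASS_ARCHETYPES, CLASS_ORDER, ClassArchetype
from .edes import ModelParameters, OGTT_TIMES, SubjectContext, simulate
from .fitting import OGTTResponse
from .regression import FeatureTable

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "SubjectTruth",
    "DEFAULT_CLASS_MIX",
    "sample_class_parameters",
    "generate_features",
    "generate_cohort",
    "FEATURE_SCHEMA",
]

#: class mix loosely following a mixed middle-aged European cohort
#: (about half normoglycemic, a fifth diabetic, the rest prediabetic)
DEFAULT_CLASS_MIX = {"NGM": 0.48, "IFG": 0.18, "IGT": 0.05, "IFG&IGT": 0.08, "T2DM": 0.21}


@dataclass
class CohortSpec:
    """Generation settings; the defaults define the study conditions."""

    n: int = 300
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    glucose_cv: float = 0.03
    insulin_cv: float = 0.08
    missing_prob: float = 0.02     # per analyte per interior timepoint
    allow_missing_anchors: bool = False   # True only to exercise the exclusion filter
    seed: int = 0
    feature_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.glucose_cv < 0 or self.insulin_cv < 0:
            raise ValueError("noise CVs must be nonnegative")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must lie in [0, 1)")
        unknown = set(self.class_mix) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if total <= 0:
            raise ValueError("class mix weights must sum to a positive value")
        self.class_mix = {k: v / total for k, v in self.class_mix.items()}


@dataclass
class SubjectTruth:
    subject_id: str
    label: str
    params: ModelParameters
    g0: float
    i0: float
    glucose_auc: float          # trapezoidal AUC of the noiseless curve


@dataclass
class SyntheticCohort:
    responses: list[OGTTResponse]
    features: FeatureTable
    truth: list[SubjectTruth]

    def truth_by_id(self) -> dict[str, SubjectTruth]:
        return {t.subject_id: t for t in self.truth}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_class_parameters(arch: ClassArchetype, rng: np.random.Generator,
                            base: ModelParameters | None = None) -> ModelParameters:
    """Draw a personal parameter set from a class's log-normal laws."""
    base = base or ModelParameters()
    draws = {
        name: float(np.exp(np.log(med) + arch.k_log_sd[name] * rng.standard_normal()))
        for name, med in arch.k_median.items()
    }
    return base.replace(**draws)


# ---------------------------------------------------------------------------
# phenotype features

FEATURE_SCHEMA: dict[str, str] = {
    # anthropometry
    "age_years": "numeric", "bmi_kg_m2": "numeric", "waist_cm": "numeric",
    "body_fat_pct": "numeric",
    # glycemic markers
    "hba1c_pct": "numeric", "fasting_glucose_lab": "numeric",
    "fasting_insulin_lab": "numeric",
    # lipids and cardiometabolic labs
    "triglycerides_mmol_l": "numeric", "hdl_mmol_l": "numeric",
    "ldl_mmol_l": "numeric", "total_chol_mmol_l": "numeric",
    "crp_mg_l": "numeric", "alt_u_l": "numeric", "ggt_u_l": "numeric",
    "systolic_bp_mmhg": "numeric", "diastolic_bp_mmhg": "numeric",
    # lifestyle
    "steps_per_day": "numeric", "sedentary_hours": "numeric",
    "alcohol_units_week": "numeric", "diet_quality_score": "numeric",
    # categoricals
    "sex": "categorical", "smoking_status": "categorical",
    "glucose_lowering_med": "categorical", "metabolic_syndrome": "categorical",
    "family_history_t2dm": "categorical", "education_level": "categorical",
}

# linear couplings: feature = intercept + sum(coef * driver) + noise_sd * eps
# drivers: z-scores of log personal parameters, class index 0..4, centered
# basal values, and the standardized glucose AUC of the noiseless curve.
DEFAULT_COUPLINGS: dict[str, tuple[float, dict[str, float], float]] = {
    "age_years":            (58.0, {"cls": 1.5}, 7.0),
    "bmi_kg_m2":            (26.5, {"cls": 0.9, "z_k5": -1.0}, 2.5),
    "waist_cm":             (95.0, {"cls": 2.5, "z_k5": -2.5}, 7.0),
    "body_fat_pct":         (30.0, {"cls": 1.2, "z_k5": -1.5}, 5.0),
    "hba1c_pct":            (5.25, {"auc_z": 0.55, "cls": 0.10}, 0.12),
    "fasting_glucose_lab":  (0.0,  {"g0": 1.0}, 0.12),
    "fasting_insulin_lab":  (0.0,  {"i0": 1.0}, 1.2),
    "triglycerides_mmol_l": (1.4,  {"cls": 0.15, "z_k5": -0.12}, 0.45),
    "hdl_mmol_l":           (1.45, {"cls": -0.07, "z_k5": 0.08}, 0.28),
    "ldl_mmol_l":           (3.1,  {"cls": 0.05}, 0.75),
    "total_chol_mmol_l":    (5.3,  {"cls": 0.05}, 0.85),
    "crp_mg_l":             (2.0,  {"cls": 0.35}, 1.6),
    "alt_u_l":              (26.0, {"cls": 1.5, "z_k5": -1.5}, 8.0),
    "ggt_u_l":              (30.0, {"cls": 3.0}, 12.0),
    "systolic_bp_mmhg":     (130.0, {"cls": 2.5}, 12.0),
    "diastolic_bp_mmhg":    (78.0, {"cls": 1.0}, 8.0),
    "steps_per_day":        (7500.0, {"cls": -350.0, "z_k5": 350.0}, 2200.0),
    "sedentary_hours":      (8.5,  {"cls": 0.25, "z_k5": -0.2}, 1.6),
    "alcohol_units_week":   (6.0,  {}, 5.0),
    "diet_quality_score":   (55.0, {"cls": -1.5}, 12.0),
}

#: probability of a positive flag per class index (0=NGM .. 4=T2DM)
_MED_PROB = (0.0, 0.0, 0.0, 0.02, 0.70)
_METSYN_PROB = (0.15, 0.35, 0.40, 0.50, 0.70)
_FAMHIST_PROB = (0.20, 0.28, 0.30, 0.35, 0.50)


def generate_features(truth: SubjectTruth, rng: np.random.Generator,
                      couplings: dict | None = None,
                      noise_scale: float = 1.0) -> dict[str, object]:
    """One phenotype feature row statistically coupled to the ground truth.

    Numeric features are linear in the standardized log-parameters, the
    class index, the basal values and the glucose AUC of the noiseless
    curve, plus Gaussian noise; the glucose-lowering-medication flag is
    essentially confined to the T2DM class; the HbA1c-like marker
    increases with the simulated glycemic exposure.
    """
    couplings = couplings if couplings is not None else DEFAULT_COUPLINGS
    ngm = CLASS_ARCHETYPES["NGM"]
    cls = float(CLASS_ORDER.index(truth.label))
    drivers = {
        "cls": cls,
        "g0": truth.g0,
        "i0": truth.i0,
        "auc_z": (truth.glucose_auc - 700.0) / 150.0,
    }
    for name in ("k1", "k5", "k6", "k8"):
        drivers[f"z_{name}"] = (
            np.log(getattr(truth.params, name)) - np.log(ngm.k_median[name])
        ) / max(ngm.k_log_sd[name], 1e-6)
    row: dict[str, object] = {"subject_id": truth.subject_id}
    for feat, (intercept, coefs, sd) in couplings.items():
        val = intercept + sum(c * drivers[d] for d, c in coefs.items())
        row[feat] = float(val + noise_scale * sd * rng.standard_normal())
    ci = int(cls)
    row["sex"] = "female" if rng.random() < 0.5 else "male"
    row["smoking_status"] = str(rng.choice(["never", "former", "current"], p=[0.45, 0.35, 0.2]))
    row["glucose_lowering_med"] = "yes" if rng.random() < _MED_PROB[ci] else "no"
    row["metabolic_syndrome"] = "yes" if rng.random() < _METSYN_PROB[ci] else "no"
    row["family_history_t2dm"] = "yes" if rng.random() < _FAMHIST_PROB[ci] else "no"
    row["education_level"] = str(rng.choice(["low", "mid", "high"], p=[0.3, 0.4, 0.3]))
    return row


def generate_cohort(spec: CohortSpec, ctx: SubjectContext | None = None,
                    base_params: ModelParameters | None = None) -> SyntheticCohort:
    """Generate a fully seeded cohort of responses, features and truth."""
    ctx = ctx or SubjectContext()
    base = base_params or ModelParameters()
    rng = np.random.default_rng(spec.seed)
    times = np.array(OGTT_TIMES)
    labels = list(spec.class_mix)
    weights = np.array([spec.class_mix[l] for l in labels])

    responses: list[OGTTResponse] = []
    truths: list[SubjectTruth] = []
    rows: list[dict] = []
    for k in range(spec.n):
        sid = f"S{k:04d}"
        label = str(rng.choice(labels, p=weights))
        arch = CLASS_ARCHETYPES[label]
        sim = None
        for _attempt in range(5):
            params = sample_class_parameters(arch, rng, base)
            g0 = _truncnorm(rng, *arch.basal_glucose)
            i0 = _truncnorm(rng, *arch.basal_insulin)
            sim = simulate(params, ctx, g0, i0, times)
            if sim.success:
                break
        if sim is None or not sim.success:
            raise RuntimeError(f"{sid}: simulation failed after retries")
        auc = float(np.trapezoid(sim.g_traj, times))
        truth = SubjectTruth(sid, label, params, g0, i0, auc)

        g = sim.g_traj.copy()
        i = sim.i_traj.copy()
        if spec.glucose_cv > 0:
            noisy = g * (1 + spec.glucose_cv * rng.standard_normal(len(times)))
            g = np.maximum(noisy, 0.1 * g)
        if spec.insulin_cv > 0:
            noisy = i * (1 + spec.insulin_cv * rng.standard_normal(len(times)))
            i = np.maximum(noisy, 0.1 * i)
        if spec.missing_prob > 0:
            protected = {0, len(times) - 1} if not spec.allow_missing_anchors else set()
            for j in range(len(times)):
                if j in protected:
                    continue
                if rng.random() < spec.missing_prob:
                    g[j] = np.nan
                if rng.random() < spec.missing_prob:
                    i[j] = np.nan
        responses.append(OGTTResponse(sid, times.copy(), g, i))
        truths.append(truth)
        rows.append(generate_features(truth, rng, noise_scale=spec.feature_noise_scale))

    features = FeatureTable(data=pd.DataFrame(rows), schema=dict(FEATURE_SCHEMA))
    return SyntheticCohort(responses=responses, features=features, truth=truths)
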