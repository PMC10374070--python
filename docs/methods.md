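# Methods

## The mechanistic model

The simulator is a five-state compartmental model of the postprandial
glucose–insulin system in minutes, mmol/L (glucose) and mU/L (insulin).
States: glucose mass in the gut `M` (mmol), plasma glucose `G`, the
integral `Z` of the glucose excursion, plasma insulin `I` and remote
(interstitial) insulin `Q`.

Gastric emptying is Weibull-shaped,
`m(t) = D·σ·k₁^σ·t^(σ−1)·exp(−(k₁t)^σ)`, which integrates exactly to the
dose `D` and reduces to first-order emptying at σ = 1; σ > 1 delays the
peak, as observed after a liquid glucose drink. Gut glucose is absorbed
at rate k₂ and appears in plasma scaled by bioavailability `f` over the
distribution volume `V = v_g·BW`.

Plasma glucose balances four clearance routes against endogenous
production: insulin-independent uptake (Michaelis–Menten in `G`,
normalized so it equals `u_b` at the basal state), insulin-dependent
uptake `k₅·Q·G/(K_m+G)`, a hepatic term `EGP_b − k₃(G−G_b) − k₄·Q`
(production suppressed by both hyperglycemia and insulin), and renal
excretion `c₁(G−g_th)/V` active only above the renal threshold — inert
for the default phenotypes, whose excursions stay below 9 mmol/L.

Insulin secretion is a PID controller on the excursion about the basal
set-points: proportional (k₆), integral (k₇/τᵢ acting on `Z`) and
derivative (k₈·τ_d acting on dG/dt) terms, scaled by a pancreatic
responsiveness factor β and clamped at zero — the pancreas cannot
secrete negatively. β multiplies the whole secretion signal (it is a
responsiveness scale, and this placement makes the β·k₆ product
degeneracy used in the identifiability checks exact); the integrator is
not anti-windup-clamped because the simulated horizon is only 120 min.
Insulin is cleared at k₉ and exchanges with the remote compartment at
k₁₀; remote insulin is what drives glucose uptake, giving the
physiological delay between plasma insulin and its action.

**Basal closure.** `EGP_b = u_b + I_b·(k₄ + k₅·G_b/(K_m+G_b))` makes the
fasting state `(M=0, G=G_b, Z=0, I=I_b, Q=I_b)` an exact equilibrium;
the equilibrium test holds it to <1e−6 mmol/L over 4 h.

**Anchoring convention.** `simulate` sets `G_b := G(0)` and
`I_b := I(0)` from the supplied initial values and re-derives `EGP_b`.
Fits therefore reproduce the t = 0 measurements exactly, which is why
the personalized scenarios exclude t = 0 from their performance metrics
(it is an input, not a prediction).

**Numerics.** LSODA (stiff-capable, adaptive) with rtol 1e−8,
atol 1e−10; halving tolerances moves peak glucose by far less than
1e−4 mmol/L. Integration failures return a flagged result, never silent
NaNs; during fitting a failed simulation maps to a large residual so the
optimizer retreats.

## Default parameters

Fixed constants (configurable): σ=1.34, k₂=0.28 min⁻¹, k₃=0.005 min⁻¹,
k₄=1e−4, k₇=0.05, k₉=0.05 min⁻¹, k₁₀=0.05 min⁻¹, u_b=0.04 mmol/(L·min),
K_m=13.2 mmol/L, g_th=9 mmol/L, c₁=0.05 L/min, τᵢ=31 min, τ_d=3 min,
β=1, f=1, v_g=0.25 L/kg, BW=75 kg, dose 75 g (416.3 mmol).

The personal subset {k₁, k₅, k₆, k₈} defaults to the normoglycemic
archetype **k₁=0.015 min⁻¹, k₅=0.02, k₆=0.5, k₈=4.0**, calibrated so
that the simulated 75 g response peaks at 8.9 mmol/L at 40 min with an
insulin peak of ~40 mU/L and returns to 5.2 mmol/L by 120 min — the
shape clinicians expect of a healthy OGTT.

## Personalization

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) on log10-parameters — rate constants span decades and
the log parameterization conditions the problem — with bounds
[1e−4, 1e2] times each default. Residuals concatenate glucose and
insulin `(prediction − measurement)/scale` with the per-subject mean of
the present values as scale, so the two analytes (an order of magnitude
apart in units) contribute comparably; a fixed-unit alternative is
available. Missing interior samples are dropped, never imputed. The
returned SSR never exceeds the SSR at the initial guess; a single start
from population defaults is the default, with an optional seeded
multistart. On noiseless synthetic curves the estimator returns the
truth to machine precision; at 3% proportional noise the median
relative error over {k₁,k₅,k₆,k₈} stays well under 15%.

## Model selection

- **LPSA**: central differences at ±5% relative perturbation; the score
  is the mean over the 14 outputs of |Δoutput/output|/(Δp/p), invariant
  to output rescaling. The "sensitive" cutoff is top-k (default 6).
- **Candidates**: all subsets of size ≥ 3 of the sensitive parameters,
  ordered by size then lexicographically.
- **Representative curves**: one noiseless archetype per glucometabolic
  class (NGM, IFG, IGT, IFG&IGT, T2DM — basal values inside each class's
  diagnostic band) plus the cohort's extreme responses by trapezoidal
  glucose AUC, seven curves in all.
- **AIC**: least-squares form `n·ln(SSR/n) + 2k`, summed across curves
  (sum and mean rank identically); ties go to the smaller subset, then
  lexicographic order. A perfect fit returns −∞ with a warning rather
  than a silent non-finite value.
- **PLA**: the profiled parameter is fixed on a log-spaced grid (default
  41 points, ±1 decade), the remaining parameters re-optimized with
  warm starts spreading outward from the optimum. The SSR profile is
  scaled by σ̂² = SSR_min/(n−k) so the 95% χ²(1) threshold 3.84 marks a
  pointwise confidence bound; σ̂² is floored at 1e−12 to keep the scaling
  meaningful on numerically perfect (noiseless) fits. Crossing the
  threshold on both sides ⇒ identifiable; a profile flat to within 0.5
  of the minimum everywhere ⇒ structurally non-identifiable; anything
  else ⇒ practically non-identifiable.

On cohorts generated by varying only {k₁,k₅,k₆,k₈}, the workflow selects
exactly that subset, and each member profiles as identifiable from a
noiseless 7-point curve.

## Data-driven regression

Per-timepoint `GradientBoostingRegressor` models (squared-error loss;
gain importances are the MSE reduction weighted by the fraction of
samples reaching each split) under nested 5×5 CV: the outer folds are
held out entirely; the inner folds tune the grid trees {100, 300} ×
depth {2, 3, 4} × learning rate {0.05, 0.1} × subsample {0.8, 1.0}
(ties to the first configuration in that fixed order). Numeric features
are median-imputed and z-scored, categoricals dummy-coded with an
explicit missing level — all statistics fitted on the training fold
only; unseen test levels encode as all zeros. Fold assignment is a
seeded shuffle without stratification and is shared across targets;
subjects missing a target are dropped for that target only. Indicator
importances are summed into their parent feature and normalized to 1.
A permuted-target null run yields mean out-of-fold R² ≈ 0, confirming
no leakage through encoding or tuning. Desk-scale runs (the examples,
the acceptance script) use reduced grids — e.g. 100 trees, depth
{2, 3}, learning rate {0.05, 0.1} — which leaves every ranking
conclusion unchanged.

## Scenarios and the hybrid

`REF_EDES` fits {k₁,k₅,k₆,k₈} once on the median curve of the subjects
classified normoglycemic from their measured fasting/2-h glucose, then
simulates every subject with those estimates and the subject's own t = 0
anchor (the alternative — simulating from the median's basal values — is
a configuration choice; anchoring makes the t = 0 cell of the reference
metrics degenerate, and it is flagged as such). `PERS_EDES` uses each
subject's own fit. `REF_GBR` regresses the concentrations directly.
The hybrids train the same nested-CV regressors on mechanistic
residuals (prediction − measurement) and subtract the predicted residual
from the mechanistic prediction, flooring negative concentrations at
zero. Residuals at t = 0 vanish identically by anchoring, so no residual
model is trained there. Mechanistic fits are strictly per-subject (no
cross-subject information), so residual regressors can be trained and
evaluated inside the same outer folds as the direct regressors. All
reported regression metrics are out-of-fold.

## The synthetic cohort

Each subject draws a class from a configurable mix (default
NGM .48 / IFG .18 / IGT .05 / IFG&IGT .08 / T2DM .21, a mixed
middle-aged European cohort), class-conditional log-normal
{k₁,k₅,k₆,k₈} and truncated-normal basal values inside the class's
diagnostic band. Class medians are calibrated so the median subject's
simulated 2-h glucose lands in-band (NGM 5.2, IFG 6.5, IGT 8.8,
IFG&IGT 10.2, T2DM 14.6 mmol/L); insulin sensitivity k₅ and secretion k₆
decrease strictly from NGM to T2DM, mirroring the pathophysiology.
Measurements get multiplicative Gaussian noise (CV 3% glucose, 8%
insulin — typical assay-plus-biological repeatability — floored at 0.1×
the true value) and interior samples go missing with probability 0.02
per analyte; t = 0 and 120 min are protected unless the exclusion filter
itself is under test. The ~26 phenotype features (20 numeric, 6
categorical) are linear in the standardized log-parameters, class index,
basal values and simulated glucose AUC plus Gaussian noise: an HbA1c
analogue tracks glycemic exposure, a lab fasting glucose tracks the
basal state, a medication flag is essentially confined to the T2DM
class, and anthropometry/lipids/lifestyle carry weaker couplings.
Ground truth travels in a separate block that no fitting or regression
API accepts.

What the generator does **not** emulate: the realistic covariance of a
deep-phenotyping battery (features here are conditionally independent
given the truth), longitudinal structure, assay-specific error shapes,
or model mis-specification — synthetic subjects are generated by the
same model family that is fitted, so recovery tests certify the
estimation machinery, not the biological adequacy of the model. The
data-driven scenarios look stronger here than they would on real data
because two features are direct proxies of the generating state; the
scenario ordering (personalized mechanistic ≥ hybrid ≫ reference
mechanistic) is the transferable conclusion, not the absolute R² levels.

## Problem sizes and defaults used in the shipped runs

The acceptance script and the heavyweight tests use a 300-subject
cohort for the scenario comparison and the permutation null (20
permutations, one representative target), 20 replicates for the
recovery studies, 10 candidates × 3 curves for the selection oracle,
and the reduced tuning grid above; these sizes give stable verdicts for
every property while keeping a full run in a few minutes on one core.

## Known limitations

- The flux forms are a reconstruction honoring the published structure
  (gut + plasma compartments, Weibull emptying, Michaelis–Menten uptake,
  PID secretion, t = 0 set-point anchoring); an original-source variant
  can be substituted behind the same interface.
- No glycogen dynamics, glucagon, incretins, exogenous insulin or mixed
  meals; the model is specific to a standardized glucose drink.
- k₈ (derivative secretion) is the least identifiable of the personal
  subset on 7-point data; its recovery error dominates the noisy-fit
  budget.
- The Matsuda implementation presumes insulin in mU/L (≡ μU/mL) and
  converts glucose with 18.016 mg/dL per mmol/L.
- The exclusion filter defaults to the permissive "more than two missing
  timepoints" reading; a strict "two or more" switch is provided because
  both readings appear in descriptions of the protocol.
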