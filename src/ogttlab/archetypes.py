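"""Glucometabolic class archetypes.

Five canonical responder classes span the glucometabolic spectrum —
normal glucose metabolism (NGM), impaired fasting glucose (IFG),
impaired glucose tolerance (IGT), combined IFG&IGT, and type 2 diabetes
(T2DM).  Each archetype carries median personal parameters
``{k1, k5, k6, k8}`` and basal glucose/insulin distributions whose
medians were calibrated so a noiseless simulation of the median subject
lands inside the class's fasting/2-h diagnostic bands (ADA cut-points).
Insulin sensitivity (k5) and proportional secretion (k6) decrease
monotonically from NGM to T2DM, mirroring the progressive uptake and
beta-cell impairment that defines the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ClassArchetype", "CLASS_ARCHETYPES", "CLASS_ORDER"]

CLASS_ORDER = ("NGM", "IFG", "IGT", "IFG&IGT", "T2DM")


@dataclass(frozen=True)
class ClassArchetype:
    """Generating distributions of one glucometabolic class.

    ``k_median`` are medians of log-normal laws with log-sd ``k_log_sd``;
    basal glucose/insulin are truncated normals (mean, sd, lo, hi).
    """

    label: str
    k_median: dict[str, float]
    k_log_sd: dict[str, float]
    basal_glucose: tuple[float, float, float, float]   # mean, sd, lo, hi (mmol/L)
    basal_insulin: tuple[float, float, float, float]   # mean, sd, lo, hi (mU/L)

    def median_params(self) -> dict[str, float]:
        return dict(self.k_median)


def _arch(label, k1, k5, k6, k8, sd, bg, bi) -> ClassArchetype:
    return ClassArchetype(
        label=label,
        k_median={"k1": k1, "k5": k5, "k6": k6, "k8": k8},
        k_log_sd={"k1": sd, "k5": sd, "k6": sd, "k8": sd},
        basal_glucose=bg,
        basal_insulin=bi,
    )


#: calibrated class table (see module docstring); basal bands follow the
#: ADA fasting cut-points 5.6 / 7.0 mmol/L with a small margin.
CLASS_ARCHETYPES: dict[str, ClassArchetype] = {
    "NGM": _arch("NGM", 0.015, 0.020, 0.50, 4.0, 0.12,
                 (5.0, 0.25, 4.2, 5.50), (8.0, 2.0, 3.0, 18.0)),
    "IFG": _arch("IFG", 0.015, 0.016, 0.45, 3.5, 0.10,
                 (6.2, 0.30, 5.65, 6.90), (11.0, 3.0, 4.0, 24.0)),
    "IGT": _arch("IGT", 0.016, 0.007, 0.26, 1.6, 0.08,
                 (5.2, 0.25, 4.2, 5.50), (13.0, 3.5, 5.0, 28.0)),
    "IFG&IGT": _arch("IFG&IGT", 0.016, 0.0065, 0.25, 1.5, 0.08,
                     (6.3, 0.30, 5.65, 6.90), (14.0, 4.0, 5.0, 30.0)),
    "T2DM": _arch("T2DM", 0.017, 0.004, 0.15, 1.0, 0.15,
                  (8.0, 0.80, 7.05, 11.0), (15.0, 5.0, 5.0, 40.0)),
}
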