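"""Metric formulas, Matsuda index, ADA classifier, exclusion filter, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ogttlab.edes import OGTT_TIMES
from ogttlab.fitting import FitResult, OGTTResponse
from ogttlab.metrics import (
    ADAThresholds,
    MMOL_TO_MGDL,
    classify_glucometabolic,
    exclusion_filter,
    matsuda_index,
    mse_r2_per_timepoint,
    parameter_pca,
)

TIMES = np.array(OGTT_TIMES)


def wide(values_by_subject):
    return pd.DataFrame(values_by_subject, index=[0.0]).T


class TestMseR2:
    def test_hand_computed_example(self):
        meas = wide({"A": 1.0, "B": 2.0, "C": 3.0})
        pred = wide({"A": 1.0, "B": 2.0, "C": 4.0})
        out = mse_r2_per_timepoint(pred, meas)
        assert out.loc[0, "mse"] == pytest.approx(1 / 3)
        assert out.loc[0, "r2"] == pytest.approx(0.5)
        assert out.loc[0, "n"] == 3

    def test_perfect_prediction(self):
        meas = wide({"A": 1.0, "B": 2.0, "C": 3.0})
        out = mse_r2_per_timepoint(meas.copy(), meas)
        assert out.loc[0, "mse"] == 0.0
        assert out.loc[0, "r2"] == 1.0

    def test_mean_predictor_scores_zero(self):
        meas = wide({"A": 1.0, "B": 2.0, "C": 6.0})
        pred = wide({"A": 3.0, "B": 3.0, "C": 3.0})
        out = mse_r2_per_timepoint(pred, meas)
        assert out.loc[0, "r2"] == pytest.approx(0.0)

    def test_zero_variance_measurements_reported_missing(self):
        meas = wide({"A": 2.0, "B": 2.0})
        pred = wide({"A": 2.5, "B": 1.5})
        out = mse_r2_per_timepoint(pred, meas)
        assert math.isnan(out.loc[0, "r2"])
        assert "variance" in out.loc[0, "note"]

    def test_t0_exclusion_flagged(self):
        meas = pd.DataFrame({0.0: [5.0, 6.0], 60.0: [8.0, 9.0]}, index=["A", "B"])
        pred = meas + 0.5
        out = mse_r2_per_timepoint(pred, meas, exclude_t0=True)
        row0 = out[out.time_min == 0.0].iloc[0]
        assert math.isnan(row0["mse"]) and "excluded" in row0["note"]
        assert out[out.time_min == 60.0].iloc[0]["mse"] == pytest.approx(0.25)


class TestMatsuda:
    def _resp(self, g_mgdl, i0, g_mean_mgdl, i_mean):
        g = np.full(7, g_mean_mgdl / MMOL_TO_MGDL)
        g[0] = g_mgdl / MMOL_TO_MGDL
        # choose the remaining entries so the overall means hit the targets
        g[1:] = (7 * g_mean_mgdl / MMOL_TO_MGDL - g[0]) / 6
        i = np.full(7, (7 * i_mean - i0) / 6)
        i[0] = i0
        return OGTTResponse("M", TIMES, g, i)

    def test_flat_profile_value(self):
        resp = self._resp(100.0, 25.0, 100.0, 25.0)
        assert matsuda_index(resp) == pytest.approx(4.0, rel=1e-12)

    def test_mixed_profile_value(self):
        resp = self._resp(90.0, 10.0, 120.0, 40.0)
        assert matsuda_index(resp) == pytest.approx(10000 / math.sqrt(4_320_000), rel=1e-9)

    def test_missing_2h_insulin_gives_missing(self):
        resp = self._resp(100.0, 25.0, 100.0, 25.0)
        resp.insulin[-1] = np.nan
        assert math.isnan(matsuda_index(resp))

    def test_missing_baseline_gives_missing(self):
        resp = self._resp(100.0, 25.0, 100.0, 25.0)
        resp.glucose[0] = np.nan
        assert math.isnan(matsuda_index(resp))


class TestClassifier:
    @pytest.mark.parametrize("fasting, two_hour, label", [
        (5.0, 6.0, "NGM"),
        (5.5, 7.7, "NGM"),       # just under both bands
        (5.6, 6.0, "IFG"),       # fasting band floor
        (6.9, 7.0, "IFG"),
        (5.0, 7.8, "IGT"),       # 2-h band floor
        (5.0, 11.0, "IGT"),
        (6.3, 8.5, "IFG&IGT"),
        (7.0, 6.0, "T2DM"),      # fasting cut
        (7.2, 20.0, "T2DM"),
        (5.0, 11.1, "T2DM"),     # 2-h cut
    ])
    def test_ada_decision_table(self, fasting, two_hour, label):
        assert classify_glucometabolic(fasting, two_hour) == label

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_glucometabolic(float("nan"), 6.0)

    @given(fasting=st.floats(3.0, 15.0), two_hour=st.floats(3.0, 25.0))
    def test_partition_of_the_plane(self, fasting, two_hour):
        label = classify_glucometabolic(fasting, two_hour)
        assert label in {"NGM", "IFG", "IGT", "IFG&IGT", "T2DM"}

    def test_thresholds_configurable(self):
        th = ADAThresholds(ifg_lo=6.1)  # WHO-style fasting floor
        assert classify_glucometabolic(5.8, 6.0, th) == "NGM"


def _resp_with_missing(sid, missing):
    g = np.full(7, 5.0)
    i = np.full(7, 10.0)
    for idx, analyte in missing:
        (g if analyte == "g" else i)[idx] = np.nan
    return OGTTResponse(sid, TIMES, g, i)


class TestExclusionFilter:
    def test_complete_response_included(self):
        inc, exc = exclusion_filter([_resp_with_missing("A", [])])
        assert len(inc) == 1 and not exc

    def test_missing_baseline_glucose_excluded(self):
        inc, exc = exclusion_filter([_resp_with_missing("A", [(0, "g")])])
        assert not inc
        assert "baseline missing" in exc[0][1]

    def test_missing_2h_excluded(self):
        _, exc = exclusion_filter([_resp_with_missing("A", [(6, "i")])])
        assert "2h post-load missing" in exc[0][1]

    def test_two_interior_missing_included_default(self):
        # the "more than two" reading admits exactly two missing timepoints
        resp = _resp_with_missing("A", [(1, "g"), (2, "i")])
        inc, _ = exclusion_filter([resp])
        assert len(inc) == 1

    def test_three_interior_missing_excluded(self):
        resp = _resp_with_missing("A", [(1, "g"), (2, "i"), (3, "g")])
        _, exc = exclusion_filter([resp])
        assert "3 missing timepoints" in exc[0][1]

    def test_strict_reading_excludes_two(self):
        resp = _resp_with_missing("A", [(1, "g"), (2, "i")])
        _, exc = exclusion_filter([resp], strict=True)
        assert len(exc) == 1

    def test_either_analyte_marks_timepoint_missing(self):
        # glucose and insulin missing at the same timepoint count once
        resp = _resp_with_missing("A", [(1, "g"), (1, "i"), (2, "g")])
        inc, _ = exclusion_filter([resp])
        assert len(inc) == 1


def _fits(n=12, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        est = {"k1": float(np.exp(rng.normal(-4.2, 0.3))),
               "k5": float(np.exp(rng.normal(-4.0, 0.5))),
               "k6": float(np.exp(rng.normal(-0.7, 0.4))),
               "k8": float(np.exp(rng.normal(1.2, 0.3)))}
        out.append(FitResult(f"S{k}", est, 0.1, np.zeros(7), np.zeros(7), 14,
                             True, 5, np.zeros(7), np.zeros(7)))
    return out


class TestParameterPCA:
    def test_scores_centered_and_variance_sums_to_one(self):
        pca = parameter_pca(_fits())
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0.0, atol=1e-12)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(pca.explained_variance_ratio >= 0)

    def test_loadings_orthonormal(self):
        pca = parameter_pca(_fits())
        L = pca.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_full_reconstruction(self):
        pca = parameter_pca(_fits())
        np.testing.assert_allclose(pca.scores @ pca.loadings.T, pca.standardized,
                                   atol=1e-9)

    def test_constant_parameter_rejected(self):
        fits = _fits()
        for f in fits:
            f.estimates["k1"] = 0.015
        with pytest.raises(ValueError, match="k1"):
            parameter_pca(fits)

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            parameter_pca(_fits(2))
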