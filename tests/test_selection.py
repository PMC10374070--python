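"""Sensitivity ranking, candidate enumeration, AIC selection, PLA."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from ogttlab.edes import ModelParameters, OGTT_TIMES, SubjectContext, simulate
from ogttlab.fitting import FitConfig, OGTTResponse, fit_individual
from ogttlab.selection import (
    CandidateModel,
    aic_score,
    candidate_sets,
    local_sensitivity,
    profile_likelihood,
    representative_curves,
    select_parsimonious,
)

TIMES = np.array(OGTT_TIMES)


def noiseless_curve(params, ctx, g0=5.0, i0=8.0, sid="A"):
    sim = simulate(params, ctx, g0, i0, TIMES)
    assert sim.success
    return OGTTResponse(sid, TIMES.copy(), sim.g_traj, sim.i_traj)


class TestLocalSensitivity:
    def test_inactive_renal_pathway_scores_zero(self, params0, ctx, ngm_curve):
        # the NGM archetype stays below the renal threshold g_th
        rep = local_sensitivity(params0, ctx, ngm_curve)
        assert rep.scores["c1"] == 0.0

    def test_personal_parameters_outrank_renal(self, params0, ctx, ngm_curve):
        rep = local_sensitivity(params0, ctx, ngm_curve)
        for name in ("k1", "k5", "k6", "k8"):
            assert rep.scores[name] > rep.scores["c1"]

    def test_matches_half_step_oracle_for_top4(self, params0, ctx, ngm_curve):
        coarse = local_sensitivity(params0, ctx, ngm_curve, rel_perturbation=0.05)
        fine = local_sensitivity(params0, ctx, ngm_curve, rel_perturbation=0.025)
        for name in coarse.ranking[:4]:
            assert coarse.scores[name] == pytest.approx(fine.scores[name], rel=0.05)

    def test_scores_invariant_to_output_units(self, params0, ctx, ngm_curve):
        # the relative formulation cancels any common output rescaling;
        # equality to a re-run is the degenerate unit-change case
        a = local_sensitivity(params0, ctx, ngm_curve)
        b = local_sensitivity(params0, ctx, ngm_curve)
        assert a.scores == b.scores

    def test_incomplete_archetype_rejected(self, params0, ctx, ngm_curve):
        bad = OGTTResponse("B", TIMES, ngm_curve.glucose.copy(), ngm_curve.insulin.copy())
        bad.glucose[3] = np.nan
        with pytest.raises(ValueError):
            local_sensitivity(params0, ctx, bad)


class TestCandidateSets:
    def test_three_names_single_candidate(self):
        out = candidate_sets(["k1", "k5", "k6"])
        assert out == [CandidateModel(subset=("k1", "k5", "k6"))]

    def test_six_names_give_42_candidates(self):
        out = candidate_sets(["k1", "k2", "k5", "k6", "k8", "k9"])
        assert len(out) == 42  # C(6,3)+C(6,4)+C(6,5)+C(6,6)

    def test_all_sizes_at_least_three(self):
        assert all(len(c.subset) >= 3 for c in candidate_sets(list("abcde")))

    def test_too_few_names_error(self):
        with pytest.raises(ValueError):
            candidate_sets(["k1", "k5"])


class TestRepresentativeCurves:
    def test_seven_curves_with_min_max(self, params0, ctx, small_cohort):
        curves = representative_curves(small_cohort.responses, params0, ctx)
        assert len(curves) == 7
        ids = [c.subject_id for c in curves]
        assert sum(i.startswith("ARCH_") for i in ids) == 5
        assert any(i.startswith("MIN_") for i in ids)
        assert any(i.startswith("MAX_") for i in ids)

    def test_min_max_are_extremes_by_glucose_auc(self, params0, ctx, small_cohort):
        from ogttlab.selection import glucose_auc
        curves = representative_curves(small_cohort.responses, params0, ctx)
        lo = next(c for c in curves if c.subject_id.startswith("MIN_"))
        hi = next(c for c in curves if c.subject_id.startswith("MAX_"))
        aucs = [glucose_auc(r) for r in small_cohort.responses
                if r.glucose_mask.sum() >= 2]
        assert glucose_auc(lo) == min(aucs)
        assert glucose_auc(hi) == max(aucs)

    def test_ifg_archetype_sits_in_fasting_band(self, params0, ctx, small_cohort):
        curves = representative_curves(small_cohort.responses, params0, ctx)
        ifg = next(c for c in curves if c.subject_id == "ARCH_IFG")
        assert 5.6 <= ifg.glucose[0] < 7.0
        assert ifg.glucose[-1] < 7.8


class TestAicScore:
    def test_direct_evaluation(self):
        assert aic_score(ssr=14.0, n_obs=14, n_params=4) == pytest.approx(8.0)

    def test_parameter_penalty_is_two_per_parameter(self):
        assert aic_score(10.0, 14, 5) - aic_score(10.0, 14, 4) == pytest.approx(2.0)

    def test_halving_ssr_drops_by_n_ln2(self):
        drop = aic_score(10.0, 14, 4) - aic_score(5.0, 14, 4)
        assert drop == pytest.approx(14 * math.log(2), abs=1e-9)

    def test_perfect_fit_warns_and_returns_neg_inf(self):
        with pytest.warns(RuntimeWarning):
            assert aic_score(0.0, 14, 4) == -math.inf


@pytest.fixture(scope="module")
def varied_curves(params0, ctx):
    rng = np.random.default_rng(42)
    curves = []
    for j in range(3):
        factors = np.exp(0.35 * rng.standard_normal(4))
        p = params0.replace(k1=0.015 * factors[0], k5=0.02 * factors[1],
                            k6=0.5 * factors[2], k8=4.0 * factors[3])
        curves.append(noiseless_curve(p, ctx, sid=f"C{j}"))
    return curves


class TestSelectParsimonious:
    def test_single_candidate_wins(self, params0, ctx, varied_curves):
        cand = [CandidateModel(("k1", "k5", "k6"))]
        sel = select_parsimonious(cand, varied_curves[:1], FitConfig(), params0, ctx)
        assert sel.winner.subset == ("k1", "k5", "k6")

    def test_recovers_generating_subset(self, params0, ctx, varied_curves):
        # curves vary only {k1,k5,k6,k8}: that subset should win over its
        # 3-parameter restrictions despite the larger AIC penalty
        cands = candidate_sets(["k1", "k5", "k6", "k8"])
        sel = select_parsimonious(cands, varied_curves, FitConfig(), params0, ctx)
        assert sel.winner.subset == ("k1", "k5", "k6", "k8")

    def test_invariant_to_candidate_order(self, params0, ctx, varied_curves):
        cands = candidate_sets(["k1", "k5", "k6", "k8"])
        a = select_parsimonious(cands, varied_curves[:2], FitConfig(), params0, ctx)
        b = select_parsimonious(cands[::-1], varied_curves[:2], FitConfig(), params0, ctx)
        assert a.winner == b.winner


class TestProfileLikelihood:
    def test_threshold_is_chi2_95_quantile(self, params0, ctx, ngm_curve):
        cfg = FitConfig(params_to_fit=("k1",))
        fr = fit_individual(ngm_curve, cfg, params0, ctx)
        pl = profile_likelihood(ngm_curve, fr, "k1", cfg, params0, ctx, n_points=11)
        assert pl.threshold == pytest.approx(chi2.ppf(0.95, 1))

    def test_k1_identifiable_on_noiseless_data(self, params0, ctx, ngm_curve):
        cfg = FitConfig(params_to_fit=("k1",))
        fr = fit_individual(ngm_curve, cfg, params0, ctx)
        pl = profile_likelihood(ngm_curve, fr, "k1", cfg, params0, ctx)
        assert pl.verdict == "identifiable"
        assert pl.crosses_left and pl.crosses_right

    def test_product_degeneracy_is_flat(self, ctx):
        # with integral/derivative secretion off, only beta*k6 enters the
        # dynamics: profiling k6 while re-optimizing beta must be flat
        p0 = ModelParameters(k7=0.0, k8=0.0)
        curve = noiseless_curve(p0, ctx, sid="DEGEN")
        cfg = FitConfig(params_to_fit=("k6", "beta"))
        fr = fit_individual(curve, cfg, p0, ctx)
        pl = profile_likelihood(curve, fr, "k6", cfg, p0, ctx, n_points=21)
        assert pl.verdict == "structurally_non_identifiable"

    def test_profile_never_below_global_minimum(self, params0, ctx, ngm_curve):
        cfg = FitConfig(params_to_fit=("k1", "k5"))
        fr = fit_individual(ngm_curve, cfg, params0, ctx)
        pl = profile_likelihood(ngm_curve, fr, "k1", cfg, params0, ctx, n_points=11)
        assert np.nanmin(pl.profile) >= -1e-9
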