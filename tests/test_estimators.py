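"""g-computation, IPW and SDR estimators against exact and hand oracles."""

import numpy as np
import pandas as pd
import pytest

from ttemu import (DGPConfig, DYNAMIC, NEVER, contrast, discrete_true_g,
                   enumerate_truth, estimate_risk_difference, fit_nuisances,
                   gcomp_estimate, ipw_estimate, sdr_estimate,
                   simulate_cohort, simulate_discrete_cohort)
from ttemu.discrete import DiscreteDGPConfig
from ttemu.estimators import EstimateResult
from ttemu.experiments import DISCRETE_FEATURES


def one_day_cohort(A, Y):
    n = len(A)
    return pd.DataFrame({
        "patient_id": np.arange(n), "day": 0,
        "age": 0.0, "sex": 0, "comorbid": 0,
        "severity": 0.0, "hypoxia": 0, "measured": 1,
        "treat": A, "death": Y, "censor": 0,
    })


class TestOracleEquivalence:
    """On the exactly weighted population cohort with saturated models,
    every route must reproduce the enumeration oracle."""

    @pytest.mark.parametrize("regime", [DYNAMIC, NEVER],
                             ids=["dynamic", "never"])
    def test_gcomp_ipw_sdr_match_enumeration(self, dconfig, pop_cohort,
                                             regime):
        truth = enumerate_truth(dconfig, regime)
        nus = fit_nuisances(pop_cohort, regime, v_folds=1,
                            g_learners=["saturated"], m_learners=["saturated"],
                            features=DISCRETE_FEATURES, trim=1e-9,
                            horizon=dconfig.horizon)
        gc = gcomp_estimate(pop_cohort, regime, nus)
        ip = ipw_estimate(pop_cohort, regime, nus)
        sd = sdr_estimate(pop_cohort, regime, ["saturated"], 1,
                          nuisances=nus)
        assert gc.estimate == pytest.approx(truth, abs=1e-8)
        assert ip.estimate == pytest.approx(truth, abs=1e-8)
        assert sd.estimate == pytest.approx(truth, abs=1e-6)
        assert sd.estimate == pytest.approx(gc.estimate, abs=1e-6)

    def test_ipw_with_true_propensities_on_sampled_cohort(self, dconfig):
        n = 30000
        coh = simulate_discrete_cohort(dconfig, n, seed=5)
        truth = enumerate_truth(dconfig, NEVER)
        pA, pC = discrete_true_g(dconfig, coh, NEVER)
        nus = fit_nuisances(coh, NEVER, v_folds=1, known_pA=pA, known_pC=pC,
                            features=DISCRETE_FEATURES, trim=1e-9,
                            m_learners=["saturated"], horizon=dconfig.horizon)
        ip = ipw_estimate(coh, NEVER, nus)
        assert abs(ip.estimate - truth) < 3 * ip.se


def test_ipw_equals_hand_horvitz_thompson_mean():
    """tau=1, known propensity 1/2, no censoring: the weighted mean is
    computable by hand."""
    A = np.array([0, 0, 0, 0, 0, 1, 1, 1, 0, 0])
    Y = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 1])
    coh = one_day_cohort(A, Y)
    pA = np.full((10, 1), 0.5)
    nus = fit_nuisances(coh, NEVER, v_folds=1, known_pA=pA,
                        m_learners=["saturated"],
                        features=["severity"], trim=1e-9, horizon=1)
    ip = ipw_estimate(coh, NEVER, nus)
    # adherent (untreated) deaths: 3 of 10 patients, each weighted 1/0.5
    assert ip.estimate == pytest.approx(0.6, abs=1e-12)


def test_ipw_under_full_adherence_recovers_raw_mortality():
    cfg = DGPConfig(n_patients=400, seed=6)
    coh = simulate_cohort(cfg, regime=NEVER, allow_discharge=False)
    raw = coh.groupby("patient_id")["death"].max().mean()
    n = coh["patient_id"].nunique()
    nus = fit_nuisances(coh, NEVER, v_folds=1,
                        known_pA=np.zeros((n, 28)),
                        known_pC=np.ones((n, 28)),
                        m_learners=["intercept_only"], trim=1e-12, horizon=28)
    ip = ipw_estimate(coh, NEVER, nus)
    assert ip.estimate == pytest.approx(raw, abs=1e-9)


def test_no_censoring_gives_unit_censoring_fits():
    cfg = DGPConfig(n_patients=200, seed=4, horizon=8)
    cfg.discharge_hazard_coefs["intercept"] = -np.inf
    coh = simulate_cohort(cfg)
    nus = fit_nuisances(coh, NEVER, v_folds=2, horizon=8)
    assert np.all(nus.pC == 1.0)


def test_probability_trimming_contract():
    coh = one_day_cohort(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))
    nus = fit_nuisances(coh, NEVER, v_folds=1,
                        known_pA=np.full((4, 1), 0.001), trim=0.01,
                        m_learners=["intercept_only"], horizon=1)
    assert np.all(nus.pA == 0.01)


def test_fitted_propensity_recovers_randomized_assignment():
    dc = DiscreteDGPConfig(p_treat=(0.5, 0.5))
    coh = simulate_discrete_cohort(dc, 3000, seed=9)
    nus = fit_nuisances(coh, NEVER, v_folds=2, features=DISCRETE_FEATURES,
                        horizon=dc.horizon)
    from ttemu.estimators import Panel
    present = Panel.from_cohort(coh, horizon=dc.horizon).present
    assert abs(nus.pA[present].mean() - 0.5) < 0.02


def test_null_effect_risk_difference_near_zero():
    cfg = DGPConfig(n_patients=1500, seed=13, treatment_effect=0.0)
    coh = simulate_cohort(cfg)
    res = estimate_risk_difference(coh, method="gcomp",
                                   learners=("linear_additive",), v_folds=2,
                                   seed=1, horizon=28)
    rd = res["risk_difference"]
    assert abs(rd.estimate) < 3 * rd.se


def test_estimates_invariant_to_patient_order_and_fold_seed(dconfig):
    coh = simulate_discrete_cohort(dconfig, 2500, seed=3)
    order = np.random.default_rng(0).permutation(coh["patient_id"].unique())
    rank = {pid: i for i, pid in enumerate(order)}
    shuffled = (coh.assign(_k=coh["patient_id"].map(rank))
                .sort_values(["_k", "day"]).drop(columns="_k")
                .reset_index(drop=True))

    def run(df, seed):
        return sdr_estimate(df, NEVER, ["saturated"], 5,
                            g_learners=["saturated"],
                            features=DISCRETE_FEATURES, seed=seed,
                            horizon=dconfig.horizon)

    a, b, c = run(coh, 1), run(shuffled, 1), run(coh, 99)
    assert abs(a.estimate - b.estimate) <= max(a.se, b.se)
    assert abs(a.estimate - c.estimate) <= max(a.se, c.se)


def test_sdr_error_shrinks_with_sample_size(dconfig):
    """Consistency: root-mean-squared error against the enumerated truth
    drops as the cohort grows."""
    theta = (enumerate_truth(dconfig, DYNAMIC)
             - enumerate_truth(dconfig, NEVER))
    errs = {400: [], 6000: []}
    for rep in range(12):
        for n in errs:
            coh = simulate_discrete_cohort(dconfig, n, seed=9000 + rep)
            ests = {}
            for regime in (DYNAMIC, NEVER):
                nus = fit_nuisances(coh, regime, 2, g_learners=["saturated"],
                                    m_learners=["saturated"],
                                    features=DISCRETE_FEATURES, seed=rep,
                                    horizon=dconfig.horizon)
                ests[regime.kind] = sdr_estimate(coh, regime, ["saturated"],
                                                 2, nuisances=nus, seed=rep)
            rd = (ests["dynamic_steroids"].estimate
                  - ests["never_treat"].estimate)
            errs[n].append(rd - theta)
    rmse = {n: float(np.sqrt(np.mean(np.square(e)))) for n, e in errs.items()}
    assert rmse[6000] < rmse[400]


class TestContrast:
    def make(self, p, method="sdr", n=100, eif=None):
        return EstimateResult("risk_dynamic", method, p, 0.01,
                              p - 0.02, p + 0.02, n, 2, eif=eif)

    def test_printed_rates_reproduce_reported_effect_measures(self):
        rt, rc = self.make(0.257), self.make(0.322)
        assert contrast(rt, rc, "odds_ratio").estimate == pytest.approx(
            0.73, abs=0.005)
        assert contrast(rt, rc, "difference").estimate == pytest.approx(
            -0.065, abs=1e-12)

    def test_equal_risks_are_null_on_every_scale(self):
        rt, rc = self.make(0.3), self.make(0.3)
        assert contrast(rt, rc, "difference").estimate == 0.0
        assert contrast(rt, rc, "ratio").estimate == 1.0
        assert contrast(rt, rc, "odds_ratio").estimate == 1.0

    def test_eif_difference_variance_used_when_available(self):
        rng = np.random.default_rng(2)
        e1, e2 = rng.normal(size=100), rng.normal(size=100)
        rt = self.make(0.3, eif=e1)
        rc = self.make(0.25, eif=e2)
        c = contrast(rt, rc, "difference")
        assert c.se == pytest.approx(np.std(e1 - e2) / 10, rel=0.02)

    def test_mismatched_methods_and_boundary_risks_rejected(self):
        with pytest.raises(ValueError):
            contrast(self.make(0.3, "sdr"), self.make(0.2, "ipw"))
        with pytest.raises(ValueError):
            contrast(self.make(0.0), self.make(0.2), "ratio")
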