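"""Synthetic cohort generator: determinism, absorption, confounding, truth."""

import numpy as np
import pandas as pd
import pytest

from ttemu import (DGPConfig, DYNAMIC, NEVER, counterfactual_risk_mc,
                   naive_exposure_contrast, simulate_cohort, validate_cohort)


def test_fixed_seed_reproduces_cohort_exactly():
    cfg = DGPConfig(n_patients=300, seed=7)
    a = simulate_cohort(cfg)
    b = simulate_cohort(DGPConfig(n_patients=300, seed=7))
    pd.testing.assert_frame_equal(a, b)
    c = simulate_cohort(DGPConfig(n_patients=300, seed=8))
    assert not a.equals(c)


def test_growing_cohort_preserves_existing_patients():
    small = simulate_cohort(DGPConfig(n_patients=150, seed=3))
    big = simulate_cohort(DGPConfig(n_patients=400, seed=3))
    head = big[big["patient_id"] < 150].reset_index(drop=True)
    pd.testing.assert_frame_equal(small, head)


def test_cohort_satisfies_person_day_invariants(small_cohort):
    validate_cohort(small_cohort, horizon=28)
    # death and discharge absorbing, never simultaneous
    assert not ((small_cohort["death"] == 1) & (small_cohort["censor"] == 1)).any()


def test_never_treat_forced_by_degenerate_propensity():
    cfg = DGPConfig(n_patients=200, seed=1)
    cfg.treat_propensity_coefs["intercept"] = -np.inf
    coh = simulate_cohort(cfg)
    assert (coh["treat"] == 0).all()


def test_no_absorbing_events_gives_full_follow_up():
    cfg = DGPConfig(n_patients=100, seed=2, horizon=10)
    cfg.death_hazard_coefs["intercept"] = -np.inf
    cfg.discharge_hazard_coefs["intercept"] = -np.inf
    coh = simulate_cohort(cfg)
    assert (coh.groupby("patient_id").size() == 10).all()
    assert (coh["death"] == 0).all() and (coh["censor"] == 0).all()


def test_nan_coefficient_rejected():
    with pytest.raises(ValueError):
        DGPConfig(treatment_effect=float("nan"))
    cfg = DGPConfig()
    cfg.severity_coefs["ar"] = float("inf")
    with pytest.raises(ValueError):
        cfg.validate()


def test_null_effect_gives_identical_counterfactual_worlds():
    """With treatment_effect = 0 no downstream node responds to treatment,
    so the two regimes produce the same deaths draw for draw."""
    cfg = DGPConfig(n_patients=1, treatment_effect=0.0)
    r1 = counterfactual_risk_mc(cfg, DYNAMIC, 20000, seed=11)
    r0 = counterfactual_risk_mc(cfg, NEVER, 20000, seed=11)
    assert r1.risk == r0.risk


def test_protective_effect_lowers_counterfactual_risk():
    cfg = DGPConfig()
    r1 = counterfactual_risk_mc(cfg, DYNAMIC, 60000, seed=21)
    r0 = counterfactual_risk_mc(cfg, NEVER, 60000, seed=22)
    se = np.hypot(r1.se, r0.se)
    assert r1.risk < r0.risk - 3 * se


def test_treatment_goes_to_sicker_patients_confounding_is_real():
    """The crude ever- vs never-treated mortality contrast has the opposite
    sign of the true protective counterfactual contrast."""
    cfg = DGPConfig(n_patients=4000, seed=9)
    naive = naive_exposure_contrast(simulate_cohort(cfg))
    r1 = counterfactual_risk_mc(cfg, DYNAMIC, 60000, seed=31)
    r0 = counterfactual_risk_mc(cfg, NEVER, 60000, seed=32)
    truth = r1.risk - r0.risk
    assert truth < 0
    se = np.hypot(r1.se, r0.se)
    assert naive["difference"] - truth > 3 * se
    assert naive["difference"] > 0  # sicker patients get treated and die more
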