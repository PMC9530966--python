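"""Model-first design construction and Cox fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ttemu import (DGPConfig, TABLE1_DESIGNS, construct_design_dataset,
                   expand_time_varying, fit_cox, run_all_designs,
                   simulate_cohort)
from ttemu.cox_designs import CoxDesignSpec, CoxFitError


def build_cohort(patients):
    """patients: list of dicts with keys days, hyp (set), treat (set),
    death_day, censor_day."""
    rows = []
    for pid, p in enumerate(patients):
        for d in range(p["days"]):
            rows.append({
                "patient_id": pid, "day": d, "age": p.get("age", 0.0),
                "sex": 0, "comorbid": 0, "severity": float(d in p["hyp"]),
                "hypoxia": int(d in p["hyp"]), "measured": 1,
                "treat": int(d in p["treat"]),
                "death": int(d == p.get("death_day", -1)),
                "censor": int(d == p.get("censor_day", -1)),
            })
    return pd.DataFrame(rows)


class TestDesignConstruction:
    def test_anytime_exposure_classifies_late_treatment_as_exposed(self):
        # hypoxia day 2, treated day 10: design A exposed, design B control
        coh = build_cohort([
            dict(days=15, hyp={2}, treat={10}),
            dict(days=15, hyp={2}, treat=set()),
        ])
        recs_a, _ = construct_design_dataset(coh, TABLE1_DESIGNS["A"])
        recs_b, _ = construct_design_dataset(coh, TABLE1_DESIGNS["B"])
        assert recs_a.set_index("patient_id")["exposed"].tolist() == [1, 0]
        assert recs_b.set_index("patient_id")["exposed"].tolist() == [0, 0]

    def test_deaths_inside_window_excluded_and_logged(self):
        # untreated death 2 days after hypoxia: excluded by G (5-day window)
        coh = build_cohort([
            dict(days=5, hyp={2}, treat=set(), death_day=4),
            dict(days=20, hyp={2}, treat={3}),
        ])
        recs, log = construct_design_dataset(coh, TABLE1_DESIGNS["G"])
        assert log["excluded_died_in_window"] == 1
        assert recs["patient_id"].tolist() == [1]

    def test_pretreated_patients_excluded(self):
        # treated the day before hypoxia: excluded by H
        coh = build_cohort([
            dict(days=20, hyp={5}, treat={4}),
            dict(days=20, hyp={5}, treat={6}),
        ])
        recs, log = construct_design_dataset(coh, TABLE1_DESIGNS["H"])
        assert log["excluded_pretreated"] == 1
        assert recs["patient_id"].tolist() == [1]

    def test_late_treatment_censored_under_design_e(self):
        # treated day 8 after hypoxia day 2 (window ends day 3): censored at 8
        coh = build_cohort([
            dict(days=20, hyp={2}, treat={8}, death_day=15),
            dict(days=20, hyp={2}, treat={2}),
        ])
        recs, log = construct_design_dataset(coh, TABLE1_DESIGNS["E"])
        r0 = recs.set_index("patient_id").loc[0]
        assert r0["event"] == 0 and r0["duration"] == 8 - 2 + 1
        assert log["censored_at_late_treatment"] == 1
        assert recs.set_index("patient_id").loc[1, "exposed"] == 1

    def test_exclusion_accounting_balances(self, small_cohort):
        for did in "ABCDEFGHI":
            _, log = construct_design_dataset(small_cohort,
                                              TABLE1_DESIGNS[did])
            excluded = sum(v for k, v in log.items()
                           if k.startswith("excluded_"))
            assert log["patients_in"] == log["patients_analyzed"] + excluded

    def test_time_varying_spec_rejected_here(self, small_cohort):
        with pytest.raises(ValueError):
            construct_design_dataset(small_cohort, TABLE1_DESIGNS["J"])


class TestCountingProcess:
    def test_person_day_expansion_row_count_and_coding(self):
        coh = build_cohort([dict(days=6, hyp={1}, treat={2, 3, 4}),
                            dict(days=3, hyp=set(), treat=set())])
        recs = expand_time_varying(coh)
        assert len(recs) == 9  # one row per person-day at risk
        p0 = recs[recs["patient_id"] == 0]
        assert p0["exposed"].tolist() == [0, 0, 1, 1, 1, 0]
        assert (p0["stop"] - p0["start"] == 1).all()

    def test_ever_exposed_coding(self):
        coh = build_cohort([dict(days=5, hyp=set(), treat={2})])
        recs = expand_time_varying(coh, ever_exposed=True)
        assert recs["exposed"].tolist() == [0, 0, 1, 1, 1]


class TestCoxFit:
    def hand_data(self):
        return pd.DataFrame({
            "patient_id": range(6),
            "duration": [1.0, 2.5, 3.0, 4.2, 5.0, 6.1],
            "event": [1, 1, 0, 1, 1, 0],
            "exposed": [1, 0, 1, 1, 0, 0],
        })

    def test_matches_hand_partial_likelihood(self):
        """No ties: the exposure coefficient must equal the maximiser of the
        hand-written Cox partial likelihood."""
        df = self.hand_data()

        def neg_pl(beta):
            order = np.argsort(df["duration"].to_numpy())
            t = df["duration"].to_numpy()[order]
            e = df["event"].to_numpy()[order]
            x = df["exposed"].to_numpy()[order]
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    riskset = x[i:]
                    ll += beta * x[i] - np.log(np.exp(beta * riskset).sum())
            return -ll

        beta_hand = minimize_scalar(neg_pl, bounds=(-4, 4),
                                    method="bounded").x
        fit = fit_cox(df, covariates=[])
        assert fit.coef == pytest.approx(beta_hand, abs=1e-5)
        fit_b = fit_cox(df, covariates=[], ties="breslow")
        assert fit_b.coef == pytest.approx(beta_hand, abs=1e-4)

    def test_wald_interval_covers_true_hazard_ratio(self):
        """Two-group exponential survival with true HR 2."""
        rng = np.random.default_rng(7)
        covered = 0
        reps = 20
        for _ in range(reps):
            n = 1000
            x = rng.integers(0, 2, n)
            t = rng.exponential(1.0 / np.where(x == 1, 2.0, 1.0))
            c = rng.exponential(2.0, n)
            df = pd.DataFrame({"patient_id": range(n),
                               "duration": np.minimum(t, c),
                               "event": (t <= c).astype(int), "exposed": x})
            fit = fit_cox(df, covariates=[])
            covered += fit.ci_low <= 2.0 <= fit.ci_high
        assert covered >= reps * 0.8

    def test_null_exposure_gives_unit_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 800
        df = pd.DataFrame({"patient_id": range(n),
                           "duration": rng.exponential(1.0, n),
                           "event": 1,
                           "exposed": rng.integers(0, 2, n)})
        fit = fit_cox(df, covariates=[])
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_degenerate_inputs_raise_distinctly(self):
        df = self.hand_data()
        with pytest.raises(CoxFitError):
            fit_cox(df.assign(event=0), covariates=[])
        with pytest.raises(CoxFitError):
            fit_cox(df.assign(exposed=1), covariates=[])
        # complete separation: exposure perfectly predicts early events
        sep = pd.DataFrame({"patient_id": range(40),
                            "duration": np.r_[np.full(20, 1.0),
                                              np.full(20, 10.0)],
                            "event": np.r_[np.ones(20), np.zeros(20)],
                            "exposed": np.r_[np.ones(20), np.zeros(20)]})
        with pytest.raises(CoxFitError):
            fit_cox(sep, covariates=[])

    def test_invalid_spec_combination_rejected(self):
        with pytest.raises(ValueError):
            CoxDesignSpec("X", 3)


def test_run_all_designs_emits_full_forest_table(small_cohort):
    tab = run_all_designs(small_cohort, "ABFJ")
    assert tab["design"].tolist() == list("ABFJ")
    ok = tab[tab["error"] == ""]
    assert len(ok) >= 3
    assert (ok["hr"] > 0).all()
    assert (ok["ci_low"] <= ok["hr"]).all() and (ok["hr"] <= ok["ci_high"]).all()
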