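"""Replicated simulation studies of estimator behaviour.

These are the package's standard experiments: parameter recovery of the
counterfactual risk difference by the sequentially doubly robust (SDR)
estimator against a Monte-Carlo truth, the double-robustness contrast with
singly robust estimators under deliberate nuisance misspecification, and
the immortal-time-bias demonstration for the model-first Cox designs under
a null treatment effect. The acceptance script and the acceptance test
suite both drive these functions.

Problem sizes used by the standard studies (kept moderate so a full run
completes in a few minutes on one core) are recorded in docs/methods.md.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import DGPConfig
from .cox_designs import run_all_designs
from .discrete import DiscreteDGPConfig, enumerate_truth, simulate_discrete_cohort
from .estimators import (contrast, estimate_risk_difference, fit_nuisances,
                         gcomp_estimate, ipw_estimate, sdr_estimate)
from .regimes import DYNAMIC, NEVER
from .simulate import counterfactual_risk_mc, simulate_cohort

__all__ = ["mc_truth", "parameter_recovery_study", "misspecification_study",
           "null_design_study", "DISCRETE_FEATURES"]

#: history features that saturate the discrete replica's state space
DISCRETE_FEATURES = ["severity", "prev_treat", "ever_treat_prev", "hyp_seen"]


def _sub_seeds(seed: int, k: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed)).generate_state(k) % (2 ** 31)


def mc_truth(config: DGPConfig, n_mc: int, seed: int) -> dict:
    """Counterfactual risks under both regimes and their difference."""
    s1, s0 = _sub_seeds(seed, 2)
    r1 = counterfactual_risk_mc(config, DYNAMIC, n_mc, int(s1))
    r0 = counterfactual_risk_mc(config, NEVER, n_mc, int(s0))
    return {"risk_dynamic": r1.risk, "risk_never": r0.risk,
            "risk_difference": r1.risk - r0.risk,
            "mc_se": float(np.hypot(r1.se, r0.se)), "n_mc": n_mc}


def parameter_recovery_study(config: DGPConfig, n_reps: int = 50,
                             n_patients: int = 5000, seed: int = 0,
                             v_folds: int = 5,
                             learners=("linear_additive",),
                             method: str = "sdr") -> pd.DataFrame:
    """Replicated estimation of the risk difference on fresh cohorts.

    Returns one row per replicate with the estimate, its EIF standard error
    and the 95% CI; compare against :func:`mc_truth` for bias, z-scores and
    coverage.
    """
    rows = []
    for rep, rs in enumerate(_sub_seeds(seed, n_reps)):
        cohort = simulate_cohort(config.replace(seed=int(rs),
                                                n_patients=n_patients))
        res = estimate_risk_difference(cohort, method=method,
                                       learners=tuple(learners),
                                       v_folds=v_folds, seed=int(rs),
                                       horizon=config.horizon)
        rd = res["risk_difference"]
        rows.append({"replicate": rep, "estimate": rd.estimate, "se": rd.se,
                     "ci_low": rd.ci_low, "ci_high": rd.ci_high,
                     "risk_dynamic": res["dynamic_steroids"].estimate,
                     "risk_never": res["never_treat"].estimate})
    return pd.DataFrame(rows)


def misspecification_study(dconfig: DiscreteDGPConfig | None = None,
                           n_reps: int = 50, n_patients: int = 4000,
                           seed: int = 0, v_folds: int = 5) -> pd.DataFrame:
    """Double robustness under deliberate nuisance misspecification.

    Run on the discrete replica of the cohort process, whose exact
    counterfactual truth comes from enumeration and whose three-day horizon
    keeps adherence weights bounded, so the comparison isolates estimator
    properties. Two scenarios per replicate:

    * outcome models replaced by intercept-only (treatment/censoring models
      correctly specified): SDR vs the singly robust g-computation;
    * treatment/censoring models replaced by intercept-only (outcome models
      correctly specified): SDR vs the singly robust IPW.

    Returns a tidy frame (replicate, scenario, estimator, estimate, se).
    """
    dc = DiscreteDGPConfig() if dconfig is None else dconfig
    theta = enumerate_truth(dc, DYNAMIC) - enumerate_truth(dc, NEVER)
    rows = []
    for rep, rs in enumerate(_sub_seeds(seed, n_reps)):
        coh = simulate_discrete_cohort(dc, n_patients, int(rs))
        per = {}
        for regime in (DYNAMIC, NEVER):
            nus_g = fit_nuisances(coh, regime, v_folds,
                                  g_learners=["saturated"],
                                  m_learners=["intercept_only"],
                                  features=DISCRETE_FEATURES, seed=rep,
                                  horizon=dc.horizon)
            per[regime.kind, "sdr_mis_outcome"] = sdr_estimate(
                coh, regime, ["intercept_only"], v_folds, nuisances=nus_g,
                seed=rep)
            per[regime.kind, "gcomp_mis_outcome"] = gcomp_estimate(
                coh, regime, nus_g)
            nus_b = fit_nuisances(coh, regime, v_folds,
                                  g_learners=["intercept_only"],
                                  m_learners=["saturated"],
                                  features=DISCRETE_FEATURES, seed=rep,
                                  horizon=dc.horizon)
            per[regime.kind, "sdr_mis_treatment"] = sdr_estimate(
                coh, regime, ["saturated"], v_folds, nuisances=nus_b,
                seed=rep)
            per[regime.kind, "ipw_mis_treatment"] = ipw_estimate(
                coh, regime, nus_b)
        for est in ("sdr_mis_outcome", "gcomp_mis_outcome",
                    "sdr_mis_treatment", "ipw_mis_treatment"):
            c = contrast(per["dynamic_steroids", est],
                         per["never_treat", est], "difference")
            rows.append({"replicate": rep, "estimator": est,
                         "estimate": c.estimate, "se": c.se,
                         "error": c.estimate - theta,
                         "covered": bool(c.ci_low <= theta <= c.ci_high)})
    out = pd.DataFrame(rows)
    out.attrs["theta"] = theta
    return out


def null_design_study(config: DGPConfig | None = None, n_reps: int = 50,
                      n_patients: int = 2000, designs: str = "ABF",
                      seed: int = 0) -> pd.DataFrame:
    """Model-first design HRs under a sharp null treatment effect.

    Any systematic departure of a design's hazard ratio from 1 is pure
    design bias (immortal time, selection, or feedback). Returns a tidy
    frame (replicate, design, hr).
    """
    cfg = (DGPConfig() if config is None else config).replace(
        treatment_effect=0.0)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep, rs in enumerate(_sub_seeds(seed, n_reps)):
            coh = simulate_cohort(cfg.replace(seed=int(rs),
                                              n_patients=n_patients))
            tab = run_all_designs(coh, designs)
            for _, row in tab.iterrows():
                if row["error"] == "":
                    rows.append({"replicate": rep, "design": row["design"],
                                 "hr": row["hr"], "ci_low": row["ci_low"],
                                 "ci_high": row["ci_high"]})
    return pd.DataFrame(rows)
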