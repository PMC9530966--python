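"""A finite-state replica of the cohort process, small enough to enumerate.

Severity is binary (1 = severe hypoxia day), there are no baseline
covariates, and every hazard is a logistic function of the current state,
so counterfactual risks under any regime can be computed *exactly* by
summing over all trajectories. This is the independent oracle against
which the Monte-Carlo simulator and the causal estimators are checked.

As in the continuous generator, every treatment pathway (death hazard and
severity transition) is scaled by ``treatment_effect`` so that a zero
effect is a sharp null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import CH, uniforms
from .regimes import Regime

__all__ = [
    "DiscreteDGPConfig", "enumerate_truth",
    "enumerate_observational_cohort", "simulate_discrete_cohort",
    "discrete_true_g",
]


@dataclass
class DiscreteDGPConfig:
    horizon: int = 3
    p_sev0: float = 0.5
    #: logit of P(S_{t+1} = 1 | S_t = s), before the treatment shift
    trans_logit: tuple = (-0.8, 0.8)
    #: severity-transition log-odds shift is ``trans_treat_scale * treatment_effect``
    trans_treat_scale: float = 0.5
    #: P(A_t = 1 | S_t = s), the observational propensity
    p_treat: tuple = (0.15, 0.5)
    #: logit of the daily death hazard given S_t = s
    death_logit: tuple = (-2.5, -1.2)
    #: P(discharge | survived the day, S_t = s)
    p_discharge: tuple = (0.25, 0.05)
    #: log-odds shift on the death hazard once ever treated (0 = sharp null)
    treatment_effect: float = -0.7
    #: refuse enumeration beyond this many severity paths
    max_paths: int = 4096

    def validate(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for name in ("p_sev0",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for pair in (self.p_treat, self.p_discharge):
            if not all(0.0 <= p <= 1.0 for p in pair):
                raise ValueError("probabilities must lie in [0, 1]")

    def p_trans(self, s: int, a: int) -> float:
        return float(expit(self.trans_logit[s]
                           + self.trans_treat_scale * self.treatment_effect * a))

    def p_death(self, s: int, recent_treat: bool) -> float:
        return float(expit(self.death_logit[s]
                           + self.treatment_effect * bool(recent_treat)))


def enumerate_truth(config: DiscreteDGPConfig, regime: Regime) -> float:
    """Exact counterfactual death probability by the horizon under ``regime``.

    Sums over all severity trajectories with discharge disabled and treatment
    forced by the rule; deterministic. Restricted to short horizons (every
    treated day still shifts the hazard at the end of follow-up, i.e. the
    horizon must not exceed the treatment-memory window of 6 days).
    """
    config.validate()
    if config.horizon > 6:
        raise ValueError("enumeration supports horizon <= 6")
    if 2 ** config.horizon > config.max_paths:
        raise ValueError("state space exceeds max_paths cap")

    cache: dict = {}

    def risk(t: int, s: int, first_hyp: int, ever: bool) -> float:
        if s == 1 and first_hyp < 0:
            first_hyp = t
        key = (t, s, first_hyp, ever)
        if key in cache:
            return cache[key]
        if regime.kind == "never_treat":
            a = 0
        else:
            a = int(first_hyp >= 0 and first_hyp <= t < first_hyp + regime.duration_days)
        ever2 = ever or bool(a)
        h = config.p_death(s, ever2)
        if t == config.horizon - 1:
            cache[key] = h
            return h
        p1 = config.p_trans(s, a)
        out = h + (1.0 - h) * (p1 * risk(t + 1, 1, first_hyp, ever2)
                               + (1.0 - p1) * risk(t + 1, 0, first_hyp, ever2))
        cache[key] = out
        return out

    p0 = config.p_sev0
    return p0 * risk(0, 1, -1, False) + (1.0 - p0) * risk(0, 0, -1, False)


def enumerate_observational_cohort(config: DiscreteDGPConfig,
                                   min_weight: float = 0.0) -> pd.DataFrame:
    """Every observational trajectory as one pseudo-patient, weighted by its
    exact probability.

    On this "population cohort" empirical (weighted) conditional means equal
    the true ones, so saturated-model estimators must reproduce
    :func:`enumerate_truth` to numerical precision — the backbone of the
    oracle-equivalence tests. Weights sum to 1 up to trajectories pruned
    below ``min_weight``.
    """
    config.validate()
    rows: list[dict] = []
    pid = [0]

    def emit(traj: list, prob: float) -> None:
        for r in traj:
            rows.append(dict(patient_id=pid[0], weight=prob, **r))
        pid[0] += 1

    def walk(t: int, s: int, ever: bool, traj: list, prob: float) -> None:
        if prob <= min_weight:
            return
        for a, pa in ((1, config.p_treat[s]), (0, 1.0 - config.p_treat[s])):
            if pa <= 0.0:
                continue
            ever2 = ever or bool(a)
            pd_ = config.p_death(s, ever2)
            base = dict(day=t, age=0.0, sex=0, comorbid=0, severity=float(s),
                        hypoxia=s, measured=1, treat=a)
            # death ends the day
            emit(traj + [dict(base, death=1, censor=0)], prob * pa * pd_)
            p_alive = prob * pa * (1.0 - pd_)
            pc = config.p_discharge[s]
            if t == config.horizon - 1:
                emit(traj + [dict(base, death=0, censor=0)], p_alive)
                continue
            if pc > 0.0:
                emit(traj + [dict(base, death=0, censor=1)], p_alive * pc)
            p_stay = p_alive * (1.0 - pc)
            if p_stay <= 0.0:
                continue
            p1 = config.p_trans(s, a)
            step = traj + [dict(base, death=0, censor=0)]
            if p1 > 0.0:
                walk(t + 1, 1, ever2, step, p_stay * p1)
            if p1 < 1.0:
                walk(t + 1, 0, ever2, step, p_stay * (1.0 - p1))

    if config.p_sev0 > 0.0:
        walk(0, 1, False, [], config.p_sev0)
    if config.p_sev0 < 1.0:
        walk(0, 0, False, [], 1.0 - config.p_sev0)

    df = pd.DataFrame(rows)
    return df.sort_values(["patient_id", "day"]).reset_index(drop=True)


def simulate_discrete_cohort(config: DiscreteDGPConfig, n: int,
                             seed: int) -> pd.DataFrame:
    """Sample ``n`` observational patients from the discrete process."""
    config.validate()
    ids = np.arange(n, dtype=np.uint64)
    s = (uniforms(seed, ids, 0, CH.SEV0) < config.p_sev0).astype(np.int8)
    active = np.ones(n, dtype=bool)
    ever = np.zeros(n, dtype=bool)
    recs = []
    for t in range(config.horizon):
        pa = np.asarray(config.p_treat)[s]
        a = (uniforms(seed, ids, t, CH.TREAT) < pa) & active
        ever = ever | a
        p_die = expit(np.asarray(config.death_logit)[s]
                      + config.treatment_effect * ever)
        die = (uniforms(seed, ids, t, CH.DEATH) < p_die) & active
        pc = np.asarray(config.p_discharge)[s]
        disc = (uniforms(seed, ids, t, CH.DISCHARGE) < pc) & active & ~die
        if t == config.horizon - 1:
            disc[:] = False
        recs.append(dict(day=t, sev=s.copy(), a=a.copy(), die=die.copy(),
                         disc=disc.copy(), active=active.copy()))
        active = active & ~die & ~disc
        p1 = expit(np.asarray(config.trans_logit)[s]
                   + config.trans_treat_scale * config.treatment_effect * a)
        s = (uniforms(seed, ids, t + 1, CH.SEV_NOISE) < p1).astype(np.int8)

    frames = []
    for r in recs:
        m = r["active"]
        frames.append(pd.DataFrame({
            "patient_id": ids[m].astype(np.int64), "day": r["day"],
            "age": 0.0, "sex": 0, "comorbid": 0,
            "severity": r["sev"][m].astype(float), "hypoxia": r["sev"][m],
            "measured": 1, "treat": r["a"][m].astype(np.int8),
            "death": r["die"][m].astype(np.int8),
            "censor": r["disc"][m].astype(np.int8),
        }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["patient_id", "day"]).reset_index(drop=True)


def discrete_true_g(config: DiscreteDGPConfig, cohort: pd.DataFrame,
                    regime: Regime) -> tuple[np.ndarray, np.ndarray]:
    """True per-day nuisance probabilities for a discrete cohort.

    Returns (pA, pC) matrices aligned with the patient-by-day panel built by
    the estimators: pA is the treatment probability P(A_t = 1 | S_t) — the
    estimators flip it to the regime arm themselves — and pC is
    P(remain uncensored | survived day t, S_t) (1 on death days). The
    ``regime`` argument fixes the panel horizon/shape convention only.
    """
    from .estimators import Panel  # local import: estimators does not import us

    panel = Panel.from_cohort(cohort)
    s_idx = panel.feat["severity"].astype(int)
    pA = np.asarray(config.p_treat, dtype=float)[s_idx]
    pC = 1.0 - np.asarray(config.p_discharge, dtype=float)[s_idx]
    pC = np.where(panel.died, 1.0, pC)
    pA[~panel.present] = 0.5
    pC[~panel.present] = 1.0
    return pA, pC
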