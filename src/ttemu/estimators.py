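"""Longitudinal g-formula estimators for the emulated trial.

Estimates the counterfactual 28-day mortality risk under a treatment
regime — "assign treatment by the rule and prevent loss to follow-up" —
from an observational person-day cohort, by three routes:

* ``gcomp``  — iterated-conditional-expectation (ICE) g-computation:
  backward regressions of the next stage's value on history, evaluated
  with treatment set to the rule;
* ``ipw``    — inverse probability of treatment-and-censoring weighting
  (Horvitz–Thompson form);
* ``sdr``    — the sequentially doubly robust estimator: the backward
  recursion regresses doubly robust pseudo-outcomes

  .. math::

      \\phi_t = r_t\\,(\\text{target}_t - m_t(H_t, A_t))
               + m_t(H_t, d_t(H_t)), \\qquad
      r_t = \\frac{1\\{A_t = d_t\\}\\,1\\{\\text{uncensored}\\}}
                 {g^A_t\\, g^C_t},

  so the fit at time ``t`` is consistent if *either* the later outcome
  regressions *or* the treatment/censoring models are correct. The point
  estimate is the mean of :math:`\\phi_0` and the standard error is the
  sample standard deviation of the efficient-influence-function values
  :math:`\\phi_0 - \\hat\\psi` divided by :math:`\\sqrt n`.

All nuisance regressions are fit per day, cross-fit over patient-level
folds, with an optional super-learner library; fitted probabilities are
trimmed away from 0 and 1, and IPW products are capped at an upper
quantile. Per-patient frequency weights are honoured throughout so the
estimators can run on exactly weighted "population cohorts".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .regimes import Regime
from .superlearner import LearnerSpec, _as_spec, _make, fit_superlearner

__all__ = [
    "Panel", "NuisanceFits", "EstimateResult",
    "fit_nuisances", "gcomp_estimate", "ipw_estimate", "sdr_estimate",
    "contrast", "estimate_risk_difference", "DEFAULT_FEATURES",
]

DEFAULT_FEATURES = ["age", "sex", "comorbid", "severity", "hypoxia",
                    "measured", "prev_treat", "recent_treat_prev",
                    "course_done_prev", "hyp_seen"]

_Z = float(norm.ppf(0.975))


# --------------------------------------------------------------------- panel
class Panel:
    """Person-day cohort reshaped to patient-by-day arrays."""

    def __init__(self, ids, present, A, C, died, feat, hyp, w, tau):
        self.ids = ids
        self.present = present        # (n, tau) at risk at start of day
        self.A = A                    # (n, tau) treatment
        self.C = C                    # (n, tau) censored at end of day
        self.died = died              # (n, tau) died during day
        self.feat = feat              # name -> (n,) baseline or (n, tau)
        self.hyp = hyp                # (n, tau)
        self.w = w                    # (n,) patient weights
        self.n, self.tau = present.shape
        self.died_ever = died.any(axis=1)

    @classmethod
    def from_cohort(cls, df: pd.DataFrame, horizon: int | None = None) -> "Panel":
        codes, uniq = pd.factorize(df["patient_id"], sort=False)
        day = df["day"].to_numpy(dtype=np.int64)
        n = len(uniq)
        tau = int(horizon if horizon is not None else day.max() + 1)
        flat = codes * tau + day

        def mat(col, dtype=float):
            out = np.zeros(n * tau, dtype=dtype)
            out[flat] = df[col].to_numpy()
            return out.reshape(n, tau)

        present = np.zeros(n * tau, dtype=bool)
        present[flat] = True
        present = present.reshape(n, tau)
        A = mat("treat", np.int8)
        C = mat("censor", np.int8)
        died = mat("death", np.int8).astype(bool)
        hyp = mat("hypoxia", np.int8)

        first_idx = np.zeros(n, dtype=np.int64)
        first_idx[codes[::-1]] = np.arange(len(df))[::-1]
        feat: dict = {}
        for col in ("age", "sex", "comorbid"):
            feat[col] = df[col].to_numpy(dtype=float)[first_idx]
        for col in ("severity", "hypoxia", "measured"):
            feat[col] = mat(col)
        # history-derived features, measurable at the start of each day
        prev = np.zeros((n, tau))
        prev[:, 1:] = A[:, :-1]
        feat["prev_treat"] = prev
        everp = np.zeros((n, tau))
        everp[:, 1:] = np.cumsum(A[:, :-1], axis=1) > 0
        feat["ever_treat_prev"] = everp
        recent = np.zeros((n, tau))
        for t in range(1, tau):  # any treatment in the previous 5 days
            recent[:, t] = A[:, max(0, t - 5):t].any(axis=1)
        feat["recent_treat_prev"] = recent
        cum_prev = np.zeros((n, tau))
        cum_prev[:, 1:] = np.cumsum(A[:, :-1], axis=1)
        feat["course_done_prev"] = (cum_prev >= 6).astype(float)
        feat["hyp_seen"] = (np.cumsum(hyp, axis=1) > 0).astype(float)

        if "weight" in df.columns:
            w = df["weight"].to_numpy(dtype=float)[first_idx]
        else:
            w = np.ones(n)
        return cls(uniq.to_numpy(), present, A, C, died, feat, hyp, w, tau)

    def X(self, t: int, features: list, treat_col: np.ndarray | None = None):
        cols = []
        for name in features:
            arr = self.feat[name]
            cols.append(arr if arr.ndim == 1 else arr[:, t])
        if treat_col is not None:
            cols.append(treat_col.astype(float))
        return np.column_stack(cols)


def _wmean(x, w):
    return float(np.average(x, weights=w))


def _wse(x, w):
    """SE of the weighted mean via effective sample size."""
    mu = np.average(x, weights=w)
    var = np.average((x - mu) ** 2, weights=w)
    n_eff = w.sum() ** 2 / np.maximum((w ** 2).sum(), 1e-300)
    return float(np.sqrt(var / max(n_eff, 1.0)))


def _fit_model(Xtr, ytr, wtr, learners, loss, seed, min_rows=12):
    """Fit a regression for one (day, fold) cell; returns a predict callable."""
    ytr = np.asarray(ytr, dtype=float)
    if len(ytr) < min_rows or np.ptp(ytr) == 0.0:
        c = _wmean(ytr, wtr) if len(ytr) else 0.0
        return lambda X: np.full(len(X), c)
    try:
        if len(learners) == 1:
            m = _make(_as_spec(learners[0], loss)).fit(Xtr, ytr, wtr)
            return m.predict
        sl = fit_superlearner(Xtr, ytr, learners, v_folds=5, loss=loss,
                              sample_weight=wtr, seed=seed)
        return sl.predict
    except Exception:
        c = _wmean(ytr, wtr)
        return lambda X: np.full(len(X), c)


# ----------------------------------------------------------------- nuisances
@dataclass
class EstimateResult:
    estimand_label: str
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    folds: int
    eif: np.ndarray | None = field(default=None, repr=False)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            self.ci_low, self.ci_high = self.ci_high, self.ci_low

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("estimand_label", "method", "estimate", "se",
                 "ci_low", "ci_high", "n", "folds", "warnings")}


@dataclass
class NuisanceFits:
    """Cross-fitted nuisance quantities for one cohort and regime."""

    panel: Panel
    regime: Regime
    d: np.ndarray                 # (n, tau) rule assignment from observed history
    pA: np.ndarray                # (n, tau) fitted P(A_t = 1 | H_t), trimmed
    pC: np.ndarray                # (n, tau) fitted P(uncensored | survived, H_t, A_t)
    m_nat: np.ndarray             # ICE outcome fits at the observed treatment
    m_reg: np.ndarray             # ICE outcome fits at the rule's treatment
    tgt: np.ndarray               # ICE regression targets per stage
    folds: np.ndarray
    v_folds: int
    trim: float
    weight_cap_quantile: float
    features: list
    warnings: list = field(default_factory=list)

    def gA(self, d: np.ndarray | None = None) -> np.ndarray:
        d = self.d if d is None else d
        return np.where(d == 1, self.pA, 1.0 - self.pA)

    def gC_eff(self) -> np.ndarray:
        return np.where(self.panel.died, 1.0, self.pC)

    def ratios(self, d: np.ndarray | None = None):
        """Per-day ratio r_t and cumulative product omega_t (zero after
        non-adherence or censoring; frozen after exit), with the cumulative
        products capped at the configured upper quantile day by day."""
        p = self.panel
        d = self.d if d is None else d
        return _ratio_mats(p, d, self.gA(d), self.gC_eff(),
                           self.weight_cap_quantile)


def _ratio_mats(panel, d, gA, gC_eff, cap_q):
    """Adherence/censoring ratios and their capped cumulative products.

    r_t = 1{A_t = d_t} 1{kept} / (gA_t gC_t) per at-risk day; omega_t is the
    running product, capped day by day at its ``cap_q`` quantile among
    positive values (spec: trimming acts on the cumulative weight products,
    which otherwise grow without bound over a 28-day horizon). The returned
    per-day ratios are consistent with the capped products, so the backward
    recursion and the weight products agree.
    """
    p = panel
    adh = (p.A == d)
    keep = p.died | (p.C == 0)
    r_raw = np.where(p.present, adh * keep / (gA * gC_eff), 1.0)
    omega = np.ones_like(r_raw)
    r_eff = np.ones_like(r_raw)
    cur = np.ones(p.n)
    for t in range(p.tau):
        new = np.where(p.present[:, t], cur * r_raw[:, t], cur)
        if cap_q < 1.0:
            pos = new[p.present[:, t] & (new > 0)]
            if pos.size:
                cap = np.quantile(pos, cap_q)
                new = np.minimum(new, cap)
        ratio = np.divide(new, cur, out=np.zeros_like(new), where=cur > 0)
        r_eff[:, t] = np.where(p.present[:, t] & (cur > 0), ratio,
                               np.where(p.present[:, t], 0.0, 1.0))
        omega[:, t] = new
        cur = new
    return r_eff, omega


def _assign_folds(n: int, v: int, seed: int) -> np.ndarray:
    if v <= 1:
        return np.zeros(n, dtype=int)
    return np.random.default_rng(seed).permutation(n) % v


def _fit_g_probs(panel, folds, v, learners, features, trim, seed, warnings):
    n, tau = panel.n, panel.tau
    pA = np.full((n, tau), 0.5)
    pC = np.ones((n, tau))
    for t in range(tau):
        risk = panel.present[:, t]
        if not risk.any():
            warnings.append(f"day {t}: no at-risk patients; fit skipped")
            continue
        Xt = panel.X(t, features)
        XtA = panel.X(t, features, treat_col=panel.A[:, t])
        yA = panel.A[:, t].astype(float)
        surv = risk & ~panel.died[:, t]
        yC = 1.0 - panel.C[:, t].astype(float)
        for k in range(max(v, 1)):
            te = risk if v <= 1 else (risk & (folds == k))
            tr = risk if v <= 1 else (risk & (folds != k))
            if not te.any():
                continue
            f = _fit_model(Xt[tr], yA[tr], panel.w[tr],
                           learners, "log", seed + 13 * t + k)
            pA[te, t] = f(Xt[te])
            tec = te & surv
            trc = tr & surv
            if tec.any():
                fc = _fit_model(XtA[trc], yC[trc], panel.w[trc],
                                learners, "log", seed + 29 * t + k)
                pC[tec, t] = fc(XtA[tec])
    np.clip(pA, trim, 1.0 - trim, out=pA)
    np.clip(pC, trim, 1.0, out=pC)
    return pA, pC


def _backward(panel, d, folds, v, learners, features, dr, pA, pC, trim, seed,
              warnings, cap_q=0.999):
    """Shared ICE / SDR backward recursion.

    Each stage fits two regressions on at-risk rows: the discrete-time death
    hazard h_t (died during the day, fully observed) and the continuation
    value q_t (the next stage's pseudo-outcome among survivors who remained
    uncensored — valid because discharge is random given the modelled
    history). The stage value is m_t = h_t + (1 - h_t) q_t; a single pooled
    regression that simply drops censored rows would be selection-biased,
    since death precedes discharge within a day.

    Returns (phi, m_nat, m_reg, tgt): phi is the per-patient value after the
    final stage — ICE plug-in predictions when ``dr`` is False, doubly robust
    pseudo-outcomes when True.
    """
    n, tau = panel.n, panel.tau
    phi = np.zeros(n)
    m_nat = np.full((n, tau), np.nan)
    m_reg = np.full((n, tau), np.nan)
    tgt_s = np.full((n, tau), np.nan)
    if dr:
        gA_mat = np.where(d == 1, pA, 1.0 - pA)
        gC_mat = np.where(panel.died, 1.0, pC)
        r_eff, _ = _ratio_mats(panel, d, gA_mat, gC_mat, cap_q)
    for t in range(tau - 1, -1, -1):
        risk = panel.present[:, t]
        if not risk.any():
            continue
        died_t = panel.died[:, t]
        cont = risk & ~died_t & (panel.C[:, t] == 0)
        target = np.where(died_t, 1.0, phi)
        Xnat = panel.X(t, features, treat_col=panel.A[:, t])
        Xreg = panel.X(t, features, treat_col=d[:, t])
        hn = np.zeros(n)
        hr = np.zeros(n)
        qn = np.zeros(n)
        qr = np.zeros(n)
        ydie = died_t.astype(float)
        for k in range(max(v, 1)):
            te = risk if v <= 1 else (risk & (folds == k))
            trh = risk if v <= 1 else (risk & (folds != k))
            trq = cont if v <= 1 else (cont & (folds != k))
            if not te.any():
                continue
            fh = _fit_model(Xnat[trh], ydie[trh], panel.w[trh],
                            learners, "log", seed + 7 * t + k)
            hn[te] = fh(Xnat[te])
            hr[te] = fh(Xreg[te])
            fq = _fit_model(Xnat[trq], phi[trq], panel.w[trq],
                            learners, "squared", seed + 11 * t + k)
            qn[te] = fq(Xnat[te])
            qr[te] = fq(Xreg[te])
        hn = np.clip(hn, 0.0, 1.0)
        hr = np.clip(hr, 0.0, 1.0)
        qn = np.clip(qn, 0.0, 1.0)
        qr = np.clip(qr, 0.0, 1.0)
        mn = hn + (1.0 - hn) * qn
        mr = hr + (1.0 - hr) * qr
        if dr:
            new = r_eff[:, t] * (target - mn) + mr
        else:
            new = mr
        phi = np.where(risk, new, phi)
        m_nat[risk, t] = mn[risk]
        m_reg[risk, t] = mr[risk]
        tgt_s[risk, t] = target[risk]
    return phi, m_nat, m_reg, tgt_s


def fit_nuisances(cohort: pd.DataFrame, regime: Regime, v_folds: int = 10,
                  *, g_learners=("linear_additive",),
                  m_learners=("linear_additive",),
                  features: list | None = None, trim: float = 0.01,
                  weight_cap_quantile: float = 0.999, seed: int = 0,
                  known_pA: np.ndarray | None = None,
                  known_pC: np.ndarray | None = None,
                  horizon: int | None = None,
                  fit_ice: bool = True) -> NuisanceFits:
    """Cross-fit the treatment, censoring and ICE outcome regressions.

    ``known_pA``/``known_pC`` (patient-by-day arrays of P(A_t = 1 | H_t) and
    P(uncensored | survived, H_t)) bypass fitting — used to plug in true
    propensities in oracle checks.
    """
    panel = Panel.from_cohort(cohort, horizon=horizon)
    d = regime.assign_path(panel.hyp)
    folds = _assign_folds(panel.n, v_folds, seed)
    warnings: list = []
    features = list(DEFAULT_FEATURES if features is None else features)
    if known_pA is not None:
        pA = np.clip(np.asarray(known_pA, dtype=float), trim, 1 - trim)
        pC = (np.clip(np.asarray(known_pC, dtype=float), trim, 1.0)
              if known_pC is not None else np.ones((panel.n, panel.tau)))
    else:
        pA, pC = _fit_g_probs(panel, folds, v_folds, list(g_learners),
                              features, trim, seed, warnings)
    if fit_ice:
        _, m_nat, m_reg, tgt = _backward(panel, d, folds, v_folds,
                                         list(m_learners), features, False,
                                         pA, pC, trim, seed, warnings)
    else:
        m_nat = m_reg = tgt = np.full((panel.n, panel.tau), np.nan)
    return NuisanceFits(panel, regime, d, pA, pC, m_nat, m_reg, tgt, folds,
                        v_folds, trim, weight_cap_quantile, features, warnings)


def _risk_label(regime: Regime) -> str:
    return ("risk_dynamic" if regime.kind == "dynamic_steroids"
            else "risk_never")


def gcomp_estimate(cohort: pd.DataFrame, regime: Regime,
                   nuisances: NuisanceFits) -> EstimateResult:
    """ICE g-computation estimate with a one-step EIF standard error.

    The point estimate is the mean of the stage-0 outcome regression
    evaluated under the regime; the SE comes from the efficient influence
    function assembled around the ICE fits using the fitted propensities.
    """
    p = nuisances.panel
    m0 = nuisances.m_reg[:, 0]
    est = _wmean(m0, p.w)
    # one-step EIF around the ICE fits: sum_t omega_t (target_t - m_t(A_t))
    _, omega = nuisances.ratios()
    corr = np.zeros(p.n)
    for t in range(p.tau):
        risk = p.present[:, t]
        diff = np.where(risk, np.nan_to_num(nuisances.tgt[:, t])
                        - np.nan_to_num(nuisances.m_nat[:, t]), 0.0)
        corr += np.where(risk, omega[:, t] * diff, 0.0)
    eif = m0 + corr - est
    se = _wse(eif + est, p.w)
    return EstimateResult(_risk_label(regime), "gcomp",
                          float(np.clip(est, 0, 1)), se,
                          est - _Z * se, est + _Z * se, p.n,
                          nuisances.v_folds, eif=eif,
                          warnings=list(nuisances.warnings))


def ipw_estimate(cohort: pd.DataFrame, regime: Regime,
                 nuisances: NuisanceFits) -> EstimateResult:
    """Horvitz–Thompson inverse-probability-weighted estimate.

    Weight = cumulative product of adherence/censoring indicators over the
    fitted treatment and censoring probabilities, capped at the configured
    upper quantile; estimate = mean of weight x death indicator.
    """
    p = nuisances.panel
    _, omega = nuisances.ratios()
    exit_day = np.where(p.died_ever, p.died.argmax(axis=1),
                        p.present.sum(axis=1) - 1)
    w_exit = omega[np.arange(p.n), np.maximum(exit_day, 0)]
    if not (w_exit > 0).any():
        raise ValueError("all IPW weights are zero (no adherent patients)")
    score = w_exit * p.died_ever.astype(float)
    est = _wmean(score, p.w)
    se = _wse(score, p.w)
    return EstimateResult(_risk_label(regime), "ipw",
                          float(np.clip(est, 0, 1)), se,
                          est - _Z * se, est + _Z * se, p.n,
                          nuisances.v_folds, eif=score - est,
                          warnings=list(nuisances.warnings))


def sdr_estimate(cohort: pd.DataFrame, regime: Regime,
                 learners=("intercept_only", "linear_additive",
                           "gradient_boosted_trees"),
                 v_folds: int = 10, *, g_learners=None,
                 features: list | None = None, trim: float = 0.01,
                 seed: int = 0, nuisances: NuisanceFits | None = None,
                 horizon: int | None = None,
                 weight_cap_quantile: float = 0.999) -> EstimateResult:
    """Sequentially doubly robust estimate of the counterfactual risk.

    Cross-fits treatment/censoring models and the backward doubly robust
    pseudo-outcome regressions; the estimate is the mean pseudo-outcome at
    stage 0 and the CI is the normal approximation from the EIF standard
    error. A warning is attached when more than 5% of at-risk person-days
    sit at the propensity trimming bound (poor overlap).
    """
    if len(learners) < 1:
        raise ValueError("need at least one outcome learner")
    if nuisances is not None:
        panel, pA, pC = nuisances.panel, nuisances.pA, nuisances.pC
        folds, v_folds = nuisances.folds, nuisances.v_folds
        features = nuisances.features if features is None else features
        warnings = list(nuisances.warnings)
        trim = nuisances.trim
        weight_cap_quantile = nuisances.weight_cap_quantile
    else:
        panel = Panel.from_cohort(cohort, horizon=horizon)
        folds = _assign_folds(panel.n, v_folds, seed)
        warnings = []
        features = list(DEFAULT_FEATURES if features is None else features)
        pA, pC = _fit_g_probs(panel, folds, v_folds,
                              list(g_learners or learners), features, trim,
                              seed, warnings)
    d = regime.assign_path(panel.hyp)
    g_arm = np.where(d == 1, pA, 1.0 - pA)
    at_bound = (g_arm <= trim) & panel.present
    frac = at_bound.sum() / max(panel.present.sum(), 1)
    if frac > 0.05:
        warnings.append(f"poor overlap: {frac:.1%} of person-days at the "
                        f"trimming bound")
    phi, *_ = _backward(panel, d, folds, v_folds, list(learners), features,
                        True, pA, pC, trim, seed, warnings,
                        cap_q=weight_cap_quantile)
    est = _wmean(phi, panel.w)
    se = _wse(phi, panel.w)
    return EstimateResult(_risk_label(regime), "sdr",
                          float(np.clip(est, 0, 1)), se,
                          est - _Z * se, est + _Z * se, panel.n, v_folds,
                          eif=phi - est, warnings=warnings)


# ------------------------------------------------------------------ contrast
def contrast(result_treat: EstimateResult, result_control: EstimateResult,
             scale: str = "difference") -> EstimateResult:
    """Contrast two regime-specific risks on a chosen scale.

    Uses the difference of the per-patient EIF values when both results carry
    them (same cohort), otherwise combines SEs assuming independence; ratio
    and odds-ratio scales use the delta method on the log scale.
    """
    rt, rc = result_treat, result_control
    if rt.method != rc.method or rt.n != rc.n:
        raise ValueError("contrasted results must share method and n")
    pt, pc = rt.estimate, rc.estimate
    have_eif = rt.eif is not None and rc.eif is not None and len(rt.eif) == len(rc.eif)
    w = np.ones(rt.n)
    if scale == "difference":
        est = pt - pc
        if have_eif:
            eif = rt.eif - rc.eif
            se = _wse(eif, w)
        else:
            eif, se = None, float(np.hypot(rt.se, rc.se))
        lo, hi = est - _Z * se, est + _Z * se
        label = "risk_difference"
    elif scale in ("ratio", "odds_ratio"):
        if pc <= 0 or pt <= 0 or (scale == "odds_ratio" and (pc >= 1 or pt >= 1)):
            raise ValueError(f"risks on the boundary for {scale} scale")
        if scale == "ratio":
            est = pt / pc
            gt, gc = 1.0 / pt, 1.0 / pc
            label = "risk_ratio"
        else:
            est = (pt / (1 - pt)) / (pc / (1 - pc))
            gt, gc = 1.0 / (pt * (1 - pt)), 1.0 / (pc * (1 - pc))
            label = "odds_ratio"
        if have_eif:
            eif = gt * rt.eif - gc * rc.eif
            se_log = _wse(eif, w)
        else:
            eif, se_log = None, float(np.hypot(gt * rt.se, gc * rc.se))
        lo, hi = est * np.exp(-_Z * se_log), est * np.exp(_Z * se_log)
        se = est * se_log
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return EstimateResult(label, rt.method, float(est), float(se),
                          float(lo), float(hi), rt.n, rt.folds, eif=eif,
                          warnings=rt.warnings + rc.warnings)


def estimate_risk_difference(cohort: pd.DataFrame, method: str = "sdr",
                             learners=("linear_additive",), v_folds: int = 10,
                             trim: float = 0.01, seed: int = 0,
                             features: list | None = None,
                             horizon: int | None = None) -> dict:
    """Both regime risks and their difference in one call (shared nuisances)."""
    from .regimes import DYNAMIC, NEVER

    results = {}
    nus = {}
    need_ice = method in ("gcomp", "ipw")
    nus[DYNAMIC.kind] = fit_nuisances(
        cohort, DYNAMIC, v_folds, g_learners=learners, m_learners=learners,
        features=features, trim=trim, seed=seed, horizon=horizon,
        fit_ice=need_ice)
    # treatment/censoring fits do not depend on the regime: reuse them
    nus[NEVER.kind] = fit_nuisances(
        cohort, NEVER, v_folds, g_learners=learners, m_learners=learners,
        features=features, trim=trim, seed=seed, horizon=horizon,
        known_pA=nus[DYNAMIC.kind].pA, known_pC=nus[DYNAMIC.kind].pC,
        fit_ice=need_ice)
    if method == "sdr":
        for regime in (DYNAMIC, NEVER):
            results[regime.kind] = sdr_estimate(
                cohort, regime, learners, v_folds, nuisances=nus[regime.kind],
                seed=seed)
    elif method == "gcomp":
        for regime in (DYNAMIC, NEVER):
            results[regime.kind] = gcomp_estimate(cohort, regime,
                                                  nus[regime.kind])
    elif method == "ipw":
        for regime in (DYNAMIC, NEVER):
            results[regime.kind] = ipw_estimate(cohort, regime,
                                                nus[regime.kind])
    else:
        raise ValueError(f"unknown method {method!r}")
    results["risk_difference"] = contrast(results["dynamic_steroids"],
                                          results["never_treat"],
                                          "difference")
    return results
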