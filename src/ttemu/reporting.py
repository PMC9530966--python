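"""Descriptive tables, effect-measure arithmetic and experiment orchestration."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DGPConfig
from .simulate import counterfactual_risk_mc, simulate_cohort
from .regimes import DYNAMIC, NEVER

__all__ = ["format_count_percent", "describe_cohort", "rates_to_or",
           "run_experiment"]


def format_count_percent(k: int, n: int) -> str:
    """``"699 (21)"`` style cell: count and integer-rounded percent.

    Positive counts whose percent rounds to zero print ``(<1)``; an empty
    denominator omits the percent.
    """
    if n <= 0:
        return str(int(k))
    pct = 100.0 * k / n
    r = int(round(pct))
    if k > 0 and r == 0:
        return f"{int(k)} (<1)"
    return f"{int(k)} ({r})"


def _median_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if len(x) == 0:
        return ""
    med, lo, hi = x.median(), x.quantile(0.25), x.quantile(0.75)
    return f"{med:.2g} ({lo:.2g}-{hi:.2g})"


def describe_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics overall and stratified by any corticosteroid
    exposure during follow-up.

    Binary characteristics print count (integer percent); continuous ones
    print median (IQR). Stratum counts always sum to the overall count.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    g = cohort.groupby("patient_id", sort=True)
    base = g.first()
    base["ever_treat"] = g["treat"].max()
    base["died"] = g["death"].max()
    base["ever_hypoxia"] = g["hypoxia"].max()

    strata = {"overall": base,
              "never": base.loc[base["ever_treat"] == 0],
              "ever": base.loc[base["ever_treat"] == 1]}
    rows = []

    def add(name, fn):
        rows.append({"characteristic": name,
                     **{k: fn(v) for k, v in strata.items()}})

    add("Patients, No.", lambda d: str(len(d)))
    add("Age (standardized), median (IQR)", lambda d: _median_iqr(d["age"]))
    add("Male sex, No. (%)",
        lambda d: format_count_percent(int(d["sex"].sum()), len(d)))
    add("Major comorbidity, No. (%)",
        lambda d: format_count_percent(int(d["comorbid"].sum()), len(d)))
    add("Severe hypoxia during follow-up, No. (%)",
        lambda d: format_count_percent(int(d["ever_hypoxia"].sum()), len(d)))
    add("Outcome: 28-d mortality, No. (%)",
        lambda d: format_count_percent(int(d["died"].sum()), len(d)))
    return pd.DataFrame(rows)


def rates_to_or(p_treat: float, p_control: float) -> float:
    """Odds ratio implied by two risks: [p1/(1-p1)] / [p0/(1-p0)]."""
    for p in (p_treat, p_control):
        if not 0.0 < p < 1.0:
            raise ValueError("risks must lie strictly between 0 and 1")
    return (p_treat / (1.0 - p_treat)) / (p_control / (1.0 - p_control))


# ----------------------------------------------------------------- experiment
def _sub_seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)]


def run_experiment(config: dict | str, out_dir: str | None = None) -> dict:
    """Simulate -> estimate -> model-first designs over replicates.

    ``config`` is a mapping (or path to a YAML file) with a mandatory ``dgp``
    section (DGPConfig fields) and optional keys ``replicates`` (default 1),
    ``seed``, ``methods`` (subset of sdr/gcomp/ipw), ``learners``,
    ``v_folds``, ``designs`` (string of design ids, "" to skip) and
    ``truth_n_mc`` (Monte-Carlo draws for the reference truth; 0 to skip).
    Writes a bundle (results/ tables + logs/run.log) when ``out_dir`` is
    given; repeated runs with the same config reproduce results/ byte for
    byte.
    """
    from .estimators import estimate_risk_difference
    from .cox_designs import run_all_designs

    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "dgp" not in config:
        raise ValueError("experiment config must contain a 'dgp' section")
    dgp = DGPConfig.from_dict(config["dgp"])
    reps = int(config.get("replicates", 1))
    seed = int(config.get("seed", dgp.seed))
    methods = list(config.get("methods", ["sdr"]))
    learners = tuple(config.get("learners", ["linear_additive"]))
    v_folds = int(config.get("v_folds", 2))
    designs = str(config.get("designs", ""))
    truth_n_mc = int(config.get("truth_n_mc", 0))

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]
    log_lines = [f"ttemu experiment | seed={seed} | config_hash={cfg_hash}",
                 f"python={sys.version.split()[0]}"]

    truth = {}
    if truth_n_mc > 0:
        s_dyn, s_nev = _sub_seeds(seed + 1, 2)
        r1 = counterfactual_risk_mc(dgp, DYNAMIC, truth_n_mc, s_dyn)
        r0 = counterfactual_risk_mc(dgp, NEVER, truth_n_mc, s_nev)
        truth = {"risk_dynamic": r1.risk, "risk_never": r0.risk,
                 "risk_difference": r1.risk - r0.risk,
                 "mc_se": float(np.hypot(r1.se, r0.se)), "n_mc": truth_n_mc}
        log_lines.append(f"truth: {truth}")

    est_rows, design_rows, failures = [], [], []
    for rep, rs in enumerate(_sub_seeds(seed, reps)):
        try:
            cohort = simulate_cohort(dgp.replace(seed=rs))
            for method in methods:
                res = estimate_risk_difference(
                    cohort, method=method, learners=learners,
                    v_folds=v_folds, seed=rs, horizon=dgp.horizon)
                for label, r in res.items():
                    est_rows.append({"replicate": rep, "method": method,
                                     "estimand": r.estimand_label,
                                     "estimate": r.estimate, "se": r.se,
                                     "ci_low": r.ci_low, "ci_high": r.ci_high})
            if designs:
                dd = run_all_designs(cohort, designs)
                dd.insert(0, "replicate", rep)
                design_rows.append(dd)
        except Exception as e:  # keep other replicates alive
            failures.append({"replicate": rep, "error": str(e)})
            log_lines.append(f"replicate {rep} FAILED: {e}")

    est = pd.DataFrame(est_rows)
    des = (pd.concat(design_rows, ignore_index=True)
           if design_rows else pd.DataFrame())

    summary: dict = {"seed": seed, "replicates": reps,
                     "config_hash": cfg_hash, "failures": failures,
                     "truth": truth}
    if len(est):
        agg = (est.groupby(["method", "estimand"])["estimate"]
               .agg(["mean", "std"]).reset_index())
        summary["estimates"] = agg.to_dict("records")
        if truth:
            for method in methods:
                sub = est[(est["method"] == method)
                          & (est["estimand"] == "risk_difference")]
                if len(sub):
                    th = truth["risk_difference"]
                    summary[f"{method}_bias"] = float(
                        (sub["estimate"] - th).mean())
                    summary[f"{method}_coverage"] = float(
                        ((sub["ci_low"] <= th)
                         & (th <= sub["ci_high"])).mean())

    bundle = {"estimates": est, "designs": des, "summary": summary,
              "log": log_lines}
    if out_dir is not None:
        out = Path(out_dir)
        (out / "results").mkdir(parents=True, exist_ok=True)
        (out / "logs").mkdir(parents=True, exist_ok=True)
        est.to_csv(out / "results" / "estimates.csv", index=False)
        des.to_csv(out / "results" / "designs.csv", index=False)
        with open(out / "results" / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        (out / "logs" / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle
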