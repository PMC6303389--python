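"""End-to-end analysis chains for the four McGurk experiments.

Each experiment's chain mirrors its published analysis structure:
per-condition prevalence means with standard errors, a t-test on
participant means, a baseline-vs-effect pair of binomial GLMMs compared by
BIC, marginalized (population-average) predictions where the effect is the
headline result, and -- for the repetition-without-co-articulation
experiment -- an additional Gaussian LMM on per-record binomial variances.
Reports carry full provenance (seed, config hash, timestamp) so that every
number is recomputable from the stored trial table and configuration.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .behavior import validate_trial_table
from .stats import (
    FixedTerm,
    GLMMFit,
    GLMMSpec,
    compare_models,
    fit_glmm,
    fit_variance_lmm,
    independent_t_test,
    marginal_prevalence,
    paired_t_test,
)

__all__ = ["SchemaError", "AnalysisReport", "run_experiment_analysis"]


class SchemaError(ValueError):
    """The trial table does not match the experiment's expected schema."""


#: per experiment: GLMM condition coding, baseline fixed terms, t-test kind
_EXPERIMENT_PLAN = {
    1: {
        "conditions": ["one_rep", "six_rep"],
        "condition_term": FixedTerm("condition", categorical=True),
        "baseline_fixed": (FixedTerm("group", categorical=True),),
        "t_test": ("paired", "one_rep", "six_rep"),
        "marginal": True,
        "variance_lmm": False,
    },
    2: {
        "conditions": None,  # numeric repetition levels
        "condition_term": FixedTerm("condition", categorical=False),
        "baseline_fixed": (),
        "t_test": None,
        "marginal": False,
        "variance_lmm": True,
    },
    3: {
        "conditions": ["familiar", "unfamiliar"],
        "condition_term": FixedTerm("condition", categorical=True),
        "baseline_fixed": (FixedTerm("group", categorical=True),),
        "t_test": ("paired", "unfamiliar", "familiar"),
        "marginal": False,
        "variance_lmm": False,
    },
    4: {
        "conditions": ["online", "in_person"],
        "condition_term": FixedTerm("condition", categorical=True),
        "baseline_fixed": (),
        "t_test": ("independent", "in_person", "online"),
        "marginal": False,
        "variance_lmm": False,
    },
}


def _glmm_summary(fit: GLMMFit) -> dict:
    return {
        "coefficients": fit.coefficients,
        "se": fit.se,
        "z": fit.wald_z(),
        "p": fit.p_values(),
        "variance_components": fit.variance_components,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "bic": fit.bic,
        "converged": fit.converged,
        "singular": fit.singular,
    }


@dataclass
class AnalysisReport:
    """Results of one experiment's analysis chain, JSON-serializable."""

    experiment_id: int
    condition_summary: list[dict]
    t_test: dict | None
    glmm_baseline: dict
    glmm_effect: dict
    comparison: dict
    effect_odds_ratio: dict | None
    marginal_predictions: dict | None
    variance_analysis: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "condition_summary": self.condition_summary,
            "t_test": self.t_test,
            "glmm_baseline": self.glmm_baseline,
            "glmm_effect": self.glmm_effect,
            "comparison": self.comparison,
            "effect_odds_ratio": self.effect_odds_ratio,
            "marginal_predictions": self.marginal_predictions,
            "variance_analysis": self.variance_analysis,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)

    def render_text(self) -> str:
        lines = [f"=== Experiment {self.experiment_id} analysis ==="]
        lines.append("condition prevalence (mean +/- SEM across participants):")
        for row in self.condition_summary:
            lines.append(
                f"  {row['condition']:<12s} {100 * row['mean']:5.1f}% +/- "
                f"{100 * row['sem']:4.1f}%  (n={row['n_participants']})"
            )
        if self.t_test is not None:
            t = self.t_test
            lines.append(
                f"t-test ({t['kind']}, {t['contrast']}): t({t['df']:.0f}) = "
                f"{t['statistic']:.2f}, p = {t['pvalue']:.2g}"
            )
        cmp_ = self.comparison
        lines.append(
            f"GLMM BIC comparison: baseline {cmp_['bic_baseline']:.1f} vs effect "
            f"{cmp_['bic_alternative']:.1f}; dBIC = {cmp_['delta_bic']:.1f} "
            f"in favor of the {cmp_['preferred']} model"
            + (" (decisive)" if cmp_["decisive"] else "")
        )
        if self.effect_odds_ratio is not None:
            orr = self.effect_odds_ratio
            lines.append(
                f"effect odds ratio [{orr['term']}]: {orr['odds_ratio']:.2f} "
                f"(z = {orr['z']:.2f}, p = {orr['p']:.2g})"
            )
        if self.marginal_predictions:
            parts = ", ".join(
                f"{k}: {100 * v:.1f}%" for k, v in self.marginal_predictions.items()
            )
            lines.append(f"marginalized prevalence: {parts}")
        if self.variance_analysis is not None:
            va = self.variance_analysis
            lines.append(
                f"binomial-variance LMM: slope {va['slope']:+.4f} +/- {va['slope_se']:.4f}; "
                f"dBIC = {va['delta_bic']:.1f} in favor of the {va['preferred']} model"
            )
        prov = self.provenance
        lines.append(f"provenance: seed={prov.get('seed')} config_hash={prov.get('config_hash')}")
        return "\n".join(lines)


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _participant_condition_means(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby(["participant_id", "condition"], sort=True)
    out = (g["n_da_tha"].sum() / g["n_trials"].sum()).rename("prevalence").reset_index()
    return out


def run_experiment_analysis(
    trials: pd.DataFrame,
    experiment_id: int,
    config: Mapping | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full analysis chain for one experiment on a trial table.

    The table may include congruent-control rows (condition "congruent");
    they are excluded from the McGurk analyses. Raises :class:`SchemaError`
    for malformed tables or condition structure.
    """
    if experiment_id not in _EXPERIMENT_PLAN:
        raise SchemaError(f"unknown experiment_id {experiment_id!r}; expected 1-4")
    plan = _EXPERIMENT_PLAN[experiment_id]
    config = dict(config or {})

    try:
        trials = validate_trial_table(trials)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc

    mcgurk = trials[trials["condition"].astype(str) != "congruent"].copy()
    if mcgurk.empty:
        raise SchemaError("no McGurk rows in the trial table")
    mcgurk["condition"] = mcgurk["condition"].astype(str)

    if plan["conditions"] is not None:
        analysis = mcgurk[mcgurk["condition"].isin(plan["conditions"])].copy()
        present = set(analysis["condition"].unique())
        missing = set(plan["conditions"]) - present
        if missing:
            raise SchemaError(
                f"experiment {experiment_id} requires conditions {plan['conditions']}; "
                f"missing {sorted(missing)}"
            )
    else:
        try:
            pd.to_numeric(mcgurk["condition"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                "experiment 2 requires numeric repetition levels in the condition column"
            ) from exc
        analysis = mcgurk

    # ---- per-condition prevalence across participants ----
    pcm = _participant_condition_means(mcgurk)
    condition_summary = []
    for cond, sub in pcm.groupby("condition", sort=True):
        vals = sub["prevalence"].to_numpy()
        condition_summary.append(
            {
                "condition": str(cond),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "n_participants": int(len(vals)),
            }
        )

    # ---- t-test on participant means ----
    t_test = None
    if plan["t_test"] is not None:
        kind, cond_a, cond_b = plan["t_test"]
        wide = pcm.pivot(index="participant_id", columns="condition", values="prevalence")
        if kind == "paired":
            both = wide[[cond_a, cond_b]].dropna()
            res = paired_t_test(both[cond_b], both[cond_a])
        else:
            a = wide[cond_a].dropna().to_numpy()
            b = wide[cond_b].dropna().to_numpy()
            res = independent_t_test(a, b, pooled=False)
        t_test = {
            "kind": kind,
            "contrast": f"{cond_b} vs {cond_a}",
            "statistic": float(res.statistic),
            "df": float(res.df),
            "pvalue": float(res.pvalue),
        }

    # ---- GLMM pair and BIC comparison ----
    baseline_spec = GLMMSpec(fixed=plan["baseline_fixed"])
    effect_spec = GLMMSpec(fixed=plan["baseline_fixed"] + (plan["condition_term"],))
    fit_base = fit_glmm(analysis, baseline_spec)
    fit_eff = fit_glmm(analysis, effect_spec)
    comparison = compare_models(fit_base, fit_eff)

    effect_or = None
    cond_term = plan["condition_term"]
    effect_names = [
        k for k in fit_eff.coefficients
        if k == cond_term.name or k.startswith(f"{cond_term.name}[")
    ]
    if effect_names:
        name = effect_names[0]
        z = fit_eff.wald_z()[name]
        effect_or = {
            "term": name,
            "log_odds": float(fit_eff.coefficients[name]),
            "odds_ratio": float(math.exp(fit_eff.coefficients[name])),
            "se_log_odds": float(fit_eff.se[name]),
            "z": float(z),
            "p": float(fit_eff.p_values()[name]),
        }

    # ---- marginalized predictions (headline-effect experiments) ----
    marginal = None
    if plan["marginal"]:
        marginal = {}
        group_levels = fit_eff.term_levels.get("group") or []
        for cond in plan["conditions"]:
            if group_levels:
                vals = [
                    marginal_prevalence(fit_eff, {"condition": cond, "group": g})
                    for g in group_levels
                ]
                marginal[cond] = float(np.mean(vals))
            else:
                marginal[cond] = marginal_prevalence(fit_eff, {"condition": cond})

    # ---- binomial-variance LMM (repetition precision analysis) ----
    variance_analysis = None
    if plan["variance_lmm"]:
        v_base = fit_variance_lmm(analysis, include_repetition_slope=False)
        v_slope = fit_variance_lmm(analysis, include_repetition_slope=True)
        v_cmp = compare_models(v_base, v_slope)
        variance_analysis = {
            "slope": float(v_slope.slope),
            "slope_se": float(v_slope.slope_se),
            "bic_baseline": v_base.bic,
            "bic_slope": v_slope.bic,
            "delta_bic": v_cmp.delta_bic,
            "preferred": "no-slope" if v_cmp.preferred == "baseline" else "slope",
        }

    provenance = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "n_records": int(len(trials)),
    }

    return AnalysisReport(
        experiment_id=experiment_id,
        condition_summary=condition_summary,
        t_test=t_test,
        glmm_baseline=_glmm_summary(fit_base),
        glmm_effect=_glmm_summary(fit_eff),
        comparison={
            "bic_baseline": comparison.bic_baseline,
            "bic_alternative": comparison.bic_alternative,
            "delta_bic": comparison.delta_bic,
            "preferred": comparison.preferred,
            "decisive": comparison.decisive,
            "approx_evidence_ratio": comparison.approx_evidence_ratio,
        },
        effect_odds_ratio=effect_or,
        marginal_predictions=marginal,
        variance_analysis=variance_analysis,
        provenance=provenance,
    )
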