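"""Stimulation-effect estimation: mixed-effects and log-binomial models.

Primary model: trial-level binomial logistic mixed model of recalled status
on condition (Stim vs matched NoStim), with random intercepts and condition
slopes for subject and for stimulation target site; the exponentiated
condition coefficient is reported as an odds ratio. A log-link binomial
companion model yields a relative risk, reported as percent change
100*(RR - 1). A linear mixed model of consecutive-word classifier-output
changes estimates the post-stimulation shift in decoded brain state.

Mixed binomial models are fit by a Laplace approximation to the marginal
likelihood (:mod:`memloop.glmm`); linear mixed models use REML
(statsmodels ``MixedLM``). t statistics use residual degrees of freedom
(n - p) throughout. Sites are treated as grouping factors alongside subjects
(a site belongs to one subject, so the crossed specification reduces to
nesting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.genmod.families import Binomial, Poisson
from statsmodels.genmod.families.links import Log
from statsmodels.tools.sm_exceptions import DomainWarning, ConvergenceWarning

from memloop.glmm import fit_logistic_glmm, intercept_and_slope_blocks

TRIAL_COLUMNS = ["recalled", "stim", "group", "subject", "site", "serial_pos", "flank"]


class EmptyAnalysisError(ValueError):
    """No analyzable rows (e.g. no matched pairs)."""


class FitError(RuntimeError):
    """Model fitting produced non-finite estimates."""


@dataclass
class EffectEstimate:
    """One fitted effect: point estimate, uncertainty and provenance."""

    name: str
    estimate: float          # on the reporting scale (OR, RR, or difference)
    se: float                # on the link/coefficient scale
    t: float
    df: int
    p: float
    model: str
    scale: str = "odds_ratio"
    coefficient: float = float("nan")  # link-scale coefficient
    converged: bool = True
    notes: str = ""

    def as_row(self) -> dict:
        return {
            "estimand": self.name, "estimate": self.estimate, "se": self.se,
            "t": self.t, "df": self.df, "p": self.p, "model": self.model,
            "scale": self.scale, "converged": self.converged, "notes": self.notes,
        }


def estimates_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in estimates])


def _t_p(coef: float, se: float, df: int) -> tuple[float, float]:
    t = coef / se
    return t, float(2.0 * sps.t.sf(abs(t), df))


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    if len(trials) == 0:
        raise EmptyAnalysisError("trial table is empty")
    t = trials.copy()
    t["recalled"] = t["recalled"].astype(int)
    t["stim"] = t["stim"].astype(int)
    if t["stim"].nunique() < 2:
        raise EmptyAnalysisError("both Stim and NoStim rows are required")
    return t


def _design(trials: pd.DataFrame, include_group: bool) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: condition, plus group main effect and interaction."""
    n = len(trials)
    stim = trials["stim"].to_numpy(dtype=float)
    if not include_group:
        return np.column_stack([np.ones(n), stim]), ["Intercept", "stim"]
    g = (trials["group"] != "lateral_temporal").to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), stim, g, stim * g])
    return X, ["Intercept", "stim", "group", "stim:group"]


def _blocks(trials: pd.DataFrame, site_effects: bool = True):
    blocks = intercept_and_slope_blocks(trials, "subject", "stim")
    if site_effects and trials["site"].nunique() > trials["subject"].nunique():
        blocks += intercept_and_slope_blocks(trials, "site", "stim")
    return blocks


# ---------------------------------------------------------------------------
# binomial mixed model (odds ratios)
# ---------------------------------------------------------------------------
def fit_stim_glme(
    trials: pd.DataFrame,
    include_group: bool = False,
    random_effects: bool = True,
    name: str = "stimulation_or",
) -> EffectEstimate:
    """Binomial logistic mixed model of recall on stimulation condition.

    Random intercepts and condition slopes for subject and site (site terms
    are included when sites subdivide subjects). With
    ``random_effects=False`` the model collapses to an ordinary logistic GLM
    on the same rows. Returns the exponentiated condition coefficient as an
    odds ratio.
    """
    t = _validate_trials(trials)
    if t["subject"].nunique() < 2:
        raise EmptyAnalysisError("need at least 2 subjects for the mixed model")
    formula = "recalled ~ stim * C(group)" if include_group else "recalled ~ stim"
    if include_group and t["group"].nunique() < 2:
        raise EmptyAnalysisError("include_group requires both groups")

    if not random_effects:
        fit = smf.glm(formula, data=t, family=Binomial()).fit()
        coef, se = fit.params["stim"], fit.bse["stim"]
        df = int(fit.df_resid)
        tt, p = _t_p(coef, se, df)
        return EffectEstimate(name, float(np.exp(coef)), float(se), tt, df, p,
                              model="binomial GLM (logit link)",
                              scale="odds_ratio", coefficient=float(coef))

    X, names = _design(t, include_group)
    try:
        fit = fit_logistic_glmm(t["recalled"].to_numpy(float), X, _blocks(t),
                                exog_names=names)
    except (FloatingPointError, np.linalg.LinAlgError) as exc:
        raise FitError(f"mixed-model fit failed: {exc}") from exc
    coef, se = fit.coef("stim")
    if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
        raise FitError(f"mixed-model fit did not produce finite estimates: {fit.message}")
    df = len(t) - len(names)
    tt, p = _t_p(coef, se, df)
    notes = "" if fit.converged else fit.message
    if np.any(fit.block_sd < 5e-3):
        notes = ("degenerate random-effect variance (collapsed toward zero); "
                 + notes).strip("; ")
    return EffectEstimate(
        name, float(np.exp(coef)), se, tt, df, p,
        model="binomial GLME, Laplace approximation (subject+site intercepts/slopes)",
        scale="odds_ratio", coefficient=coef, notes=notes,
    )


# ---------------------------------------------------------------------------
# log-binomial model (relative risk)
# ---------------------------------------------------------------------------
def fit_log_binomial(
    trials: pd.DataFrame, name: str = "stimulation_rr"
) -> EffectEstimate:
    """Log-link binomial model; condition coefficient exponentiates to a
    relative risk (reported alongside as percent change, 100*(RR-1)).

    If the log-link fit diverges or yields fitted probabilities >= 1, falls
    back to a modified-Poisson surrogate (Poisson GLM with robust HC1
    standard errors), flagged in ``notes``.
    """
    t = _validate_trials(trials)
    y = t["recalled"].to_numpy()
    X = sm.add_constant(t[["stim"]].to_numpy(dtype=float))
    note = ""
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        try:
            start = np.zeros(X.shape[1])
            start[0] = np.log(max(y.mean(), 1e-6))
            model = sm.GLM(y, X, family=Binomial(link=Log()))
            cand = model.fit(start_params=start, maxiter=200)
            mu = cand.fittedvalues
            if cand.converged and np.all(mu < 1.0):
                fit = cand
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            fit = None
    if fit is None:
        fit = sm.GLM(y, X, family=Poisson()).fit(cov_type="HC1")
        note = "log-link divergence: modified-Poisson surrogate with HC1 errors"
    coef, se = float(fit.params[1]), float(fit.bse[1])
    df = int(fit.df_resid)
    tt, p = _t_p(coef, se, df)
    return EffectEstimate(
        name, float(np.exp(coef)), se, tt, df, p,
        model="log-binomial GLM" if not note else "modified Poisson (HC1)",
        scale="relative_risk", coefficient=coef, notes=note,
    )


def percent_change(est: EffectEstimate) -> float:
    """Relative risk reported as percent change in recall probability."""
    if est.scale != "relative_risk":
        raise ValueError("percent change is defined for relative-risk estimates")
    return 100.0 * (est.estimate - 1.0)


# ---------------------------------------------------------------------------
# flanking model
# ---------------------------------------------------------------------------
def fit_flanking_glme(
    flank_trials: pd.DataFrame,
    include_group: bool = False,
    random_effects: bool = True,
    name: str = "flanking_or",
) -> EffectEstimate:
    """Binomial mixed model on flanking words (subject intercepts + slopes)."""
    t = _validate_trials(flank_trials)
    formula = "recalled ~ stim * C(group)" if include_group else "recalled ~ stim"
    if not random_effects:
        fit = smf.glm(formula, data=t, family=Binomial()).fit()
        coef, se = fit.params["stim"], fit.bse["stim"]
        df = int(fit.df_resid)
        tt, p = _t_p(coef, se, df)
        return EffectEstimate(name, float(np.exp(coef)), float(se), tt, df, p,
                              model="binomial GLM (logit link)",
                              scale="odds_ratio", coefficient=float(coef))
    X, names = _design(t, include_group)
    try:
        fit = fit_logistic_glmm(
            t["recalled"].to_numpy(float), X,
            intercept_and_slope_blocks(t, "subject", "stim"), exog_names=names,
        )
    except (FloatingPointError, np.linalg.LinAlgError) as exc:
        raise FitError(f"flanking mixed model failed: {exc}") from exc
    coef, se = fit.coef("stim")
    df = len(t) - len(names)
    tt, p = _t_p(coef, se, df)
    return EffectEstimate(
        name, float(np.exp(coef)), se, tt, df, p,
        model="binomial GLME, Laplace approximation (subject intercepts/slopes)",
        scale="odds_ratio", coefficient=coef,
        notes="" if fit.converged else fit.message,
    )


# ---------------------------------------------------------------------------
# post-stimulation classifier-output model
# ---------------------------------------------------------------------------
def build_delta_table(events: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-word classifier-output changes after stimulated/matched words.

    For every word i that was stimulated (Stim lists) or a matched control
    (NoStim lists) with a successor i+1 in the same list, one row with
    ``delta = prob[i+1] - prob[i]`` and ``stim`` flagging the condition.
    """
    ev = events.reset_index(drop=True)
    rows = []
    for (_, _, li), grp in ev.groupby(["subject", "session", "list_index"]):
        grp = grp.sort_values("serial_pos")
        probs = grp["classifier_prob"].to_numpy()
        anchors = (grp["stimulated"] | grp["matched_control"]).to_numpy()
        stim = grp["stimulated"].to_numpy()
        for k in range(len(grp) - 1):
            if anchors[k] and np.isfinite(probs[k]) and np.isfinite(probs[k + 1]):
                rows.append(
                    dict(delta=probs[k + 1] - probs[k], stim=int(stim[k]),
                         subject=grp["subject"].iloc[0], site=grp["site"].iloc[0],
                         group=grp.get("group", pd.Series(["unknown"])).iloc[0]
                         if "group" in grp else "unknown")
                )
    return pd.DataFrame(rows)


def delta_classifier_analysis(
    data, name: str = "delta_classifier"
) -> EffectEstimate:
    """Linear mixed model of the post-word classifier-output change.

    ``data`` is either a prebuilt delta table (columns delta, stim, subject,
    site) or an event table from which one is built. Random intercepts and
    condition slopes per subject, plus site components when sites subdivide
    subjects; REML estimation.
    """
    table = data if "delta" in getattr(data, "columns", []) else build_delta_table(data)
    if len(table) == 0 or table["stim"].nunique() < 2:
        raise EmptyAnalysisError("no matched Stim/NoStim consecutive-word pairs")
    vc = {}
    if table["site"].nunique() > table["subject"].nunique():
        vc["site"] = "0 + C(site)"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = smf.mixedlm(
            "delta ~ stim", data=table, groups="subject",
            re_formula="~stim", vc_formula=vc or None,
        )
        fit = model.fit(reml=True)
    notes = "; ".join(sorted({str(w.message).splitlines()[0] for w in caught}))
    coef, se = float(fit.params["stim"]), float(fit.bse["stim"])
    if not (np.isfinite(coef) and np.isfinite(se)):
        raise FitError(f"delta mixed model failed: {notes}")
    df = len(table) - 2
    tt, p = _t_p(coef, se, df)
    return EffectEstimate(
        name, coef, se, tt, df, p,
        model="linear mixed model (REML), subject intercepts/slopes",
        scale="difference", coefficient=coef, notes=notes,
    )


# ---------------------------------------------------------------------------
# balance checks
# ---------------------------------------------------------------------------
def balance_checks(
    closed_loop_events: pd.DataFrame,
    record_events: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Group-balance diagnostics across the two stimulation-target arms.

    (i) mixed-model comparison of the per-word below-threshold (trigger)
    proportion by group and its interaction with serial position;
    (ii) two-sample t-test of record-only recall percentage by group.
    Requires a ``group`` column on the event tables.
    """
    rows = []
    ev = closed_loop_events[
        closed_loop_events["list_role"].isin(["Stim", "NoStim"])
    ].copy()
    if ev["group"].nunique() < 2:
        raise EmptyAnalysisError("balance checks require both groups")
    ev["below"] = (
        ev["classifier_prob"] < 0.5
    ).astype(float)
    ev["grp"] = (ev["group"] != "lateral_temporal").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("below ~ grp", data=ev, groups="subject").fit(reml=True)
        coef, se = float(fit.params["grp"]), float(fit.bse["grp"])
        tt, p = _t_p(coef, se, len(ev) - 2)
        rows.append(EffectEstimate(
            "trigger_proportion_group_difference", coef, se, tt, len(ev) - 2, p,
            model="linear mixed model", scale="difference", coefficient=coef,
            notes=f"group means: "
                  f"{ev.groupby('group')['below'].mean().round(4).to_dict()}"))
        fit2 = smf.mixedlm(
            "below ~ serial_pos * grp", data=ev, groups="subject"
        ).fit(reml=True)
        key = "serial_pos:grp"
        coef, se = float(fit2.params[key]), float(fit2.bse[key])
        tt, p = _t_p(coef, se, len(ev) - 4)
        rows.append(EffectEstimate(
            "trigger_position_by_group", coef, se, tt, len(ev) - 4, p,
            model="linear mixed model", scale="difference", coefficient=coef))
    if record_events is not None and len(record_events):
        per = (
            record_events.groupby(["group", "subject"])["recalled"]
            .mean()
            .mul(100.0)
            .reset_index()
        )
        groups = [g["recalled"].to_numpy() for _, g in per.groupby("group")]
        if len(groups) == 2:
            res = sps.ttest_ind(groups[0], groups[1], equal_var=True)
            diff = groups[0].mean() - groups[1].mean()
            df = len(groups[0]) + len(groups[1]) - 2
            rows.append(EffectEstimate(
                "record_only_recall_group_difference", float(diff),
                float(diff / res.statistic) if res.statistic else float("nan"),
                float(res.statistic), df, float(res.pvalue),
                model="two-sample t-test", scale="difference",
                coefficient=float(diff),
                notes=f"group means (%): "
                      f"{per.groupby('group')['recalled'].mean().round(2).to_dict()}"))
    return estimates_frame(rows)


def sme_tmap(record_feats, labels) -> np.ndarray:
    """Record-only SME t statistic per frequency at one electrode pair.

    ``record_feats`` holds the z-scored features of a single pair (the
    stimulated pair's columns); returns one two-sample t value (recalled vs
    forgotten) per analysis frequency.
    """
    values = record_feats.values if hasattr(record_feats, "values") else np.asarray(record_feats)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise EmptyAnalysisError("need both recalled and forgotten events")
    return sps.ttest_ind(values[y], values[~y], axis=0, equal_var=True).statistic


def sme_map_comparison(
    tmaps: pd.DataFrame, freq_col: str = "freq", group_col: str = "group",
    value_col: str = "t_sme",
) -> pd.DataFrame:
    """Compare per-site SME t-maps at the stimulated pair across groups.

    ``tmaps`` has one row per (site, frequency) with the record-only SME t
    statistic; returns a two-sample t-test per frequency bin.
    """
    rows = []
    for f, grp in tmaps.groupby(freq_col):
        parts = [g[value_col].to_numpy() for _, g in grp.groupby(group_col)]
        if len(parts) != 2 or min(len(p) for p in parts) < 2:
            continue
        res = sps.ttest_ind(parts[0], parts[1], equal_var=True)
        rows.append(dict(freq=f, t=float(res.statistic), p=float(res.pvalue),
                         n0=len(parts[0]), n1=len(parts[1])))
    return pd.DataFrame(rows)
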