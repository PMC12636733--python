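"""Regression-based and individual-difference analyses.

Implements the choice regressions (Cs-only, color-only, combined), the
trade-off interaction model (color x total-Cs-fixated), its
strength-of-evidence control, the RT-moderation model, optimality
contrasts, relative-use indices, cross-measure correlations and the
model-versus-data correspondence summaries.

Group-level inference is two-stage: per-participant maximum-likelihood
logistic regressions followed by one-sample t-tests of the coefficients
across participants (a transparent approximation to crossed random-effects
models).  All predictors are z-scored within participant; interaction terms
are products of the z-scored components.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .agent import TrialRecord
from .fitting import FitResult
from .task import TaskSchedule, true_reward_prob

__all__ = [
    "FORMULAS",
    "build_predictors",
    "fit_choice_model",
    "accuracy_contrasts",
    "use_indices",
    "cross_measures",
    "fixations_by_trial_type",
    "model_data_correspondence",
]

#: named formulas: response is choice (1 = right), terms are z-scored
FORMULAS = {
    "cs": ("z_dCs_instructed",),
    "color": ("z_dP_color",),
    "both": ("z_dCs_instructed", "z_dP_color"),
    "tradeoff": ("z_dCs_observed", "z_dP_color", "z_dP_color_x_sumCs"),
    "tradeoff_evidence": ("z_dCs_observed", "z_dP_color",
                          "z_dP_color_x_sumCs", "z_dP_color_x_absdCs"),
    "rt": ("z_dCs_observed", "z_dP_color", "z_dP_color_x_sumCs",
           "z_dP_color_x_rt"),
}


def _zscore(v: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = np.std(v)
    if sd == 0:
        return np.zeros_like(v, dtype=float), True
    return (v - np.mean(v)) / sd, False


def build_predictors(schedule: TaskSchedule,
                     records: Sequence[TrialRecord],
                     gaze_counts: Optional[pd.DataFrame] = None,
                     participant: int = 0) -> pd.DataFrame:
    """Trial-level predictors for the choice regressions (combined trials).

    ``dP_color`` is the running proportion of rewarded outcomes among prior
    trials on which a stimulus of that color was chosen (0 before the first
    such outcome).  Observed-Cs counts come from ``gaze_counts`` (the final
    cumulative-count rows per trial from the eye pipeline) when given, else
    from the records' own fixation sequences.  Raw columns are kept; z_
    columns are z-scored within the participant, with zero-variance
    predictors flagged in ``df.attrs['constant_predictors']`` and set to 0.
    """
    by_index = {t.trial: t for t in schedule}
    counts_by_trial = {}
    if gaze_counts is not None and len(gaze_counts):
        final = gaze_counts.sort_values("step").groupby("trial").tail(1)
        for r in final.itertuples():
            counts_by_trial[int(r.trial)] = (r.left_up, r.left_down,
                                             r.right_up, r.right_down)
    chosen_n: dict[int, int] = {}
    rewarded_n: dict[int, int] = {}

    def reward_history(color_id) -> float:
        if color_id is None or chosen_n.get(color_id, 0) == 0:
            return 0.0
        return rewarded_n.get(color_id, 0) / chosen_n[color_id]

    rows = []
    for rec in records:
        trial = by_index[rec.trial]
        if trial.trial_type == "combined" and not trial.is_practice:
            if rec.trial in counts_by_trial:
                lu, ld, ru, rd = counts_by_trial[rec.trial]
            else:
                lu = sum(1 for s, o in zip(rec.sides, rec.c_orientations)
                         if s == "left" and o)
                ld = sum(1 for s, o in zip(rec.sides, rec.c_orientations)
                         if s == "left" and not o)
                ru = sum(1 for s, o in zip(rec.sides, rec.c_orientations)
                         if s == "right" and o)
                rd = sum(1 for s, o in zip(rec.sides, rec.c_orientations)
                         if s == "right" and not o)
            rows.append({
                "participant": participant,
                "trial": rec.trial,
                "choice": 1 if rec.choice == "right" else 0,
                "dCs_instructed": trial.right.up_count - trial.left.up_count,
                "dCs_observed": (ru - rd) - (lu - ld),
                "sumCs_observed": lu + ld + ru + rd,
                "dP_color": (reward_history(trial.right.color_id)
                             - reward_history(trial.left.color_id)),
                "rt": rec.rt_proxy,
            })
        chosen = trial.stimulus(rec.choice)
        if chosen.has_color:
            chosen_n[chosen.color_id] = chosen_n.get(chosen.color_id, 0) + 1
            rewarded_n[chosen.color_id] = (rewarded_n.get(chosen.color_id, 0)
                                           + rec.reward)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    constant = []
    for col in ("dCs_instructed", "dCs_observed", "sumCs_observed",
                "dP_color", "rt"):
        z, flat = _zscore(df[col].to_numpy(dtype=float))
        df["z_" + col] = z
        if flat:
            constant.append(col)
    z_abs, flat = _zscore(np.abs(df["dCs_observed"].to_numpy(dtype=float)))
    df["z_absdCs_observed"] = z_abs
    if flat:
        constant.append("absdCs_observed")
    df["z_dP_color_x_sumCs"] = df["z_dP_color"] * df["z_sumCs_observed"]
    df["z_dP_color_x_absdCs"] = df["z_dP_color"] * df["z_absdCs_observed"]
    df["z_dP_color_x_rt"] = df["z_dP_color"] * df["z_rt"]
    df.attrs["constant_predictors"] = constant
    return df


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                      float, bool]:
    """MLE logistic fit; weak-ridge fallback under separation.

    Returns (coefs, standard errors, log-likelihood, converged-cleanly).
    """
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
        clean = bool(np.all(np.isfinite(res.bse))
                     and np.max(np.abs(res.params)) < 15)
        if clean:
            return (np.asarray(res.params), np.asarray(res.bse),
                    float(res.llf), True)
    except Exception:
        pass
    res = model.fit_regularized(alpha=1.0 / len(y), L1_wt=0.0)
    params = np.asarray(res.params)
    mu = 1.0 / (1.0 + np.exp(-(X @ params)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return params, np.full_like(params, np.nan), llf, False


def fit_choice_model(predictors: pd.DataFrame, formula: str,
                     min_trials: int = 30) -> dict:
    """Two-stage estimate of a named choice regression.

    Stage 1: per-participant ML logistic regression of choice on the
    formula's z-scored terms (intercept included).  Stage 2: one-sample
    t-test of each coefficient against 0 across participants.  Also reports
    summed deviance and BIC for model comparison across formulas.
    """
    terms = FORMULAS[formula]
    per_rows, skipped = [], []
    deviance_total = bic_total = 0.0
    for pid, grp in predictors.groupby("participant"):
        if len(grp) < min_trials:
            skipped.append(pid)
            continue
        y = grp["choice"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(grp))]
                            + [grp[t].to_numpy(dtype=float) for t in terms])
        coefs, ses, llf, clean = _fit_logit(y, X)
        k = X.shape[1]
        deviance_total += -2.0 * llf
        bic_total += -2.0 * llf + k * np.log(len(grp))
        row = {"participant": pid, "converged": clean,
               "n_trials": len(grp), "intercept": coefs[0]}
        for t, c, s in zip(terms, coefs[1:], ses[1:]):
            row[t] = c
            row["se_" + t] = s
        per_rows.append(row)
    per = pd.DataFrame(per_rows)
    group_rows = []
    for t in terms:
        vals = per[t].to_numpy(dtype=float) if len(per) else np.array([])
        if len(vals) >= 2:
            tt = stats.ttest_1samp(vals, 0.0)
            group_rows.append({"term": t, "mean": float(vals.mean()),
                               "se": float(stats.sem(vals)),
                               "t": float(tt.statistic),
                               "p": float(tt.pvalue), "n": len(vals)})
        else:
            group_rows.append({"term": t,
                               "mean": float(vals.mean()) if len(vals)
                               else np.nan,
                               "se": np.nan, "t": np.nan, "p": np.nan,
                               "n": len(vals)})
    return {"formula": formula, "per_participant": per,
            "group": pd.DataFrame(group_rows),
            "deviance_total": deviance_total, "bic_total": bic_total,
            "skipped_participants": skipped}


def accuracy_contrasts(participants: Iterable) -> dict:
    """Choice optimality under three criteria, on combined trials.

    For each participant: the proportion of non-tied combined trials on
    which the choice matched (a) the higher total reward probability,
    (b) the higher up-count alone, (c) the higher color probability alone;
    plus paired t-tests of (a) against (b) and (c).
    """
    rows = []
    for p in participants:
        by_index = {t.trial: t for t in p.schedule}
        hits = {"combined": [0, 0], "cs": [0, 0], "color": [0, 0]}
        for rec in p.records:
            trial = by_index[rec.trial]
            if trial.trial_type != "combined" or trial.is_practice:
                continue
            cfg = p.schedule.config
            crits = {
                "combined": (true_reward_prob("combined", trial.right, cfg)
                             - true_reward_prob("combined", trial.left, cfg)),
                "cs": trial.right.up_count - trial.left.up_count,
                "color": trial.right.p_color - trial.left.p_color,
            }
            chose_right = rec.choice == "right"
            for name, diff in crits.items():
                if diff == 0:
                    continue
                hits[name][1] += 1
                if (diff > 0) == chose_right:
                    hits[name][0] += 1
        rows.append({
            "participant": p.pid,
            **{f"{name}_accuracy": (h / n if n else np.nan)
               for name, (h, n) in hits.items()},
        })
    table = pd.DataFrame(rows)
    tests = {}
    for other in ("cs", "color"):
        a = table["combined_accuracy"].to_numpy()
        b = table[f"{other}_accuracy"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2:
            tt = stats.ttest_rel(a[ok], b[ok])
            tests[f"combined_vs_{other}"] = {
                "t": float(tt.statistic), "p": float(tt.pvalue),
                "mean_diff": float((a[ok] - b[ok]).mean()), "n": int(ok.sum())}
    return {"table": table, "tests": tests}


def use_indices(coefs: Optional[pd.DataFrame] = None,
                fit: Optional[FitResult] = None,
                variant: str = "symmetric",
                beta_cs_col: str = "z_dCs_observed",
                beta_color_col: str = "z_dP_color",
                eps: float = 1e-8) -> pd.DataFrame:
    """Relative color-versus-Cs use, per participant.

    Regression-based index: (b_color - b_Cs) / (|b_Cs| + |b_color|)
    (``variant="symmetric"``, the default) or the literal caption reading
    (b_color - b_Cs) / (b_Cs + |b_color|) (``variant="caption"``).
    Model-based index: omega_color / alpha_gather from posterior means; the
    raw ratio is reported and negative-denominator rows are counted in
    ``df.attrs``.  Near-zero denominators yield NaN.
    """
    pieces = []
    if coefs is not None and len(coefs):
        bcs = coefs[beta_cs_col].to_numpy(dtype=float)
        bcol = coefs[beta_color_col].to_numpy(dtype=float)
        denom = (np.abs(bcs) + np.abs(bcol) if variant == "symmetric"
                 else bcs + np.abs(bcol))
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(np.abs(denom) < eps, np.nan, (bcol - bcs) / denom)
        pieces.append(pd.DataFrame({
            "participant": coefs["participant"].to_numpy(),
            "regression_index": idx}))
    if fit is not None:
        ag = fit.posterior_means["alpha_gather"].to_numpy()
        om = fit.posterior_means["omega_color"].to_numpy()
        ratio = np.where(np.abs(ag) < eps, np.nan, om / ag)
        pieces.append(pd.DataFrame({
            "participant": np.arange(len(ag)),
            "model_index": ratio,
            "alpha_gather": ag, "omega_color": om}))
    if not pieces:
        raise ValueError("need regression coefficients and/or a fit")
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.merge(piece, on="participant", how="outer")
    out.attrs["undefined_regression"] = (
        int(np.isnan(out["regression_index"]).sum())
        if "regression_index" in out else 0)
    out.attrs["negative_alpha_gather"] = (
        int((out["alpha_gather"] < 0).sum()) if "alpha_gather" in out else 0)
    return out


def cross_measures(table: pd.DataFrame,
                   pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pearson correlations (with p-values) between measure columns."""
    rows = []
    for a, b in pairs:
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"x": a, "y": b, "r": float(r), "p": float(p),
                         "n": int(ok.sum())})
        else:
            rows.append({"x": a, "y": b, "r": np.nan, "p": np.nan,
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)


def fixations_by_trial_type(participants: Iterable) -> dict:
    """Mean fixations per trial by type, with a combined-vs-Cs-only test."""
    rows = []
    for p in participants:
        means = {}
        for tt in ("combined", "cs_only", "color_only"):
            vals = [r.n_fixations for r in p.records if r.trial_type == tt]
            means[tt] = float(np.mean(vals)) if vals else np.nan
        rows.append({"participant": p.pid, **means})
    table = pd.DataFrame(rows)
    a = table["combined"].to_numpy()
    b = table["cs_only"].to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    test = None
    if ok.sum() >= 2:
        tt = stats.ttest_rel(a[ok], b[ok])
        test = {"t": float(tt.statistic), "p": float(tt.pvalue),
                "mean_diff": float((a[ok] - b[ok]).mean()), "n": int(ok.sum())}
    return {"table": table, "combined_vs_cs_only": test}


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0:
        return np.nan
    return float(np.polyfit(x, y, 1)[0])


def model_data_correspondence(participants: Iterable,
                              n_bins: int = 5) -> dict:
    """Summary curves for checking the model against (real or synthetic)
    behavior.

    * ``choice_curve``: P(choose right) by binned right-minus-left color
      reward probability, pooled over combined trials.
    * ``continue_by_fixation``: P(fixating again | reached fixation k) per
      participant, with a per-participant linear slope over k.
    * ``cs_by_dvcolor`` / ``rt_by_dvcolor``: per-participant slopes of the
      within-participant-centered number of Cs fixated (or stopping time)
      on |learned color-value difference|, combined trials.
    """
    curve_x, curve_y = [], []
    cont_rows, slope_rows = [], []
    for p in participants:
        by_index = {t.trial: t for t in p.schedule}
        dvc, nfix, rts = [], [], []
        max_fix = 0
        counts_reached: dict[int, int] = {}
        counts_continued: dict[int, int] = {}
        for rec in p.records:
            trial = by_index[rec.trial]
            if trial.trial_type != "combined" or trial.is_practice:
                continue
            curve_x.append(trial.right.p_color - trial.left.p_color)
            curve_y.append(1.0 if rec.choice == "right" else 0.0)
            dvc.append(abs(rec.v_color_right - rec.v_color_left))
            nfix.append(rec.n_fixations)
            rts.append(rec.rt_proxy)
            max_fix = max(max_fix, rec.n_fixations)
            for k in range(rec.n_fixations + 1):
                counts_reached[k] = counts_reached.get(k, 0) + 1
                if k < rec.n_fixations:
                    counts_continued[k] = counts_continued.get(k, 0) + 1
        ks = sorted(k for k in counts_reached if counts_reached[k] >= 5)
        pk = np.array([counts_continued.get(k, 0) / counts_reached[k]
                       for k in ks])
        cont_rows.append({"participant": p.pid,
                          "slope": _slope(np.array(ks, dtype=float), pk)})
        dvc = np.asarray(dvc)
        nfix = np.asarray(nfix, dtype=float)
        rts = np.asarray(rts, dtype=float)
        slope_rows.append({
            "participant": p.pid,
            "cs_slope": _slope(dvc, nfix - nfix.mean()),
            "rt_slope": _slope(dvc, rts - rts.mean()),
        })
    curve_x = np.asarray(curve_x)
    curve_y = np.asarray(curve_y)
    edges = np.linspace(curve_x.min() - 1e-9, curve_x.max() + 1e-9,
                        n_bins + 1)
    which = np.digitize(curve_x, edges) - 1
    curve = pd.DataFrame([
        {"bin_center": float((edges[b] + edges[b + 1]) / 2),
         "p_choose_right": float(curve_y[which == b].mean()),
         "n": int((which == b).sum())}
        for b in range(n_bins) if (which == b).any()
    ])
    cont = pd.DataFrame(cont_rows)
    slopes = pd.DataFrame(slope_rows)
    return {
        "choice_curve": curve,
        "continue_by_fixation": cont,
        "mean_continue_slope": float(np.nanmean(cont["slope"])),
        "dv_slopes": slopes,
        "mean_cs_slope": float(np.nanmean(slopes["cs_slope"])),
        "mean_rt_slope": float(np.nanmean(slopes["rt_slope"])),
    }
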