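"""Behavioral performance metrics and reaction-time analyses.

Hit and false-alarm rates are computed separately for the pre-cue task
(fixation-cross events) and the post-cue detection task.  Reaction
times are filtered to within +-3.5 standard deviations of the pooled
all-subject, all-condition mean and to a 150 ms floor, averaged per
subject and condition, and analyzed with a one-way repeated-measures
ANOVA over the five event conditions plus planned Holm-corrected
contrasts and a spatial-selectivity contrast backed by a Bayesian
t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference

#: the five post-cue event conditions
RT_CONDITIONS = ("val", "val_match", "inval", "inval_match", "inval_non_match")

#: planned pairwise contrasts (Holm-corrected)
PLANNED_CONTRASTS = (
    ("val_match", "inval_non_match"),
    ("val", "inval"),
    ("val_match", "inval_match"),
    ("inval_match", "inval_non_match"),
)


def filter_rts(
    table: pd.DataFrame, sd_mult: float = 3.5, floor_ms: float = 150.0
) -> pd.DataFrame:
    """Remove outlier reaction times from post-cue event responses.

    The mean and standard deviation are pooled over all subjects and
    conditions; RTs outside mean +- ``sd_mult`` x SD, or faster than
    ``floor_ms``, are dropped (the response itself is kept as a miss is
    not implied: the row's ``rt_ms`` becomes missing).  Idempotent:
    re-filtering the output removes nothing further by the SD rule.
    """
    mask = (table["trial_class"] == "postcue_event") & table["rt_ms"].notna()
    rts = table.loc[mask, "rt_ms"]
    if rts.empty:
        raise ValueError("no reaction times to filter")
    mean, sd = rts.mean(), rts.std(ddof=1)
    if np.isnan(sd):
        sd = 0.0
    keep_val = (rts >= floor_ms)
    if sd > 0:
        keep_val &= (rts - mean).abs() <= sd_mult * sd
    if not keep_val.any():
        raise ValueError("reaction-time filter removed every response")
    out = table.copy()
    dropped = keep_val.index[~keep_val]
    out.loc[dropped, "rt_ms"] = np.nan
    return out


def performance_rates(table: pd.DataFrame) -> dict[str, float]:
    """Hit and false-alarm rates, pre-cue and post-cue separately.

    Hits are responded event trials over event trials; false alarms
    are responses in trials without the respective event.  Undefined
    rates (zero denominator) are reported as NaN.
    """
    def rate(cls: str) -> float:
        sub = table[table["trial_class"] == cls]
        return float(sub["responded"].mean()) if len(sub) else float("nan")

    return {
        "postcue_hit_rate": rate("postcue_event"),
        "postcue_fa_rate": rate("postcue_noevent"),
        "precue_hit_rate": rate("precue_event"),
        "precue_fa_rate": rate("precue_noevent"),
    }


def rt_condition_analysis(
    table: pd.DataFrame,
    subject_col: str = "subject",
    r: float = 0.71,
) -> dict:
    """Condition-mean RTs, rm-ANOVA, planned contrasts, selectivity.

    ``table`` must contain multiple subjects (a ``subject`` column) and
    post-cue event rows with reaction times for every condition and
    subject.  Planned pairwise contrasts are Holm-corrected; the
    spatial-selectivity contrast (inval_non_match - val_match) vs
    (inval - val) is tested with a paired t-test and a JZS Bayesian
    t-test.
    """
    ev = table[(table["trial_class"] == "postcue_event") & table["rt_ms"].notna()]
    means = (
        ev.groupby([subject_col, "condition"], observed=True)["rt_ms"]
        .mean().unstack("condition")
    )
    missing = [c for c in RT_CONDITIONS if c not in means.columns or means[c].isna().any()]
    if missing:
        raise ValueError(f"conditions without reaction times for some subject: {missing}")
    means = means[list(RT_CONDITIONS)]

    long = means.reset_index().melt(
        id_vars=subject_col, var_name="condition", value_name="rt_ms"
    )
    anova = inference.rm_anova(
        long, dv="rt_ms", within="condition", subject=subject_col
    )

    from scipy import stats as sp_stats

    rows = []
    for a, b in PLANNED_CONTRASTS:
        d = means[a] - means[b]
        sd = d.std(ddof=1)
        if sd > 0:
            res = sp_stats.ttest_rel(means[a], means[b])
            t, p = float(res.statistic), float(res.pvalue)
        else:
            t, p = 0.0, 1.0
        rows.append({
            "contrast": f"{a}_vs_{b}", "mean_diff_ms": float(d.mean()),
            "t": t, "df": len(d) - 1, "p_value": p,
            "cohen_d": float(d.mean() / sd) if sd > 0 else 0.0,
        })
    contrasts = pd.DataFrame(rows)
    contrasts["p_holm"] = inference.holm_adjust(contrasts["p_value"].to_numpy())

    sel_same = means["inval_non_match"] - means["val_match"]
    sel_diff = means["inval"] - means["val"]
    diff = sel_same - sel_diff
    if diff.std(ddof=1) > 0:
        res = sp_stats.ttest_rel(sel_same, sel_diff)
        sel = {
            "mean_diff_ms": float(diff.mean()),
            "t": float(res.statistic), "df": len(diff) - 1,
            "p_value": float(res.pvalue),
            "bf10": inference.jzs_bf_paired(sel_same.to_numpy(),
                                            sel_diff.to_numpy(), r=r),
        }
    else:
        sel = {"mean_diff_ms": 0.0, "t": 0.0, "df": len(diff) - 1,
               "p_value": 1.0, "bf10": None}
    return {
        "condition_means": means,
        "anova": anova,
        "planned_contrasts": contrasts,
        "selectivity": sel,
    }
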