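"""Group-level screening statistics: assumption checks, 3 x 2 mixed ANOVA,
rank-based fallbacks and Bonferroni post-hoc comparisons.

The design throughout is one between-subject factor (intervention group:
PMC, M1, Sham) crossed with one within-subject factor (training time:
pre, post).  With three balanced groups of 12 the group and interaction
effects carry df (2, 33) and the time effect df (1, 33).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# assumption checks


def check_assumptions(values_by_group: dict[str, np.ndarray], alpha: float = 0.05):
    """Kolmogorov-Smirnov normality per group and Levene homogeneity.

    KS is run against a normal with the sample mean/SD (the common, if
    anti-conservative, usage).  Levene is centred at the group means.
    Returns (normality_p: dict, levene_p: float, route_nonparametric: bool).
    """
    normality = {}
    route = False
    groups = []
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise DesignError(f"group {name!r} has < 3 values")
        sd = v.std(ddof=1)
        if sd == 0:
            normality[name] = np.nan
            route = True
        else:
            p = stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue
            normality[name] = float(p)
            if p < alpha:
                route = True
        groups.append(v)
    if all(np.asarray(g).std(ddof=1) == 0 for g in groups):
        levene_p = np.nan
    else:
        levene_p = float(stats.levene(*groups, center="mean").pvalue)
    return normality, levene_p, route


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass
class MixedAnovaResult:
    """F, df and p for Group, Time and Group x Time effects."""

    effects: dict[str, dict[str, float]]
    n_groups: int
    n_subjects: int
    balanced: bool
    ss: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            dict(effect=k, F=v["F"], df_num=v["df_num"], df_den=v["df_den"], p=v["p"])
            for k, v in self.effects.items()
        ]
        return pd.DataFrame(rows)


def mixed_anova(table: pd.DataFrame, value: str = "value") -> MixedAnovaResult:
    """Two-way mixed ANOVA (between: group, within: pre/post).

    Parameters
    ----------
    table : DataFrame with columns ``subject_id``, ``group``,
        ``timepoint`` in {"pre", "post"} and the value column.
        Subjects missing either timepoint are dropped listwise.

    Notes
    -----
    Classical sums-of-squares decomposition:
    SS_total = SS_group + SS_subjects(group) + SS_time + SS_group:time
             + SS_time:subjects(group).
    Group is tested against subjects-within-groups; Time and the
    interaction against time-by-subjects-within-groups.  With two
    within-subject levels sphericity is not at issue.
    """
    needed = {"subject_id", "group", "timepoint", value}
    if not needed <= set(table.columns):
        raise DesignError(f"table must have columns {sorted(needed)}")
    wide = table.pivot_table(
        index=["subject_id", "group"], columns="timepoint", values=value, aggfunc="mean"
    )
    for tp in ("pre", "post"):
        if tp not in wide.columns:
            raise DesignError(f"missing timepoint {tp!r}")
    complete = wide.dropna(subset=["pre", "post"])
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        import logging

        logging.getLogger(__name__).warning(
            "mixed_anova: dropped %d subject(s) with missing cells", n_dropped
        )
    data = complete[["pre", "post"]].to_numpy()  # (n_subjects, 2)
    group_labels = complete.index.get_level_values("group").to_numpy()
    groups = sorted(set(group_labels))
    k = len(groups)
    n_total = data.shape[0]
    if k < 2 or n_total < k + 2:
        raise DesignError("need >= 2 groups with enough complete subjects")
    counts = np.array([(group_labels == g).sum() for g in groups])
    balanced = bool(counts.min() == counts.max())
    n_levels = 2

    grand = data.mean()
    subj_means = data.mean(axis=1)
    time_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_between_subj = float(n_levels * ((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    ss_cells = 0.0
    for g in groups:
        sel = group_labels == g
        gm = data[sel].mean()
        ss_group += n_levels * sel.sum() * (gm - grand) ** 2
        for j in range(n_levels):
            cm = data[sel, j].mean()
            ss_cells += sel.sum() * (cm - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_total * ((time_means - grand) ** 2).sum())
    ss_interaction = float(ss_cells - ss_group - ss_time)
    ss_within_subj = ss_total - ss_between_subj
    ss_error_within = float(ss_within_subj - ss_time - ss_interaction)

    df_group = k - 1
    df_subj = n_total - k
    df_time = n_levels - 1
    df_inter = (k - 1) * (n_levels - 1)
    df_err_within = (n_total - k) * (n_levels - 1)

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            return (0.0, 1.0) if ss_eff <= 0 else (np.inf, 0.0)
        f = max(ms_eff / ms_err, 0.0)
        return float(f), float(stats.f.sf(f, df_eff, df_err))

    f_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    f_t, p_t = f_and_p(ss_time, df_time, ss_error_within, df_err_within)
    f_i, p_i = f_and_p(ss_interaction, df_inter, ss_error_within, df_err_within)

    effects = {
        "group": dict(F=f_g, df_num=df_group, df_den=df_subj, p=p_g),
        "time": dict(F=f_t, df_num=df_time, df_den=df_err_within, p=p_t),
        "group_x_time": dict(F=f_i, df_num=df_inter, df_den=df_err_within, p=p_i),
    }
    ss = dict(
        total=ss_total,
        group=float(ss_group),
        subjects_within_groups=float(ss_subj_within),
        time=ss_time,
        group_x_time=ss_interaction,
        time_x_subjects=ss_error_within,
    )
    return MixedAnovaResult(
        effects=effects, n_groups=k, n_subjects=n_total, balanced=balanced, ss=ss
    )


# ---------------------------------------------------------------------------
# nonparametric fallbacks


def kruskal_wallis(values_by_group: dict[str, np.ndarray]):
    """Kruskal-Wallis H and p across >= 3 independent groups."""
    if len(values_by_group) < 3:
        raise DesignError("Kruskal-Wallis needs >= 3 groups")
    samples = [np.asarray(v, float) for v in values_by_group.values()]
    if np.ptp(np.concatenate(samples)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def friedman(conditions: np.ndarray):
    """Friedman chi-square over repeated measures, tie-corrected.

    ``conditions`` has shape (n_subjects, k_conditions); works for k = 2
    (where it reduces to a sign-test-like statistic on paired ranks),
    which scipy's implementation refuses.
    """
    x = np.asarray(conditions, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DesignError("need subjects x (>= 2 conditions)")
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = 1.0 - ties / (n * k * (k**2 - 1)) if k > 1 else 1.0
    if denom <= 0:
        return 0.0, 1.0
    chi2 /= denom
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# post-hoc


def bonferroni_posthoc(
    deltas_by_group: dict[str, np.ndarray], m: int | None = None
) -> pd.DataFrame:
    """Paired t per group on (post - pre) deltas, Bonferroni-corrected.

    ``m`` defaults to the number of groups tested; corrected p is the
    raw p multiplied by m and capped at 1.
    """
    if m is None:
        m = len(deltas_by_group)
    rows = []
    for name, deltas in deltas_by_group.items():
        d = np.asarray(deltas, dtype=float)
        n = d.size
        if n < 2:
            raise DesignError(f"group {name!r} has < 2 paired deltas")
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
            p_raw = 1.0 if d.mean() == 0 else 0.0
        else:
            t = float(d.mean() / (sd / np.sqrt(n)))
            p_raw = float(2 * stats.t.sf(abs(t), n - 1))
        rows.append(
            dict(
                group=name,
                t=t,
                df=n - 1,
                p_raw=p_raw,
                p_corrected=min(p_raw * m, 1.0),
            )
        )
    return pd.DataFrame(rows)
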