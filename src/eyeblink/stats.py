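"""Cohort statistics: learning curves and group comparisons.

The battery mirrors standard practice for conditioning time-course data:
unpaired two-sample t-tests for end-of-training summaries (mean of the last
four sessions), paired t-tests for extinction/savings contrasts, one-way
ANOVA with Bonferroni-adjusted planned comparisons for 3+ groups, a
two-way repeated-measures (split-plot) ANOVA with genotype between subjects
and session within, ANCOVA with age in days as covariate followed by Tukey
HSD on age-adjusted values, and Cohen's d' (pooled-SD standardized mean
difference) as the effect size accompanying significant pairwise tests.

The mixed-design ANOVA is computed from closed-form balanced sums of
squares, which keeps Monte-Carlo calibration of its type-I error cheap; it
is cross-checked against an independent implementation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DataError(ValueError):
    pass


class UsageError(ValueError):
    pass


@dataclass
class StatResult:
    """One fitted comparison, reported the way conditioning papers print it:
    'F(df1, df2) = ..., p = ..., d' = ...'."""

    design: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None
    extra: dict = field(default_factory=dict)

    def report(self) -> str:
        if self.design in ("unpaired_t", "paired_t"):
            s = f"t({self.df[0]:g}) = {self.statistic:.3g}, p = {self.p_value:.3g}"
        else:
            s = (
                f"F({self.df[0]:g},{self.df[1]:g}) = {self.statistic:.3g}, "
                f"p = {self.p_value:.3g}"
            )
        if self.effect_size is not None:
            s += f", d' = {self.effect_size:.3g}"
        return s


# ---------------------------------------------------------------------------
# Learning curves


def build_learning_curves(metrics: pd.DataFrame) -> pd.DataFrame:
    """Order per-session metrics into per-subject learning curves.

    Expects columns subject_id, group, phase, session plus metric columns
    (probability, amplitude, percent_cr).  Duplicate (subject, phase,
    session) rows are a data error; missing sessions are left missing, never
    imputed.
    """
    required = {"subject_id", "phase", "session"}
    missing = required - set(metrics.columns)
    if missing:
        raise DataError(f"metrics table missing columns: {sorted(missing)}")
    dup = metrics.duplicated(subset=["subject_id", "phase", "session"])
    if dup.any():
        rows = metrics.loc[dup, ["subject_id", "phase", "session"]].iloc[0].tolist()
        raise DataError(f"duplicate (subject, phase, session) rows, first: {rows}")
    return metrics.sort_values(["subject_id", "phase", "session"]).reset_index(drop=True)


def last_four_mean(
    curves: pd.DataFrame, phase: str, metrics: tuple[str, ...] = ("probability", "amplitude", "percent_cr")
) -> pd.DataFrame:
    """Per-subject mean of each metric over the last four sessions of a phase."""
    sub = curves[curves["phase"] == phase]
    if sub.empty:
        raise UsageError(f"no rows for phase {phase!r}")
    out = []
    for sid, g in sub.groupby("subject_id"):
        sessions = np.sort(g["session"].unique())
        if sessions.size < 4:
            raise UsageError(
                f"subject {sid} has {sessions.size} {phase} sessions; need >= 4"
            )
        last4 = g[g["session"].isin(sessions[-4:])]
        row = {"subject_id": sid}
        if "group" in g.columns:
            row["group"] = g["group"].iloc[0]
        if "age_days" in g.columns:
            row["age_days"] = g["age_days"].iloc[0]
        for m in metrics:
            if m in g.columns:
                row[m] = float(last4[m].mean())
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Effect size and t-tests


def cohens_dprime(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """|mean_a - mean_b| / pooled SD (Bessel-corrected variances)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise UsageError("each group needs n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise UsageError("zero pooled SD: effect size undefined")
    return float(abs(a.mean() - b.mean()) / np.sqrt(sp2))


def unpaired_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    t, p = sps.ttest_ind(a, b)
    try:
        d = cohens_dprime(a, b)
    except UsageError:
        d = None
    return StatResult("unpaired_t", float(t), (a.size + b.size - 2,), float(p), d)


def paired_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size:
        raise UsageError("paired test needs equal-length samples")
    if np.allclose(a, b):
        # degenerate: no within-pair variation
        return StatResult("paired_t", 0.0, (a.size - 1,), 1.0)
    t, p = sps.ttest_rel(a, b)
    return StatResult("paired_t", float(t), (a.size - 1,), float(p))


# ---------------------------------------------------------------------------
# ANOVA family


def oneway_anova_bonferroni(
    groups: dict[str, np.ndarray], planned_pairs: list[tuple[str, str]] | None = None
) -> StatResult:
    """Omnibus one-way ANOVA plus Bonferroni-adjusted planned pairwise
    comparisons (raw p times the number of planned comparisons, capped at 1)."""
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise UsageError(f"group {k!r} needs n >= 2")
    vals = list(arrays.values())
    if all(np.allclose(v, vals[0]) and v.size == vals[0].size for v in vals):
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*vals)
    k = len(arrays)
    n_tot = sum(v.size for v in vals)
    pairs = {}
    if planned_pairs:
        m = len(planned_pairs)
        for a, b in planned_pairs:
            res = unpaired_t(arrays[a], arrays[b])
            pairs[(a, b)] = {
                "t": res.statistic,
                "p_raw": res.p_value,
                "p_adj": min(1.0, m * res.p_value),
                "dprime": res.effect_size,
            }
    return StatResult(
        "oneway_anova_bonferroni", float(F), (k - 1, n_tot - k), float(p),
        extra={"pairwise": pairs},
    )


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    within: str = "session",
    between: str = "group",
) -> dict[str, StatResult]:
    """Two-way repeated-measures (split-plot) ANOVA: ``between`` factor
    between subjects, ``within`` factor (session, treated as categorical)
    within subjects.

    Balanced closed-form sums of squares; subjects missing any session are
    excluded listwise with a warning.  Returns StatResults for the
    between-group main effect, the within (session) main effect, and the
    interaction.  No sphericity correction is applied (uncorrected F/df).
    """
    df = data[[subject, within, between, dv]].dropna()
    sessions = np.sort(df[within].unique())
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == sessions.size].index
    dropped = set(df[subject].unique()) - set(complete)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} subject(s) with missing sessions: {sorted(map(str, dropped))}"
        )
        df = df[df[subject].isin(complete)]
    if df.empty or df[between].nunique() < 2:
        raise UsageError("need >= 2 groups with complete data")
    if df[subject].nunique() - df[between].nunique() < 1 or sessions.size < 2:
        raise UsageError("too few complete subjects/sessions for a mixed ANOVA")
    wide = df.pivot_table(index=[between, subject], columns=within, values=dv)
    y = wide.to_numpy()  # subjects x sessions
    glabels = wide.index.get_level_values(0).to_numpy()
    groups = np.unique(glabels)
    N, T = y.shape
    G = groups.size

    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_group = 0.0
    ss_cell = 0.0
    for g in groups:
        sel = glabels == g
        gm = y[sel].mean()
        ss_group += sel.sum() * T * (gm - grand) ** 2
        cell = y[sel].mean(axis=0)  # per-session means within group
        ss_cell += sel.sum() * ((cell - gm - sess_means + grand) ** 2).sum()
    ss_subj_within = float(
        T * sum(
            float(((subj_means[glabels == g] - y[glabels == g].mean()) ** 2).sum())
            for g in groups
        )
    )
    ss_session = N * ((sess_means - grand) ** 2).sum()
    ss_inter = ss_cell
    ss_err = ss_total - ss_group - ss_subj_within - ss_session - ss_inter

    df_group, df_sw = G - 1, N - G
    df_sess, df_inter = T - 1, (G - 1) * (T - 1)
    df_err = (N - G) * (T - 1)

    def _f(ss_num, df_num, ss_den, df_den, name):
        ms_den = ss_den / df_den
        if ms_den <= 0:
            F, p = (0.0, 1.0) if ss_num <= 1e-24 else (np.inf, 0.0)
        else:
            F = (ss_num / df_num) / ms_den
            p = float(sps.f.sf(F, df_num, df_den))
        return StatResult(name, float(F), (df_num, df_den), float(p))

    return {
        "group": _f(ss_group, df_group, ss_subj_within, df_sw, "rm_anova_group"),
        "session": _f(ss_session, df_sess, ss_err, df_err, "rm_anova_session"),
        "interaction": _f(ss_inter, df_inter, ss_err, df_err, "rm_anova_interaction"),
    }


def ancova_age_tukey(
    data: pd.DataFrame,
    dv: str = "value",
    group: str = "group",
    covariate: str = "age_days",
) -> StatResult:
    """Group effect adjusted for a common linear age slope, with Tukey HSD
    on age-adjusted values.

    With a constant covariate the model reduces to a one-way ANOVA
    (documented behavior, not an error).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[dv, group, covariate]].dropna().copy()
    df.columns = ["y", "g", "x"]
    if df["g"].nunique() < 2:
        raise UsageError("need >= 2 groups")
    if np.ptp(df["x"].to_numpy()) == 0:
        model = smf.ols("y ~ C(g)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        frow = tab.loc["C(g)"]
        slope = 0.0
    else:
        model = smf.ols("y ~ C(g) + x", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        frow = tab.loc["C(g)"]
        slope = float(model.params.get("x", 0.0))
    # Tukey HSD on values adjusted to the grand-mean age
    adj = df["y"] - slope * (df["x"] - df["x"].mean())
    samples = [adj[df["g"] == g].to_numpy() for g in sorted(df["g"].unique())]
    if all(s.size >= 2 for s in samples) and not all(
        np.allclose(s, samples[0].mean()) for s in samples
    ):
        tk = sps.tukey_hsd(*samples)
        tukey_p = {
            (sorted(df["g"].unique())[i], sorted(df["g"].unique())[j]): float(
                tk.pvalue[i, j]
            )
            for i in range(len(samples))
            for j in range(i + 1, len(samples))
        }
    else:
        tukey_p = {}
    return StatResult(
        "ancova_age_tukey",
        float(frow["F"]),
        (float(frow["df"]), float(tab.loc["Residual", "df"])),
        float(frow["PR(>F)"]),
        extra={"tukey": tukey_p, "age_slope": slope},
    )


# ---------------------------------------------------------------------------
# Extinction / savings


def savings_summary(
    curves: pd.DataFrame,
    metric: str = "percent_cr",
    never_acquired_groups: tuple[str, ...] = (),
) -> dict[str, dict[str, StatResult]]:
    """Per-group paired contrasts: last acquisition vs last extinction
    session (extinction of the CR), and last extinction vs last
    reacquisition session (savings), on the given metric.

    Groups listed in ``never_acquired_groups`` (animals that never acquired
    CRs) are reported but skipped.  Subjects missing a phase are excluded
    with a warning.
    """
    out: dict[str, dict[str, StatResult]] = {}
    for g, sub in curves.groupby("group"):
        if g in never_acquired_groups:
            out[str(g)] = {"skipped": StatResult("skipped", np.nan, (), np.nan)}
            continue
        vals = {}
        ok_subjects = None
        for phase in ("acquisition", "extinction", "reacquisition"):
            ph = sub[sub["phase"] == phase]
            if ph.empty:
                vals[phase] = None
                continue
            last = ph["session"].max()
            v = ph[ph["session"] == last].set_index("subject_id")[metric]
            vals[phase] = v
            ok_subjects = set(v.index) if ok_subjects is None else ok_subjects & set(v.index)
        if any(v is None for v in vals.values()):
            warnings.warn(f"group {g}: missing phase, savings contrasts skipped")
            continue
        all_subjects = set().union(*(set(v.index) for v in vals.values()))
        if ok_subjects != all_subjects:
            warnings.warn(
                f"group {g}: excluding subjects missing a phase: "
                f"{sorted(all_subjects - ok_subjects)}"
            )
        sids = sorted(ok_subjects)
        acq = vals["acquisition"].loc[sids].to_numpy()
        ext = vals["extinction"].loc[sids].to_numpy()
        rea = vals["reacquisition"].loc[sids].to_numpy()
        out[str(g)] = {
            "acquisition_vs_extinction": paired_t(acq, ext),
            "extinction_vs_reacquisition": paired_t(ext, rea),
        }
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo helpers (calibration and power studies)


def simulate_null_metric_curves(
    n_per_group: tuple[int, int],
    n_sessions: int,
    rng: np.random.Generator,
    session_means: np.ndarray | None = None,
    subject_sd: float = 0.08,
    noise_sd: float = 0.05,
    group_labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-session metric values for a two-group cohort with NO group effect:
    shared session means plus a subject random effect and iid noise.  Used
    for type-I error calibration of the group tests."""
    if session_means is None:
        s = np.arange(1, n_sessions + 1)
        session_means = 0.55 * (1 - np.exp(-s / 4.0))
    rows = []
    for g, n in zip(group_labels, n_per_group):
        b = rng.normal(0.0, subject_sd, n)
        eps = rng.normal(0.0, noise_sd, (n, n_sessions))
        y = session_means[None, :] + b[:, None] + eps
        for i in range(n):
            for s_idx in range(n_sessions):
                rows.append(
                    dict(subject_id=f"{g}{i}", group=g, session=s_idx, value=y[i, s_idx])
                )
    return pd.DataFrame(rows)
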