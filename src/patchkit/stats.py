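"""Normality-gated group statistics for extracted measures.

The procedure mirrors common practice in cellular electrophysiology: a
Shapiro-Wilk test per group decides between the parametric and the
nonparametric branch. If every group is consistent with normality the
comparison uses a t test (two groups; Levene's test decides between the
pooled and Welch variants), an N-way ANOVA (more groups/factors), or a
repeated-measures / mixed ANOVA with Mauchly's sphericity test and the
Greenhouse-Geisser degree-of-freedom correction for within-cell factors.
Otherwise the comparison uses Mann-Whitney (two groups) or Kruskal-Wallis
(more). Post-hoc pairwise comparisons are Bonferroni-adjusted
(p_adj = min(1, p * m)). Every branch taken is recorded in the report's
trace, so the decision path is auditable and a pure function of the data.

Standard tests are delegated to scipy/pingouin; the bespoke content is the
gating, correction, logging and reporting. Outlier screening (iterative
two-sided Grubbs) is a separate, explicit operation — values are reported,
never silently dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DesignError

log = logging.getLogger(__name__)

GROUP_COLS = ("genotype", "age")


@dataclass
class StatsReport:
    test_name: str
    statistic: float
    df: tuple | float | None
    p_value: float
    posthoc: pd.DataFrame | None
    normality: dict  # group -> Shapiro-Wilk p
    sphericity: dict | None
    trace: list = field(default_factory=list)  # every branch taken

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "posthoc": None if self.posthoc is None else self.posthoc.to_dict("records"),
            "normality": self.normality,
            "sphericity": self.sphericity,
            "trace": list(self.trace),
        }


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n."""
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def remove_outliers(
    values, alpha: float = 0.05, method: str = "grubbs"
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs screening; returns (kept, removed).

    With fewer than 3 values the test is undefined and nothing is removed
    (a warning is logged). Removal repeats until no value exceeds the
    critical deviate at ``alpha``.
    """
    if method != "grubbs":
        raise DesignError(f"unknown outlier method {method!r}")
    kept = np.asarray(values, dtype=float)
    removed: list[float] = []
    if kept.size < 3:
        log.warning("outlier screen skipped: n=%d < 3", kept.size)
        return kept, np.array(removed)
    while kept.size >= 3:
        mean, sd = kept.mean(), kept.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(kept - mean) / sd
        i = int(np.argmax(dev))
        if dev[i] > grubbs_critical(kept.size, alpha):
            removed.append(float(kept[i]))
            kept = np.delete(kept, i)
        else:
            break
    return kept, np.array(removed)


def _group_key(row, between) -> str:
    return "/".join(str(row[b]) for b in between)


def _bonferroni_pairs(groups: dict, parametric: bool, alpha: float, trace) -> pd.DataFrame:
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if parametric:
            stat, p = sps.ttest_ind(groups[a], groups[b])
            name = "t"
        else:
            stat, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            name = "U"
        rows.append(
            {"group_a": a, "group_b": b, "test": name, "statistic": float(stat),
             "p_raw": float(p), "p_bonf": min(1.0, float(p) * m)}
        )
    trace.append(f"post hoc: {m} pairwise {'t' if parametric else 'Mann-Whitney'} "
                 "tests, Bonferroni-adjusted")
    return pd.DataFrame(rows)


def select_and_run(
    table: pd.DataFrame,
    dv: str = "value",
    between: list[str] | tuple[str, ...] = ("genotype",),
    within: str | None = None,
    subject: str = "cell_id",
    alpha: float = 0.05,
) -> StatsReport:
    """Run the normality-gated decision tree on a tidy measure table.

    ``table`` holds one row per cell (x within-level when ``within`` is
    given) with the grouping columns and the measure in column ``dv``.
    The branch decisions (Shapiro-Wilk per group, Levene, Mauchly/GG) are
    logged in the returned report's trace.
    """
    between = list(between)
    if not between and within is None:
        raise DesignError("need at least one between or within factor")
    missing = [c for c in between + [dv] if c not in table.columns]
    if missing:
        raise DesignError(f"missing columns in measure table: {missing}")
    trace: list[str] = []

    if between:
        group_labels = table[between].astype(str).agg("/".join, axis=1)
    else:
        group_labels = pd.Series(["all"] * len(table), index=table.index)
    groups = {
        k: g[dv].dropna().to_numpy() for k, g in table.groupby(group_labels)
    }
    for k, v in groups.items():
        if v.size < 3:
            raise DesignError(f"design cell {k!r} has {v.size} < 3 observations")

    normality = {}
    for k, v in groups.items():
        normality[k] = float(sps.shapiro(v).pvalue)
    all_normal = all(p > alpha for p in normality.values())
    trace.append(
        "Shapiro-Wilk per group: "
        + ", ".join(f"{k}: p={p:.3g}" for k, p in sorted(normality.items()))
        + f" -> {'parametric' if all_normal else 'nonparametric'} branch"
    )

    if within is not None:
        return _within_design(table, dv, between, within, subject, alpha,
                              groups, normality, all_normal, trace)

    posthoc = None
    sphericity = None
    if all_normal:
        if len(groups) == 2:
            (ga, gb) = (groups[k] for k in sorted(groups))
            lev = sps.levene(ga, gb)
            equal_var = lev.pvalue > alpha
            trace.append(
                f"Levene: p={lev.pvalue:.3g} -> "
                f"{'pooled' if equal_var else 'Welch'} t test"
            )
            res = sps.ttest_ind(ga, gb, equal_var=equal_var)
            dfree = ga.size + gb.size - 2 if equal_var else float(res.df)
            report = StatsReport(
                test_name="t-test" if equal_var else "welch-t-test",
                statistic=float(res.statistic), df=dfree,
                p_value=float(res.pvalue), posthoc=None,
                normality=normality, sphericity=None, trace=trace,
            )
            return report
        if len(between) == 1:
            vals = [groups[k] for k in sorted(groups)]
            res = sps.f_oneway(*vals)
            trace.append(f"one-way ANOVA over {len(vals)} groups")
            posthoc = _bonferroni_pairs(groups, True, alpha, trace)
            k, n = len(vals), sum(v.size for v in vals)
            return StatsReport(
                test_name="one-way-anova", statistic=float(res.statistic),
                df=(k - 1, n - k), p_value=float(res.pvalue), posthoc=posthoc,
                normality=normality, sphericity=None, trace=trace,
            )
        # factorial between design
        import pingouin as pg

        aov = pg.anova(data=table, dv=dv, between=between, detailed=True)
        trace.append(f"{len(between)}-way ANOVA (factors {between})")
        inter = aov[aov["Source"].str.contains("\\*")]
        row = inter.iloc[0] if len(inter) else aov.iloc[0]
        posthoc = _bonferroni_pairs(groups, True, alpha, trace)
        return StatsReport(
            test_name=f"{len(between)}-way-anova",
            statistic=float(row["F"]),
            df=(float(row["DF"]), float(aov[aov["Source"] == "Residual"]["DF"].iloc[0])),
            p_value=float(row["p_unc"]), posthoc=posthoc,
            normality=normality, sphericity=None, trace=trace,
        )
    # nonparametric branch
    if len(groups) == 2:
        (ga, gb) = (groups[k] for k in sorted(groups))
        res = sps.mannwhitneyu(ga, gb, alternative="two-sided")
        trace.append("Mann-Whitney U (2 groups, non-normal)")
        return StatsReport(
            test_name="mann-whitney", statistic=float(res.statistic), df=None,
            p_value=float(res.pvalue), posthoc=None,
            normality=normality, sphericity=None, trace=trace,
        )
    vals = [groups[k] for k in sorted(groups)]
    res = sps.kruskal(*vals)
    trace.append(f"Kruskal-Wallis over {len(vals)} groups (non-normal)")
    posthoc = _bonferroni_pairs(groups, False, alpha, trace)
    return StatsReport(
        test_name="kruskal-wallis", statistic=float(res.statistic),
        df=len(vals) - 1, p_value=float(res.pvalue), posthoc=posthoc,
        normality=normality, sphericity=None, trace=trace,
    )


def _within_design(table, dv, between, within, subject, alpha,
                   groups, normality, all_normal, trace) -> StatsReport:
    import pingouin as pg

    if len(between) > 1:
        raise DesignError(
            "within-cell designs support at most one between factor here"
        )
    if not all_normal:
        trace.append("non-normal within design: comparing cell means "
                     "across groups nonparametrically")
        cell_means = table.groupby([subject] + between)[dv].mean().reset_index()
        return select_and_run(cell_means, dv=dv, between=between,
                              within=None, subject=subject, alpha=alpha)

    if between:
        aov = pg.mixed_anova(data=table, dv=dv, within=within,
                             subject=subject, between=between[0],
                             correction=True)
        trace.append(f"mixed ANOVA (between {between[0]}, within {within})")
        primary = aov[aov["Source"] == between[0]].iloc[0]
        within_row = aov[aov["Source"] == within].iloc[0]
        label = f"mixed-anova:{between[0]}"
        primary_is_within = False
    else:
        aov = pg.rm_anova(data=table, dv=dv, within=within, subject=subject,
                          correction=True, detailed=True)
        trace.append(f"repeated-measures ANOVA (within {within})")
        primary = within_row = aov.iloc[0]
        label = "rm-anova"
        primary_is_within = True

    sphericity = None
    if "W_spher" in aov.columns and not pd.isna(within_row.get("W_spher")):
        w, sp = float(within_row["W_spher"]), float(within_row["p_spher"])
        eps = float(within_row["eps"])
        sphericity = {"mauchly_W": w, "mauchly_p": sp, "gg_epsilon": eps,
                      "gg_applied": sp < alpha}
        trace.append(
            f"Mauchly: p={sp:.3g}; Greenhouse-Geisser epsilon={eps:.3f}"
            f"{' applied' if sp < alpha else ' not required'}"
        )
    else:
        trace.append("sphericity not evaluated")

    use_gg = (primary_is_within and sphericity is not None
              and sphericity["gg_applied"])
    if "DF1" in primary.index:
        df1, df2 = float(primary["DF1"]), float(primary["DF2"])
    else:  # detailed rm_anova table: effect row + error row
        df1, df2 = float(aov.iloc[0]["DF"]), float(aov.iloc[-1]["DF"])
    p_value = float(primary["p_unc"])
    if use_gg:
        if "p_GG_corr" in primary.index and not pd.isna(primary["p_GG_corr"]):
            p_value = float(primary["p_GG_corr"])
        eps = sphericity["gg_epsilon"]
        df1, df2 = df1 * eps, df2 * eps
        trace.append("degrees of freedom Greenhouse-Geisser corrected")
    return StatsReport(
        test_name=label, statistic=float(primary["F"]),
        df=(df1, df2), p_value=p_value, posthoc=None,
        normality=normality, sphericity=sphericity, trace=trace,
    )


from .cohort import phenotype_demo  # noqa: E402  (part of this module's API)
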