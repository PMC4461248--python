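"""Group statistics and table-style reporting.

Endpoint comparisons between two animal groups (e.g. control Wistar vs
diabetic Goto-Kakizaki): means +/- SEM, percent differences, unpaired
two-tailed t-tests for single-value endpoints, and two-way (group x time)
ANOVA with repeated measures on time — with Tukey pairwise contrasts per
time point when the interaction is significant — for time-course
endpoints.  Significance at alpha = 0.05 throughout; no multiplicity
correction across endpoints.

Standard fits are delegated: t-tests to scipy.stats, the mixed
(between x within) ANOVA to pingouin, Tukey contrasts to statsmodels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "percent_difference",
    "ttest_unpaired",
    "rm_anova_tukey",
    "group_summary",
    "build_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One statistical comparison of an endpoint between groups."""

    endpoint: str
    test: str
    statistic: float
    p_value: float
    group_means: dict = field(default_factory=dict)   # label -> (mean, sem, n)
    effect: str = ""                                   # e.g. "group", "time"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def percent_difference(reference_mean: float, other_mean: float) -> float:
    """Percent difference of ``other`` relative to ``reference``.

    Returns the unrounded value; display rounding to integer percent is the
    reporting convention (:func:`build_report`).
    """
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean is zero: percent difference undefined")
    return 100.0 * (other_mean - reference_mean) / reference_mean


def ttest_unpaired(values_a=None, values_b=None, *, endpoint: str = "",
                   summary_a: tuple[float, float, int] | None = None,
                   summary_b: tuple[float, float, int] | None = None,
                   welch: bool = False,
                   labels: tuple[str, str] = ("A", "B")) -> StatResult:
    """Unpaired two-tailed Student's t-test (pooled variance by default).

    Accepts either raw samples or per-group summaries ``(mean, sem, n)``
    (as printed in a results table); the summary route uses the closed-form
    t from means and standard errors and is exact when the summaries come
    from the samples.  ``welch=True`` switches to the unequal-variance
    form.  Two identical zero-variance samples return p = 1 by convention.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("supply both group summaries")
        (m1, sem1, n1), (m2, sem2, n2) = summary_a, summary_b
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per group")
        sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
        if sd1 == sd2 == 0:
            t, p = (np.inf, 0.0) if m1 != m2 else (0.0, 1.0)
        else:
            t, p = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                            equal_var=not welch)
        means = {labels[0]: (m1, sem1, n1), labels[1]: (m2, sem2, n2)}
    else:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if min(len(a), len(b)) < 2:
            raise ValueError("need n >= 2 per group")
        if np.std(a) == np.std(b) == 0:
            t, p = (np.inf, 0.0) if a.mean() != b.mean() else (0.0, 1.0)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=not welch)
        means = {labels[0]: (a.mean(), sps.sem(a), len(a)),
                 labels[1]: (b.mean(), sps.sem(b), len(b))}
    return StatResult(endpoint=endpoint,
                      test="welch t" if welch else "student t",
                      statistic=float(t), p_value=float(p), group_means=means)


def rm_anova_tukey(long_table: pd.DataFrame, endpoint: str = "value",
                   subject: str = "subject", group: str = "group",
                   time: str = "time") -> list[StatResult]:
    """Two-way (group x time) ANOVA with repeated measures on time.

    ``long_table`` is long-form with one row per subject x time point; the
    time grid must be complete within every subject.  Returns StatResults
    for the group, time and interaction effects (univariate mixed-design
    decomposition), followed by Tukey pairwise group contrasts at each time
    point when the interaction p < alpha.  A single time point degenerates
    to a one-way comparison with a warning log entry.
    """
    import pingouin as pg

    df = long_table.rename(columns={endpoint: "y"}) if endpoint != "y" else long_table.copy()
    counts = df.groupby([subject])[time].nunique()
    n_times = df[time].nunique()
    bad = counts[counts != n_times]
    if len(bad):
        missing = bad.index.tolist()
        raise ValueError(f"missing time cells for subjects {missing}")

    if n_times == 1:
        logger.warning("single time point: degenerating to one-way comparison")
        g = df.groupby(group)["y"]
        labels = list(g.groups)
        res = ttest_unpaired(*(g.get_group(lbl).to_numpy() for lbl in labels),
                             endpoint=endpoint, labels=tuple(labels))
        return [StatResult(endpoint=endpoint, test=res.test,
                           statistic=res.statistic, p_value=res.p_value,
                           group_means=res.group_means, effect="group")]

    aov = pg.mixed_anova(data=df, dv="y", within=time, between=group,
                         subject=subject, correction=False)
    results = []
    name_map = {group: "group", time: "time", "Interaction": "interaction"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for _, row in aov.iterrows():
        results.append(StatResult(
            endpoint=endpoint, test="rm-anova",
            statistic=float(row["F"]),
            p_value=float(min(max(row[p_col], 0.0), 1.0)),
            effect=name_map.get(row["Source"], str(row["Source"])),
        ))

    interaction = next((r for r in results if r.effect == "interaction"), None)
    if interaction is not None and interaction.significant:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for tval, sub in df.groupby(time):
            tk = pairwise_tukeyhsd(sub["y"].to_numpy(), sub[group].to_numpy())
            for i in range(len(tk.pvalues)):
                results.append(StatResult(
                    endpoint=endpoint, test="tukey",
                    statistic=float(tk.meandiffs[i]),
                    p_value=float(tk.pvalues[i]),
                    effect=f"time={tval}",
                ))
    return results


def group_summary(table: pd.DataFrame, group: str = "group") -> pd.DataFrame:
    """Means +/- SEM per group for every numeric endpoint column."""
    num = table.select_dtypes("number")
    out = table[[group]].join(num).groupby(group).agg(["mean", "sem", "count"])
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    return out


def build_report(table: pd.DataFrame, group: str = "group",
                 reference: str | None = None,
                 timecourses: dict[str, pd.DataFrame] | None = None,
                 alpha: float = ALPHA) -> dict:
    """Assemble a machine-readable endpoint report for a two-group study.

    For every numeric endpoint column of ``table`` (one row per subject):
    group means +/- SEM, the percent difference of the non-reference group
    (display-rounded to integer percent), and the unpaired t-test.
    ``timecourses`` maps endpoint names to long tables for the repeated-
    measures ANOVA.  Endpoints with fewer than two finite values in a group
    are omitted with a log entry.  Deterministic given its inputs.
    """
    labels = list(pd.unique(table[group]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    ref = reference if reference is not None else labels[0]
    other = next(l for l in labels if l != ref)

    report: dict = {"groups": {"reference": ref, "other": other},
                    "alpha": alpha, "endpoints": {}, "timecourses": {}}
    for col in table.select_dtypes("number").columns:
        a = table.loc[table[group] == ref, col].dropna().to_numpy()
        b = table.loc[table[group] == other, col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.info("endpoint %s omitted: fewer than 2 values per group", col)
            continue
        res = ttest_unpaired(a, b, endpoint=col, labels=(ref, other))
        pct = percent_difference(a.mean(), b.mean()) if a.mean() != 0 else np.nan
        report["endpoints"][col] = {
            "mean_sem": {ref: [float(a.mean()), float(sps.sem(a)), len(a)],
                         other: [float(b.mean()), float(sps.sem(b)), len(b)]},
            "percent_difference": None if np.isnan(pct) else float(pct),
            "percent_difference_display": None if np.isnan(pct) else int(round(pct)),
            "test": res.test,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": bool(res.p_value < alpha),
        }
    for name, tc in (timecourses or {}).items():
        report["timecourses"][name] = [asdict(r) | {"significant": r.significant}
                                       for r in rm_anova_tukey(tc, endpoint=name)]
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    ref = report["groups"]["reference"]
    other = report["groups"]["other"]
    lines = [f"Endpoint report ({ref} vs {other}, alpha={report['alpha']})", ""]
    for name, ep in report["endpoints"].items():
        (m1, s1, n1) = ep["mean_sem"][ref]
        (m2, s2, n2) = ep["mean_sem"][other]
        star = " *" if ep["significant"] else ""
        pct = ep["percent_difference_display"]
        pct_s = f" ({pct:+d}%)" if pct is not None else ""
        lines.append(f"{name}: {m1:.3g} ± {s1:.2g} (n={n1}) vs "
                     f"{m2:.3g} ± {s2:.2g} (n={n2}){pct_s}, "
                     f"p={ep['p_value']:.3g}{star}")
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
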