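"""Validation-study statistics: descriptives, one-way ANOVA, Tukey HSD.

The comparison layer consumes a long-format trial table with one row per
(subject, exercise, method, score) and produces, per exercise, descriptive
statistics per method, a one-way ANOVA row and Tukey HSD pairwise rows —
the shape of a multi-method validation study's summary tables. Subjects
contribute one score to every method, but the analysis deliberately treats
the groups as independent (plain one-way ANOVA, no repeated-measures
modeling); the report flags this limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXERCISES = (
    "HEAD_DIAG",
    "TRUNK_DIAG",
    "SHOULDER_DIAG",
    "HEAD_ROT",
    "TRUNK_ROT",
    "SHOULDER_ROT",
)
METHODS = ("QTM", "DTW", "APP")
ALPHA = 0.05

TRIAL_COLUMNS = ("subject", "exercise", "method", "score")


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a (subject, exercise, method, score) table's invariants."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    dupes = table.duplicated(subset=["subject", "exercise", "method"])
    if dupes.any():
        first = table[dupes].iloc[0]
        raise ValueError(
            "duplicate (subject, exercise, method) record: "
            f"({first['subject']}, {first['exercise']}, {first['method']})"
        )
    scores = table["score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 100)):
        raise ValueError("scores must lie in [0, 100]")
    return table


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean, sample sd, range, Fisher skewness and excess kurtosis."""

    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    skewness: float  # NaN when undefined (constant sample)
    excess_kurtosis: float  # NaN when undefined


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    mean_difference: float  # mean(group1) - mean(group2)
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class TukeyResult:
    comparisons: tuple[PairwiseComparison, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group1": [c.group1 for c in self.comparisons],
                "group2": [c.group2 for c in self.comparisons],
                "mean_difference": [c.mean_difference for c in self.comparisons],
                "p": [c.p for c in self.comparisons],
                "significant": ["*" if c.significant else "" for c in self.comparisons],
            }
        )


def describe(values, raw_kurtosis: bool = False) -> DescriptiveStats:
    """Descriptive statistics of a sample (sample sd, bias-corrected
    skewness, excess kurtosis; a normal sample has both near 0).

    Constant samples get sd 0 and undefined (NaN) shape statistics.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("describe needs at least 2 values")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=not raw_kurtosis, bias=False))
    return DescriptiveStats(
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        minimum=float(x.min()),
        maximum=float(x.max()),
        skewness=skew,
        excess_kurtosis=kurt,
    )


def one_way_anova(groups) -> AnovaResult:
    """Classical equal-variance one-way ANOVA from definitional sums of
    squares; p from the F distribution with (k-1, N-k) df."""
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = sum(g.sum() for g in gs) / n_total
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = k - 1
    df_w = n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ss_between == 0.0:
            raise ValueError(
                "degenerate ANOVA: zero between- and within-group variance"
            )
        f_val = math.inf
        p = 0.0
    else:
        f_val = float((ss_between / df_b) / ms_within)
        p = float(stats.f.sf(f_val, df_b, df_w))
    return AnovaResult(F=f_val, df_between=df_b, df_within=df_w, p=p)


def tukey_hsd(groups, labels=None) -> TukeyResult:
    """Tukey HSD pairwise comparisons (Tukey–Kramer when unbalanced).

    Mean differences are mean(group1) - mean(group2) for label-sorted pairs
    and are exactly antisymmetric; adjusted p-values come from the
    studentized-range distribution.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels must match the number of groups")
    order = np.argsort(np.asarray(labels, dtype=object))
    gs = [gs[i] for i in order]
    labels = [labels[i] for i in order]
    res = stats.tukey_hsd(*gs)
    comps = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            comps.append(
                PairwiseComparison(
                    group1=str(labels[i]),
                    group2=str(labels[j]),
                    mean_difference=float(gs[i].mean() - gs[j].mean()),
                    p=float(res.pvalue[i, j]),
                )
            )
    return TukeyResult(comparisons=tuple(comps))


@dataclass
class ComparisonReport:
    """Per-exercise descriptives, ANOVA and Tukey tables plus warnings."""

    descriptives: pd.DataFrame
    anova: pd.DataFrame
    tukey: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "descriptives": self.descriptives.to_dict(orient="records"),
            "anova": self.anova.to_dict(orient="records"),
            "tukey": self.tukey.to_dict(orient="records"),
            "warnings": list(self.warnings),
            "note": (
                "one-way ANOVA treats methods as independent groups even "
                "though subjects contribute to every method"
            ),
        }


def comparison_report(table: pd.DataFrame) -> ComparisonReport:
    """Build the full multi-method comparison report from a trial table.

    Exercises with fewer than 2 methods are skipped with a warning.
    Significance at the 0.05 level is flagged with '*'.
    """
    validate_trial_table(table)
    desc_rows, anova_rows, tukey_rows, warnings = [], [], [], []
    for exercise, sub in table.groupby("exercise", sort=True):
        methods = sorted(sub["method"].unique())
        if len(methods) < 2:
            msg = f"exercise {exercise}: fewer than 2 methods, skipped"
            warnings.append(msg)
            logger.warning(msg)
            continue
        groups = [
            sub.loc[sub["method"] == m, "score"].to_numpy(dtype=float)
            for m in methods
        ]
        for m, g in zip(methods, groups):
            d = describe(g)
            desc_rows.append(
                {
                    "exercise": exercise,
                    "method": m,
                    "n": d.n,
                    "mean": d.mean,
                    "sd": d.sd,
                    "min": d.minimum,
                    "max": d.maximum,
                    "skewness": d.skewness,
                    "excess_kurtosis": d.excess_kurtosis,
                }
            )
        a = one_way_anova(groups)
        anova_rows.append(
            {
                "exercise": exercise,
                "F": a.F,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "p": a.p,
                "significant": "*" if a.significant else "",
            }
        )
        tk = tukey_hsd(groups, labels=methods)
        for c in tk.comparisons:
            tukey_rows.append(
                {
                    "exercise": exercise,
                    "group1": c.group1,
                    "group2": c.group2,
                    "mean_difference": c.mean_difference,
                    "p": c.p,
                    "significant": "*" if c.significant else "",
                }
            )
    return ComparisonReport(
        descriptives=pd.DataFrame(desc_rows),
        anova=pd.DataFrame(anova_rows),
        tukey=pd.DataFrame(tukey_rows),
        warnings=warnings,
    )


def plot_method_distributions(table: pd.DataFrame, ax=None):
    """Box plot of score distributions per method (basic visual summary)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    methods = sorted(table["method"].unique())
    data = [table.loc[table["method"] == m, "score"] for m in methods]
    ax.boxplot(data, tick_labels=methods)
    ax.set_ylabel("score")
    ax.set_title("score distribution per method")
    return ax
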