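"""Descriptive statistics of clean trials and the standard group comparisons.

Covers the "traditional" rivalry measures: per-state relative proportions of
reported time, mean phase durations, and perceptual alternation counts (full
flips = direct changes between the two exclusive percepts; half flips = every
other change), aggregated hierarchically (trials -> participant -> group),
plus pooled-variance two-tailed independent t-tests between groups and
ordinary-least-squares trait correlations (questionnaire score vs. rivalry
measure, with a one-sample t-test on the slope against 0).

No multiple-testing correction is applied anywhere; every p-value is raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import EXCLUSIVE_STATES, STATE_ORDER, CleanTrial, PerceptState

CLASS_EXCLUSIVE = "EXCLUSIVE"
CLASS_PIECEMEAL = "PIECEMEAL"
CLASS_SUPERIMPOSED = "SUPERIMPOSED"

_CLASS_MEMBERS = {
    CLASS_EXCLUSIVE: tuple(EXCLUSIVE_STATES),
    CLASS_PIECEMEAL: (PerceptState.PIECEMEAL,),
    CLASS_SUPERIMPOSED: (PerceptState.SUPERIMPOSED,),
}


@dataclass
class PhaseStats:
    """Relative proportions (%) and mean durations (s) for one clean trial.

    States absent from the trial have proportion 0 and mean duration NaN (a
    duration that never occurred contributes no sample, not a zero).
    """

    proportions: dict[PerceptState, float]
    mean_durations: dict[PerceptState, float]
    class_proportions: dict[str, float]
    class_mean_durations: dict[str, float]
    total_time: float
    n_phases: int
    empty: bool = False


@dataclass(frozen=True)
class FlipCounts:
    full: int
    half: int

    @property
    def total(self) -> int:
        return self.full + self.half


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    ci95_slope: tuple[float, float]
    t_slope: float
    p_slope: float
    n: int
    degenerate: bool = False


def phase_stats(clean: CleanTrial) -> PhaseStats:
    """Per-state and per-class proportions and mean durations of one trial."""
    if clean.is_empty:
        return PhaseStats(
            proportions={s: math.nan for s in STATE_ORDER},
            mean_durations={s: math.nan for s in STATE_ORDER},
            class_proportions={c: math.nan for c in _CLASS_MEMBERS},
            class_mean_durations={c: math.nan for c in _CLASS_MEMBERS},
            total_time=0.0,
            n_phases=0,
            empty=True,
        )
    total = clean.total_time
    sums = {s: 0.0 for s in STATE_ORDER}
    counts = {s: 0 for s in STATE_ORDER}
    for s, d in clean.phases:
        sums[s] += d
        counts[s] += 1
    proportions = {s: 100.0 * sums[s] / total for s in STATE_ORDER}
    mean_durations = {
        s: (sums[s] / counts[s]) if counts[s] else math.nan for s in STATE_ORDER
    }
    class_proportions = {}
    class_mean_durations = {}
    for cls, members in _CLASS_MEMBERS.items():
        csum = sum(sums[s] for s in members)
        ccount = sum(counts[s] for s in members)
        class_proportions[cls] = 100.0 * csum / total
        class_mean_durations[cls] = (csum / ccount) if ccount else math.nan
    return PhaseStats(
        proportions=proportions,
        mean_durations=mean_durations,
        class_proportions=class_proportions,
        class_mean_durations=class_mean_durations,
        total_time=total,
        n_phases=clean.n_phases,
    )


def count_flips(clean: CleanTrial) -> FlipCounts:
    """Count full flips (H<->V with no intermediate) and half flips (all other
    adjacent changes) in the clean phase sequence."""
    full = 0
    half = 0
    states = clean.states()
    for a, b in zip(states, states[1:]):
        if a in EXCLUSIVE_STATES and b in EXCLUSIVE_STATES and a != b:
            full += 1
        else:
            half += 1
    return FlipCounts(full=full, half=half)


# ---------------------------------------------------------------------------
# Tidy tables and hierarchical aggregation
# ---------------------------------------------------------------------------

MEAN_MEASURES = [
    "prop_exclusive", "prop_piecemeal", "prop_superimposed",
    "mean_dur_exclusive", "mean_dur_piecemeal", "mean_dur_superimposed",
    "mean_dur_all",
]
SUM_MEASURES = ["full_flips", "half_flips", "flips_total"]


def trial_summary_table(cleans: Iterable[CleanTrial]) -> pd.DataFrame:
    """One row per non-empty clean trial with every basic measure.

    Empty trials are excluded from aggregation (flagged-missing) but counted
    in the ``n_empty`` attribute of the returned frame.
    """
    rows = []
    n_empty = 0
    for c in cleans:
        if c.is_empty:
            n_empty += 1
            continue
        ps = phase_stats(c)
        fl = count_flips(c)
        rows.append(
            {
                "participant_id": c.participant_id,
                "group": c.group,
                "paradigm": c.paradigm,
                "condition": c.condition,
                "trial": c.trial_index,
                "n_phases": c.n_phases,
                "total_time_s": ps.total_time,
                "prop_H": ps.proportions[PerceptState.HORIZONTAL],
                "prop_V": ps.proportions[PerceptState.VERTICAL],
                "prop_exclusive": ps.class_proportions[CLASS_EXCLUSIVE],
                "prop_piecemeal": ps.class_proportions[CLASS_PIECEMEAL],
                "prop_superimposed": ps.class_proportions[CLASS_SUPERIMPOSED],
                "mean_dur_exclusive": ps.class_mean_durations[CLASS_EXCLUSIVE],
                "mean_dur_piecemeal": ps.class_mean_durations[CLASS_PIECEMEAL],
                "mean_dur_superimposed": ps.class_mean_durations[CLASS_SUPERIMPOSED],
                "mean_dur_all": ps.total_time / ps.n_phases,
                "full_flips": fl.full,
                "half_flips": fl.half,
                "flips_total": fl.total,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_empty"] = n_empty
    return df


def participant_summary(
    trial_df: pd.DataFrame, per_condition: bool = False
) -> pd.DataFrame:
    """Aggregate trial rows to participants.

    Duration/proportion measures are averaged over trials (and over conditions
    unless ``per_condition``); flip counts are summed.  Every participant then
    carries equal weight in group-level statistics regardless of usable trial
    count.
    """
    keys = ["participant_id", "group", "paradigm"]
    if per_condition:
        keys.append("condition")
    agg = {m: "mean" for m in MEAN_MEASURES}
    agg.update({m: "sum" for m in SUM_MEASURES})
    agg["total_time_s"] = "sum"
    agg["n_phases"] = "sum"
    return trial_df.groupby(keys, as_index=False).agg(agg)


def group_summary(participant_df: pd.DataFrame, per_condition: bool = False) -> pd.DataFrame:
    """Unweighted mean (and SD) over participants for every measure."""
    keys = ["group", "paradigm"]
    if per_condition and "condition" in participant_df.columns:
        keys.append("condition")
    measures = [m for m in MEAN_MEASURES + SUM_MEASURES if m in participant_df.columns]
    out = participant_df.groupby(keys)[measures].agg(["mean", "std"])
    out.columns = [f"{m}_{stat}" for m, stat in out.columns]
    sums = participant_df.groupby(keys)[SUM_MEASURES].sum().add_suffix("_sum")
    return out.join(sums).reset_index()


def hierarchical_and_pooled_mean(
    trial_df: pd.DataFrame, measure: str
) -> tuple[float, float]:
    """Both aggregation readings of one measure: participant-weighted
    (mean of per-participant trial means) and trial-pooled (mean over all
    trials).  They differ whenever trial counts are unbalanced."""
    per_part = trial_df.groupby("participant_id")[measure].mean()
    return float(per_part.mean()), float(trial_df[measure].mean())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def group_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Pooled-variance (Student) two-tailed independent t-test.

    df = n1 + n2 - 2, matching the classical printed form t(df).  Zero pooled
    variance yields a flagged degenerate result rather than an exception.
    """
    a = np.asarray([v for v in values_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in values_b if np.isfinite(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per group")
    df = len(a) + len(b) - 2
    base = dict(
        df=df,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
    )
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, degenerate=True, **base)
        return TTestResult(t=math.inf if a.mean() > b.mean() else -math.inf,
                           p=0.0, degenerate=True, **base)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), **base)


def trait_correlation(x: Sequence[float], y: Sequence[float]) -> LinearFitResult:
    """OLS fit of measure ``y`` on trait score ``x`` with a one-sample t-test
    on the slope against 0 (df = n - 2) and a symmetric 95% CI."""
    xy = [(a, b) for a, b in zip(x, y) if np.isfinite(a) and np.isfinite(b)]
    if len(xy) < 3:
        raise ValueError("need at least 3 paired finite observations")
    xa = np.array([a for a, _ in xy])
    ya = np.array([b for _, b in xy])
    n = len(xa)
    if np.ptp(xa) == 0:
        return LinearFitResult(
            slope=math.nan, intercept=float(ya.mean()), r_squared=math.nan,
            ci95_slope=(math.nan, math.nan), t_slope=math.nan, p_slope=math.nan,
            n=n, degenerate=True,
        )
    res = sps.linregress(xa, ya)
    tcrit = float(sps.t.ppf(0.975, n - 2))
    half = tcrit * res.stderr
    t_slope = res.slope / res.stderr if res.stderr > 0 else math.inf
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ci95_slope=(float(res.slope - half), float(res.slope + half)),
        t_slope=float(t_slope),
        p_slope=float(res.pvalue),
        n=n,
    )


GROUP_TEST_MEASURES = MEAN_MEASURES + SUM_MEASURES


def group_comparison_table(
    participant_df: pd.DataFrame,
    group_a: str = "autism",
    group_b: str = "control",
    measures: Sequence[str] = tuple(GROUP_TEST_MEASURES),
) -> pd.DataFrame:
    """t-test every measure between the two groups, per paradigm."""
    rows = []
    for paradigm, sub in participant_df.groupby("paradigm"):
        a_df = sub[sub["group"] == group_a]
        b_df = sub[sub["group"] == group_b]
        for m in measures:
            if m not in sub.columns:
                continue
            a = a_df[m].dropna()
            b = b_df[m].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            r = group_ttest(a, b)
            rows.append(
                {
                    "paradigm": paradigm, "measure": m,
                    "t": r.t, "df": r.df, "p": r.p,
                    f"mean_{group_a}": r.mean_a, f"mean_{group_b}": r.mean_b,
                    f"sd_{group_a}": r.sd_a, f"sd_{group_b}": r.sd_b,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)


def trait_correlation_table(
    participant_df: pd.DataFrame,
    meta: pd.DataFrame,
    traits: Sequence[str] = ("aq", "eq"),
    measures: Sequence[str] = ("mean_dur_all", "flips_total"),
) -> pd.DataFrame:
    """Linear trait fits per group x paradigm x trait x measure."""
    merged = participant_df.merge(meta[["participant_id", *traits]], on="participant_id")
    rows = []
    for (group, paradigm), sub in merged.groupby(["group", "paradigm"]):
        for trait in traits:
            for m in measures:
                pairs = sub[[trait, m]].dropna()
                if len(pairs) < 3:
                    continue
                fit = trait_correlation(pairs[trait], pairs[m])
                rows.append(
                    {
                        "group": group, "paradigm": paradigm,
                        "trait": trait, "measure": m,
                        "slope": fit.slope, "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "ci95_lo": fit.ci95_slope[0], "ci95_hi": fit.ci95_slope[1],
                        "t_slope": fit.t_slope, "p_slope": fit.p_slope,
                        "n": fit.n, "degenerate": fit.degenerate,
                    }
                )
    return pd.DataFrame(rows)
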