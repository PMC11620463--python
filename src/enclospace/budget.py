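"""Activity budgets from scan samples and fall rates from event records.

Behavior proportions are computed per observation session over *visible*
scans only, then averaged in two stages — within subject, then across
subjects — so each animal contributes equally regardless of how many
sessions it completed.  Falls are all-occurrence events and enter as a
rate per observation, never as a proportion of scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .observations import ETHOGRAM_STATES, ScanDataset

__all__ = [
    "ActivityBudget",
    "PairedDifference",
    "InsufficientPairsError",
    "aggregate_budget",
    "fall_rate",
    "observation_proportions",
    "paired_mean_difference",
]


class InsufficientPairsError(ValueError):
    """Fewer than two complete pairs for a paired mean difference."""


@dataclass(frozen=True)
class PairedDifference:
    """Mean within-pair difference with a t-based 95% confidence interval."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_pairs: int


@dataclass(frozen=True)
class ActivityBudget:
    """Subject-level and summary activity budgets.

    ``subject_level``: one row per (subject, condition, phase, behavior)
    with the subject's mean proportion of visible scans (or, for ``Fall``,
    mean events per observation).  ``summary``: across-subject mean and SD
    per (condition, phase, behavior), with ``observed`` False where a
    behavior never occurred in that cell.
    """

    subject_level: pd.DataFrame
    summary: pd.DataFrame


def observation_proportions(dataset: ScanDataset) -> pd.DataFrame:
    """Per-session behavior proportions over visible scans.

    Returns one row per (session, behavior state).  Sessions with zero
    visible scans are excluded (their identifiers appear in the result's
    ``attrs["excluded_sessions"]``).
    """
    scans = dataset.scans
    if scans.empty:
        out = pd.DataFrame(columns=["session_id", "subject_id", "behavior_state",
                                    "proportion", "n_visible"])
        out.attrs["excluded_sessions"] = []
        return out
    visible = scans[scans["visible"]]
    n_visible = visible.groupby("session_id").size()
    all_sessions = scans["session_id"].unique()
    excluded = sorted(set(all_sessions) - set(n_visible.index))

    counts = (
        visible.groupby(["session_id", "behavior_state"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ETHOGRAM_STATES), fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    subj = scans.drop_duplicates("session_id").set_index("session_id")["subject_id"]
    out = (
        props.stack()
        .rename("proportion")
        .reset_index()
        .merge(n_visible.rename("n_visible"), left_on="session_id", right_index=True)
    )
    out["subject_id"] = out["session_id"].map(subj)
    out = out[["session_id", "subject_id", "behavior_state", "proportion", "n_visible"]]
    out.attrs["excluded_sessions"] = excluded
    return out


def _session_phase_map(dataset: ScanDataset) -> pd.DataFrame:
    s = dataset.sessions_with_phase()
    return s[["session_id", "subject_id", "condition", "phase"]]


def aggregate_budget(dataset: ScanDataset, drop_excluded_hours: bool = True) -> ActivityBudget:
    """Condition x phase activity budget with two-stage averaging.

    Session proportions are averaged within each subject first, then the
    across-subject mean and SD are reported, so the result is invariant to
    how many sessions each subject completed.  Fall rates (events per
    observation) are appended as a separate ``Fall`` row per cell.
    """
    props = observation_proportions(dataset)
    meta = _session_phase_map(dataset)
    df = props.merge(meta.drop(columns="subject_id"), on="session_id", how="left")
    if drop_excluded_hours:
        df = df[df["phase"] != "excluded"]

    subject_level = (
        df.groupby(["subject_id", "condition", "phase", "behavior_state"],
                   sort=True, observed=True)["proportion"]
        .mean()
        .rename("mean_proportion")
        .reset_index()
    )

    falls = fall_rate(dataset, drop_excluded_hours=drop_excluded_hours)
    fall_subj = falls.subject_level.rename(
        columns={"rate": "mean_proportion"}
    ).assign(behavior_state="Fall")
    subject_all = pd.concat(
        [subject_level, fall_subj[subject_level.columns]], ignore_index=True
    )

    summary = (
        subject_all.groupby(["condition", "phase", "behavior_state"],
                            sort=True, observed=True)["mean_proportion"]
        .agg(mean="mean", sd="std", n_subjects="size")
        .reset_index()
    )
    summary["observed"] = summary["mean"] > 0
    return ActivityBudget(subject_level=subject_all, summary=summary)


@dataclass(frozen=True)
class FallRates:
    subject_level: pd.DataFrame
    summary: pd.DataFrame
    orphan_events: int


def fall_rate(dataset: ScanDataset, drop_excluded_hours: bool = True) -> FallRates:
    """Mean falls per observation by condition x phase.

    Events are joined to their sessions; events whose session is unknown are
    counted as orphans (warning, not error) and excluded.  Averaging is
    within subject first, then across subjects.
    """
    meta = _session_phase_map(dataset)
    events = dataset.events
    known = events[events["session_id"].isin(meta["session_id"])]
    orphan = len(events) - len(known)

    per_session = (
        known.groupby("session_id").size().rename("falls").reindex(
            meta["session_id"], fill_value=0
        )
    )
    df = meta.merge(per_session.reset_index(), on="session_id")
    if drop_excluded_hours:
        df = df[df["phase"] != "excluded"]
    subject_level = (
        df.groupby(["subject_id", "condition", "phase"], sort=True)["falls"]
        .mean()
        .rename("rate")
        .reset_index()
    )
    summary = (
        subject_level.groupby(["condition", "phase"], sort=True)["rate"]
        .agg(mean="mean", sd="std", n_subjects="size")
        .reset_index()
    )
    return FallRates(subject_level=subject_level, summary=summary,
                     orphan_events=orphan)


def paired_mean_difference(
    values_a: pd.Series | dict | "np.ndarray",
    values_b: pd.Series | dict | "np.ndarray",
    conf: float = 0.95,
) -> PairedDifference:
    """Mean of within-pair differences (a - b) with a t-interval.

    Inputs are aligned by index (e.g. subject id) when both are Series or
    dicts; plain arrays pair positionally.  Requires at least two complete
    pairs; the CI uses the t distribution with n-1 degrees of freedom.
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    if isinstance(values_a, (list, tuple, np.ndarray)) and isinstance(
        values_b, (list, tuple, np.ndarray)
    ):
        b.index = a.index
    d = (a - b).dropna()
    n = len(d)
    if n < 2:
        raise InsufficientPairsError(f"need >= 2 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.5 + conf / 2, n - 1) * sd / np.sqrt(n)
    return PairedDifference(mean=mean, sd=sd, ci_low=mean - half,
                            ci_high=mean + half, n_pairs=n)
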