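"""Novelty-test and preference-test outcome measures.

The novel-environment test scores each subject's proportion of 15-s scans
spent active (any non-Inactive state) and in contact with a wall during a
10-minute exposure to an unfamiliar arena, once after each housing
condition.  The enclosure preference test places the subject in a bare
selection chamber joined to replicas of both housing conditions for 24 h
and scores first choice, entry counts, and dwell time per chamber.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "IntervalError",
    "novelty_outcomes",
    "preference_outcomes",
]


class IntervalError(ValueError):
    """Overlapping or otherwise inconsistent preference intervals."""


def novelty_outcomes(novelty: pd.DataFrame) -> pd.DataFrame:
    """Per subject x prior condition novelty-test proportions.

    Returns one row per (subject, prior condition) with the environment
    identity, the proportion of scans active (1 - proportion Inactive), the
    proportion in wall contact, and the scan count.
    """
    if novelty.empty:
        return pd.DataFrame(columns=[
            "subject_id", "prior_condition", "environment",
            "prop_active", "prop_wall_contact", "n_scans",
        ])
    grp = novelty.groupby(["subject_id", "prior_condition"], sort=True)
    rows = []
    for (sid, cond), g in grp:
        rows.append({
            "subject_id": sid,
            "prior_condition": cond,
            "environment": g["environment"].iloc[0],
            "prop_active": float((g["behavior_state"] != "Inactive").mean()),
            "prop_wall_contact": float((g["contact"] == "wall contact").mean()),
            "n_scans": len(g),
        })
    return pd.DataFrame(rows)


def _coalesce(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-chamber intervals (entry counting is invariant
    to how the video was segmented)."""
    merged = []
    for _, row in intervals.iterrows():
        if (
            merged
            and merged[-1]["chamber"] == row["chamber"]
            and abs(merged[-1]["end_s"] - row["start_s"]) < 1e-9
        ):
            merged[-1]["end_s"] = row["end_s"]
        else:
            merged.append(
                {"chamber": row["chamber"], "start_s": float(row["start_s"]),
                 "end_s": float(row["end_s"])}
            )
    return pd.DataFrame(merged)


def preference_outcomes(
    preference: pd.DataFrame, max_seconds: float = 24 * 3600
) -> pd.DataFrame:
    """Per-subject preference-test outcomes from chamber interval records.

    First choice is the chamber of the first interval outside the selection
    chamber ("none" for subjects that never left).  Entry counts tally
    maximal same-chamber intervals per housing chamber; dwell proportions
    divide chamber seconds by total housing-chamber seconds (selection time
    excluded).  Overlapping intervals raise :class:`IntervalError`.
    """
    rows = []
    for sid, g in preference.groupby("subject_id", sort=True):
        g = g.sort_values("start_s").reset_index(drop=True)
        if (g["start_s"].to_numpy()[1:] < g["end_s"].to_numpy()[:-1] - 1e-9).any():
            raise IntervalError(f"subject {sid!r}: overlapping intervals")
        if g["end_s"].max() - g["start_s"].min() > max_seconds + 1e-6:
            raise IntervalError(f"subject {sid!r}: intervals exceed the trial span")
        g = _coalesce(g)
        housing = g[g["chamber"] != "Selection"]
        first = housing["chamber"].iloc[0] if len(housing) else "none"
        secs = (
            housing.assign(dur=housing["end_s"] - housing["start_s"])
            .groupby("chamber")["dur"].sum()
        )
        t_std = float(secs.get("Standard", 0.0))
        t_cpx = float(secs.get("Complex", 0.0))
        total = t_std + t_cpx
        rows.append({
            "subject_id": sid,
            "first_choice": first,
            "entries_standard": int((housing["chamber"] == "Standard").sum()),
            "entries_complex": int((housing["chamber"] == "Complex").sum()),
            "seconds_standard": t_std,
            "seconds_complex": t_cpx,
            "dwell_prop_standard": t_std / total if total > 0 else 0.0,
            "dwell_prop_complex": t_cpx / total if total > 0 else 0.0,
            "entered_both": bool(t_std > 0 and t_cpx > 0),
        })
    return pd.DataFrame(rows)
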