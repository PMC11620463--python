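"""Reading, validating, and normalizing observation record streams.

The study design combines several record streams collected per subject and
housing condition: instantaneous behavior scans (30-s intervals within
10-min sessions), map-grid location fixes (2-min intervals), all-occurrence
fall events, weekly feeding outcomes, body weights, novel-environment-test
scans (15-s intervals), and preference-test chamber intervals.  This module
parses them from a workbook (sheet per stream) or a directory of CSVs into
one typed :class:`ScanDataset`, collecting malformed rows into a rejects
report instead of silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ETHOGRAM_STATES",
    "ELEMENTS",
    "USAGE_CATEGORIES",
    "CHAMBERS",
    "ScanDataset",
    "SchemaError",
    "AlignmentError",
    "assign_light_phase",
    "percent_agreement",
    "read_dataset",
    "validate_sampling",
    "write_dataset",
]

#: Closed behavior vocabulary (mutually exclusive instantaneous states).
ETHOGRAM_STATES = (
    "Inactive",
    "Locomotion",
    "Climb",
    "Active in Place",
    "Preen",
    "Web Construction",
    "Dig/Burrow",
    "Leg Raise",
    "Other",
)

#: States counted as "active" (everything but Inactive).
ACTIVE_STATES = tuple(s for s in ETHOGRAM_STATES if s != "Inactive")

ELEMENTS = ("ground", "wall", "ceiling", "furniture")
USAGE_CATEGORIES = ("In Hide", "On Furniture", "Open Space")
CHAMBERS = ("Standard", "Complex", "Selection")
CONDITIONS = ("Standard", "Complex")
EVENT_TYPES = ("fall",)
CONTACT_CATEGORIES = ("open space", "wall contact")

#: canonical column layout per stream
STREAM_COLUMNS: dict[str, list[str]] = {
    "sessions": ["session_id", "subject_id", "sex", "condition", "date", "hour"],
    "scans": ["subject_id", "session_id", "timestamp", "behavior_state", "visible"],
    "locations": [
        "subject_id", "session_id", "timestamp", "grid_x", "grid_y",
        "element", "element_detail", "usage",
    ],
    "events": ["subject_id", "session_id", "timestamp", "event_type"],
    "feeds": ["subject_id", "condition", "date", "ate"],
    "weights": ["subject_id", "condition", "point", "weight_g"],
    "novelty": [
        "subject_id", "prior_condition", "environment", "timestamp",
        "behavior_state", "contact",
    ],
    "preference": ["subject_id", "chamber", "start_s", "end_s"],
}


class SchemaError(ValueError):
    """A mandatory column or sheet is missing from the input."""


class AlignmentError(ValueError):
    """Coder scan lists cannot be aligned (unequal lengths)."""


def assign_light_phase(hour: int) -> str:
    """Classify an hour of day into the study's light cycle.

    Dark runs 1700-0600, light 0700-1500; the 1600 hour is excluded because
    its lighting was inconsistent.
    """
    if not (isinstance(hour, (int,)) or float(hour).is_integer()):
        raise ValueError(f"hour must be an integer, got {hour!r}")
    hour = int(hour)
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0-23, got {hour}")
    if hour == 16:
        return "excluded"
    if 7 <= hour <= 15:
        return "light"
    return "dark"


@dataclass
class ScanDataset:
    """All observation streams of one study, as normalized DataFrames.

    Each attribute carries the canonical columns in ``STREAM_COLUMNS``;
    ``rejects`` collects rows that failed validation with a reason, so that
    accepted + rejected always equals input.
    """

    sessions: pd.DataFrame = field(default_factory=pd.DataFrame)
    scans: pd.DataFrame = field(default_factory=pd.DataFrame)
    locations: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    feeds: pd.DataFrame = field(default_factory=pd.DataFrame)
    weights: pd.DataFrame = field(default_factory=pd.DataFrame)
    novelty: pd.DataFrame = field(default_factory=pd.DataFrame)
    preference: pd.DataFrame = field(default_factory=pd.DataFrame)
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["stream", "row", "reason"])
    )

    def __post_init__(self) -> None:
        for name, cols in STREAM_COLUMNS.items():
            df = getattr(self, name)
            if df.empty and list(df.columns) != cols:
                object.__setattr__(self, name, pd.DataFrame(columns=cols))

    def streams(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in STREAM_COLUMNS}

    def sessions_with_phase(self) -> pd.DataFrame:
        """Sessions annotated with the dark/light/excluded phase."""
        out = self.sessions.copy()
        out["phase"] = out["hour"].map(assign_light_phase)
        return out

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.streams().items()}


# ---------------------------------------------------------------------------
# row-level validation


def _validate_stream(name: str, df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Return (accepted rows, [(row index, reason), ...])."""
    bad: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask]:
            bad.setdefault(i, reason)

    if name == "scans":
        flag(~df["behavior_state"].isin(ETHOGRAM_STATES), "unknown state")
    elif name == "locations":
        gx = pd.to_numeric(df["grid_x"], errors="coerce")
        gy = pd.to_numeric(df["grid_y"], errors="coerce")
        flag(~(gx.ge(0) & gx.lt(600) & gy.ge(0) & gy.lt(600)),
             "grid coordinates outside [0, 600)")
        flag(~df["element"].isin(ELEMENTS), "unknown element")
        flag(~df["usage"].isin(USAGE_CATEGORIES), "unknown usage category")
        flag(df["usage"].eq("In Hide") & df["element_detail"].isna(),
             "In Hide requires an element_detail")
    elif name == "events":
        flag(~df["event_type"].isin(EVENT_TYPES), "unknown event type")
    elif name == "sessions":
        hours = pd.to_numeric(df["hour"], errors="coerce")
        flag(~(hours.ge(0) & hours.le(23)), "hour outside 0-23")
        flag(~df["condition"].isin(CONDITIONS), "unknown condition")
    elif name == "novelty":
        flag(~df["behavior_state"].isin(ETHOGRAM_STATES), "unknown state")
        flag(~df["contact"].isin(CONTACT_CATEGORIES), "unknown contact category")
    elif name == "preference":
        start = pd.to_numeric(df["start_s"], errors="coerce")
        end = pd.to_numeric(df["end_s"], errors="coerce")
        flag(~end.gt(start), "interval end must exceed start")
        flag(~df["chamber"].isin(CHAMBERS), "unknown chamber")
    elif name == "feeds":
        flag(~df["condition"].isin(CONDITIONS), "unknown condition")
    elif name == "weights":
        w = pd.to_numeric(df["weight_g"], errors="coerce")
        flag(~w.gt(0), "non-positive weight")

    reasons = sorted(bad.items())
    accepted = df.drop(index=[i for i, _ in reasons])
    return accepted, reasons


def read_dataset(
    path: str | Path, schema_map: dict[str, dict] | None = None
) -> ScanDataset:
    """Read a deposited workbook (.xlsx, sheet per stream) or a CSV directory.

    ``schema_map`` optionally remaps sheet/file names and columns per stream:
    ``{"scans": {"sheet": "Scan Data", "columns": {"behavior_state": "Behavior"}}}``.
    Missing optional streams yield empty tables; a missing mandatory column
    raises :class:`SchemaError` naming it.  Malformed rows land in
    ``dataset.rejects`` with a reason.
    """
    path = Path(path)
    schema_map = schema_map or {}
    raw: dict[str, pd.DataFrame] = {}
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        book = pd.read_excel(path, sheet_name=None)
        for name in STREAM_COLUMNS:
            sheet = schema_map.get(name, {}).get("sheet", name)
            if sheet in book:
                raw[name] = book[sheet]
    elif path.is_dir():
        for name in STREAM_COLUMNS:
            fname = schema_map.get(name, {}).get("file", f"{name}.csv")
            f = path / fname
            if f.exists():
                raw[name] = pd.read_csv(f)
    else:
        raise SchemaError(f"{path} is neither an .xlsx workbook nor a directory")

    streams: dict[str, pd.DataFrame] = {}
    rejects: list[dict] = []
    for name, df in raw.items():
        rename = {v: k for k, v in schema_map.get(name, {}).get("columns", {}).items()}
        df = df.rename(columns=rename)
        missing = [c for c in STREAM_COLUMNS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"stream {name!r} is missing column(s): {missing}")
        df = df[STREAM_COLUMNS[name]].reset_index(drop=True)
        if name in {"scans"}:
            df["visible"] = df["visible"].astype(bool)
        if name == "feeds":
            df["ate"] = df["ate"].astype(bool)
        accepted, reasons = _validate_stream(name, df)
        streams[name] = accepted.reset_index(drop=True)
        rejects.extend({"stream": name, "row": i, "reason": r} for i, r in reasons)

    ds = ScanDataset(**streams)
    if rejects:
        ds.rejects = pd.DataFrame(rejects, columns=["stream", "row", "reason"])
    return ds


def write_dataset(dataset: ScanDataset, path: str | Path) -> None:
    """Write a dataset as a CSV directory or a single .xlsx workbook.

    Round-trips with :func:`read_dataset` losslessly for all typed fields.
    """
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path) as writer:
            for name, df in dataset.streams().items():
                df.to_excel(writer, sheet_name=name, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, df in dataset.streams().items():
            df.to_csv(path / f"{name}.csv", index=False)
        if len(dataset.rejects):
            dataset.rejects.to_csv(path / "rejects.csv", index=False)


# ---------------------------------------------------------------------------
# sampling-design checks


def validate_sampling(
    dataset: ScanDataset,
    scans_per_session: int = 20,
    fixes_per_session: int = 6,
    novelty_scans: int = 40,
) -> pd.DataFrame:
    """Flag sessions whose scan/fix counts deviate from the sampling design.

    The 10-min design yields 20 behavior scans (30-s intervals) and 6
    location fixes (2-min intervals, counting t = 0); novelty tests yield
    40 scans (15-s intervals).  Deviations are warnings, never rejections.
    """
    warnings: list[dict] = []

    def check(df: pd.DataFrame, keys: list[str], expected: int, what: str) -> None:
        if df.empty:
            return
        for key, grp in df.groupby(keys, sort=True):
            n = len(grp)
            if n < expected:
                warnings.append(
                    {"scope": what, "key": str(key),
                     "warning": f"missing {what}: {expected - n}"}
                )
            elif n > expected:
                warnings.append(
                    {"scope": what, "key": str(key),
                     "warning": f"excess {what}: {n - expected}"}
                )

    check(dataset.scans, ["session_id"], scans_per_session, "scans")
    check(dataset.locations, ["session_id"], fixes_per_session, "location fixes")
    check(dataset.novelty, ["subject_id", "prior_condition"], novelty_scans,
          "novelty scans")
    return pd.DataFrame(warnings, columns=["scope", "key", "warning"])


def percent_agreement(
    coder_a: list[str], coder_b: list[str], threshold: float = 0.85
) -> pd.DataFrame:
    """Interobserver percent agreement per behavior state.

    For each state, the proportion of aligned scans on which the two coders
    agree about its presence/absence, plus an ``overall`` row (identical
    state calls).  Reliability requires agreement strictly above
    ``threshold``; states at or below it are flagged.
    """
    if len(coder_a) != len(coder_b):
        raise AlignmentError(
            f"scan lists differ in length: {len(coder_a)} vs {len(coder_b)}"
        )
    a = pd.Series(coder_a)
    b = pd.Series(coder_b)
    rows = []
    for state in ETHOGRAM_STATES:
        agree = ((a == state) == (b == state)).mean()
        rows.append({"state": state, "agreement": float(agree),
                     "flagged": bool(agree <= threshold)})
    overall = float((a == b).mean())
    rows.append({"state": "overall", "agreement": overall,
                 "flagged": bool(overall <= threshold)})
    return pd.DataFrame(rows)
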