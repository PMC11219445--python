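"""Domain types, time conventions and tabular I/O for behavioral event bundles.

All within-session times are seconds from session start; intervals are
half-open ``[start_s, end_s)``.  Absolute clock time of an event is the
session's ``start_clock`` plus the within-session offset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DaytimeWindowError, Rejection, SchemaError, ValidationIssue

SEXES = ("male", "female")
AGE_CLASSES = ("infant", "juvenile", "adult")
STATES = ("lying", "sitting", "standing", "walking")
MORPHS = ("CT", "UCT", "unknown")
CONTEXTS = ("resting_sleeping", "tension", "unclassified")
STATUSES = ("spontaneous", "response", "unassigned")
INTENSITIES = ("contact", "no_contact")

#: Half-open 2-h daytime bins covering the observation day.
DAYTIME_BINS = ("08-10", "10-12", "12-14", "14-16", "16-18")
_BIN_EDGES_H = (8, 10, 12, 14, 16, 18)

#: Observation window: events must fall between 08:00 and 18:30.
OBSERVATION_START_S = 8 * 3600
OBSERVATION_END_S = 18 * 3600 + 30 * 60

#: Default length of the tension tail after an aggression ends (seconds).
TENSION_TAIL_S = 180.0

TABLE_FILES = {
    "subjects": "subjects.csv",
    "sessions": "sessions.csv",
    "state_intervals": "state_intervals.csv",
    "yawns": "yawns.csv",
    "aggressions": "aggressions.csv",
    "exposures": "exposures.csv",
    "visibility": "visibility.csv",
}

TABLE_COLUMNS = {
    "subjects": ["subject_id", "sex", "age_years", "age_class"],
    "sessions": ["session_id", "date", "start_clock", "duration_s"],
    "state_intervals": ["subject_id", "session_id", "state", "start_s", "end_s"],
    "yawns": [
        "yawn_id", "subject_id", "session_id", "start_s", "end_s",
        "morph", "au_config", "posture", "context", "daytime_bin", "status",
    ],
    "aggressions": [
        "event_id", "session_id", "winner_id", "loser_id",
        "start_s", "end_s", "intensity", "decided", "witnesses",
    ],
    "exposures": ["trigger_yawn_id", "receiver_id", "seen", "observable_for_s"],
    "visibility": ["subject_id", "session_id", "start_s", "end_s"],
}

_OPTIONAL_STR_COLS = ("au_config", "posture", "context", "daytime_bin", "status", "witnesses")


@dataclass
class EthogramBundle:
    """One dataset: all tables read from / written to a directory."""

    subjects: pd.DataFrame
    sessions: pd.DataFrame
    state_intervals: pd.DataFrame
    yawns: pd.DataFrame
    aggressions: pd.DataFrame
    exposures: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TABLE_COLUMNS["exposures"]))
    visibility: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TABLE_COLUMNS["visibility"]))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_FILES}

    def validate(self) -> list[ValidationIssue]:
        return validate_bundle(self)


# ---------------------------------------------------------------------------
# time conventions

def parse_clock(text: str) -> dt.time:
    """Parse ``HH:MM`` or ``HH:MM:SS`` into a time of day."""
    parts = [int(p) for p in str(text).split(":")]
    if len(parts) == 2:
        parts.append(0)
    return dt.time(*parts)


def clock_seconds(t: dt.time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def assign_daytime_bin(start_clock: dt.time, event_start_s: float) -> str:
    """Return the 2-h daytime bin containing an event's absolute clock time.

    Bins are half-open ``[lower, upper)``.  Events between 18:00 and 18:30
    (observation overrun) are folded into the last bin; anything outside
    08:00-18:30 raises :class:`DaytimeWindowError`.
    """
    abs_s = clock_seconds(start_clock) + float(event_start_s)
    if abs_s < OBSERVATION_START_S or abs_s > OBSERVATION_END_S:
        raise DaytimeWindowError(
            f"event at clock {abs_s / 3600:.3f} h outside observation window 08:00-18:30"
        )
    hour = abs_s / 3600.0
    for lo, hi, label in zip(_BIN_EDGES_H[:-1], _BIN_EDGES_H[1:], DAYTIME_BINS):
        if lo <= hour < hi:
            return label
    return DAYTIME_BINS[-1]  # 18:00-18:30 overrun


def session_start_datetime(session_row: pd.Series) -> dt.datetime:
    date = dt.date.fromisoformat(str(session_row["date"]))
    return dt.datetime.combine(date, parse_clock(session_row["start_clock"]))


def absolute_event_times(yawns: pd.DataFrame, sessions: pd.DataFrame) -> pd.Series:
    """Absolute datetime of each yawn's start, indexed like ``yawns``."""
    starts = {
        row["session_id"]: session_start_datetime(row)
        for _, row in sessions.iterrows()
    }
    return yawns.apply(
        lambda r: starts[r["session_id"]] + dt.timedelta(seconds=float(r["start_s"])),
        axis=1,
    )


# ---------------------------------------------------------------------------
# context assignment

def assign_context(
    yawn_start_s: float,
    subject_id: str,
    aggressions: pd.DataFrame,
    state_intervals: pd.DataFrame,
    tail_s: float = TENSION_TAIL_S,
) -> str:
    """Classify one yawn's context as tension / resting_sleeping / unclassified.

    Tension: the yawn starts inside an aggression interval or within the
    half-open ``tail_s`` tail after its end, and the yawner participated in or
    witnessed the aggression (witness sets are input annotations).  Tension
    wins over resting when the two overlap.  Resting-sleeping: the yawner is
    inside a lying interval.  Anything else is unclassified.
    """
    t = float(yawn_start_s)
    for _, agg in aggressions.iterrows():
        witnesses = _split_ids(agg.get("witnesses", ""))
        involved = subject_id in (agg["winner_id"], agg["loser_id"]) or subject_id in witnesses
        if not involved:
            continue
        if float(agg["start_s"]) <= t < float(agg["end_s"]) + tail_s:
            return "tension"
    mask = (
        (state_intervals["subject_id"] == subject_id)
        & (state_intervals["state"] == "lying")
        & (state_intervals["start_s"].astype(float) <= t)
        & (state_intervals["end_s"].astype(float) > t)
    )
    if mask.any():
        return "resting_sleeping"
    return "unclassified"


def annotate_bundle(
    bundle: EthogramBundle, tail_s: float = TENSION_TAIL_S
) -> tuple[EthogramBundle, list[Rejection]]:
    """Fill the yawns' ``context`` and ``daytime_bin`` columns in place.

    Returns the bundle and a rejection log for events whose clock time falls
    outside the observation window (their bin is left empty).
    """
    rejections: list[Rejection] = []
    sessions = bundle.sessions.set_index("session_id")
    contexts, bins = [], []
    for _, yawn in bundle.yawns.iterrows():
        sid = yawn["session_id"]
        session = sessions.loc[sid]
        agg = bundle.aggressions[bundle.aggressions["session_id"] == sid]
        states = bundle.state_intervals[bundle.state_intervals["session_id"] == sid]
        contexts.append(
            assign_context(yawn["start_s"], yawn["subject_id"], agg, states, tail_s)
        )
        try:
            bins.append(assign_daytime_bin(parse_clock(session["start_clock"]), yawn["start_s"]))
        except DaytimeWindowError:
            bins.append("")
            rejections.append(Rejection(str(yawn["yawn_id"]), "outside_observation_window"))
    bundle.yawns["context"] = contexts
    bundle.yawns["daytime_bin"] = bins
    return bundle, rejections


# ---------------------------------------------------------------------------
# I/O

def _split_ids(text) -> list[str]:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return []
    text = str(text).strip()
    return [t for t in text.split(";") if t] if text else []


def join_ids(ids) -> str:
    return ";".join(str(i) for i in ids)


def write_tables(bundle: EthogramBundle, outdir: str | Path) -> list[Path]:
    """Write every table as UTF-8 CSV with a header row; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in TABLE_FILES.items():
        df = bundle.tables()[name].copy()
        for col in TABLE_COLUMNS[name]:
            if col not in df.columns:
                df[col] = ""
        path = outdir / fname
        df[TABLE_COLUMNS[name]].to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    return written


def read_tables(indir: str | Path) -> EthogramBundle:
    """Read a bundle directory written by :func:`write_tables`."""
    indir = Path(indir)
    frames: dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        path = indir / fname
        if not path.exists():
            if name in ("exposures", "visibility"):
                frames[name] = pd.DataFrame(columns=TABLE_COLUMNS[name])
                continue
            raise SchemaError(f"missing table file: {fname}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(TABLE_COLUMNS[name]) - set(df.columns)
        if missing:
            raise SchemaError(f"{fname}: missing columns {sorted(missing)}")
        frames[name] = _coerce(name, df)
    return EthogramBundle(**frames)


_FLOAT_COLS = {
    "subjects": ["age_years"],
    "sessions": ["duration_s"],
    "state_intervals": ["start_s", "end_s"],
    "yawns": ["start_s", "end_s"],
    "aggressions": ["start_s", "end_s"],
    "exposures": ["observable_for_s"],
    "visibility": ["start_s", "end_s"],
}


def _coerce(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _FLOAT_COLS.get(name, []):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if name == "aggressions" and len(df):
        df["decided"] = df["decided"].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


# ---------------------------------------------------------------------------
# validation

def validate_bundle(bundle: EthogramBundle) -> list[ValidationIssue]:
    """Check every invariant; collect rather than raise."""
    issues: list[ValidationIssue] = []
    sub = bundle.subjects
    known_subjects = set(sub["subject_id"])
    known_sessions = set(bundle.sessions["session_id"])
    known_yawns = set(bundle.yawns["yawn_id"])

    dupes = sub["subject_id"][sub["subject_id"].duplicated()]
    for s in dupes:
        issues.append(ValidationIssue("duplicate_subject", "subjects", str(s), "duplicated id"))
    for _, row in sub.iterrows():
        if row["sex"] not in SEXES:
            issues.append(ValidationIssue("bad_sex", "subjects", str(row["subject_id"]), f"sex={row['sex']}"))
        if row["age_class"] not in AGE_CLASSES:
            issues.append(ValidationIssue("bad_age_class", "subjects", str(row["subject_id"]), f"age_class={row['age_class']}"))
        if float(row["age_years"]) < 0:
            issues.append(ValidationIssue("bad_age", "subjects", str(row["subject_id"]), "negative age"))

    for _, row in bundle.sessions.iterrows():
        if not float(row["duration_s"]) > 0:
            issues.append(ValidationIssue("bad_duration", "sessions", str(row["session_id"]), "duration_s must be > 0"))

    for i, row in bundle.state_intervals.iterrows():
        rid = f"{row['subject_id']}@{row['session_id']}:{row['start_s']}"
        if row["subject_id"] not in known_subjects:
            issues.append(ValidationIssue("unknown_subject", "state_intervals", rid, str(row["subject_id"])))
        if row["session_id"] not in known_sessions:
            issues.append(ValidationIssue("unknown_session", "state_intervals", rid, str(row["session_id"])))
        if row["state"] not in STATES:
            issues.append(ValidationIssue("bad_state", "state_intervals", rid, str(row["state"])))
        if not float(row["end_s"]) > float(row["start_s"]):
            issues.append(ValidationIssue("bad_interval", "state_intervals", rid, "end_s <= start_s"))
    for (subj, sess), grp in bundle.state_intervals.groupby(["subject_id", "session_id"]):
        g = grp.sort_values("start_s")
        prev_end = None
        for _, row in g.iterrows():
            if prev_end is not None and float(row["start_s"]) < prev_end - 1e-9:
                issues.append(ValidationIssue(
                    "overlapping_intervals", "state_intervals",
                    f"{subj}@{sess}:{row['start_s']}", "intervals overlap"))
            prev_end = float(row["end_s"])

    for _, row in bundle.yawns.iterrows():
        rid = str(row["yawn_id"])
        if row["subject_id"] not in known_subjects:
            issues.append(ValidationIssue("unknown_subject", "yawns", rid, str(row["subject_id"])))
        if row["session_id"] not in known_sessions:
            issues.append(ValidationIssue("unknown_session", "yawns", rid, str(row["session_id"])))
        if not float(row["end_s"]) > float(row["start_s"]):
            issues.append(ValidationIssue("bad_interval", "yawns", rid, "end_s <= start_s"))
        if row.get("morph") not in MORPHS and row.get("morph"):
            issues.append(ValidationIssue("bad_morph", "yawns", rid, str(row["morph"])))
        if row.get("context") and row["context"] not in CONTEXTS:
            issues.append(ValidationIssue("bad_context", "yawns", rid, str(row["context"])))
        if row.get("status") and row["status"] not in STATUSES:
            issues.append(ValidationIssue("bad_status", "yawns", rid, str(row["status"])))
        if row.get("daytime_bin") and row["daytime_bin"] not in DAYTIME_BINS:
            issues.append(ValidationIssue("bad_daytime_bin", "yawns", rid, str(row["daytime_bin"])))

    for _, row in bundle.aggressions.iterrows():
        rid = str(row["event_id"])
        if row["winner_id"] == row["loser_id"]:
            issues.append(ValidationIssue("winner_equals_loser", "aggressions", rid, str(row["winner_id"])))
        for col in ("winner_id", "loser_id"):
            if row[col] not in known_subjects:
                issues.append(ValidationIssue("unknown_subject", "aggressions", rid, str(row[col])))
        if not float(row["end_s"]) > float(row["start_s"]):
            issues.append(ValidationIssue("bad_interval", "aggressions", rid, "end_s <= start_s"))
        if row["intensity"] not in INTENSITIES:
            issues.append(ValidationIssue("bad_intensity", "aggressions", rid, str(row["intensity"])))

    for i, row in bundle.exposures.iterrows():
        rid = f"{row['trigger_yawn_id']}->{row['receiver_id']}"
        if row["trigger_yawn_id"] not in known_yawns:
            issues.append(ValidationIssue("unknown_yawn", "exposures", rid, str(row["trigger_yawn_id"])))
        if row["receiver_id"] not in known_subjects:
            issues.append(ValidationIssue("unknown_subject", "exposures", rid, str(row["receiver_id"])))
        if str(row["seen"]).lower() not in ("yes", "no"):
            issues.append(ValidationIssue("bad_seen_flag", "exposures", rid, str(row["seen"])))

    for _, row in bundle.visibility.iterrows():
        rid = f"{row['subject_id']}@{row['session_id']}:{row['start_s']}"
        if row["subject_id"] not in known_subjects:
            issues.append(ValidationIssue("unknown_subject", "visibility", rid, str(row["subject_id"])))
        if not float(row["end_s"]) > float(row["start_s"]):
            issues.append(ValidationIssue("bad_interval", "visibility", rid, "end_s <= start_s"))

    return issues
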