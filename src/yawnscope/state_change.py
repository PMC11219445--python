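"""Slot construction around spontaneous yawns and behavioral-shift detection.

Per retained yawn at t0 the quartet of 1-min conditions is:
C1 = [t0-90, t0-30), Y = [t0-30, t0+30), C2 = [t0+30, t0+90), plus a
same-day, same-subject, same-starting-state baseline minute (BL) free of
yawning.  Y is additionally split into 30-s pre/post halves at t0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import Rejection, StateGapError

SLOT_HALF_SPAN_S = 90.0
SLOT_LEN_S = 60.0
CONDITIONS = ("C1", "Y", "C2", "BL")


def build_slots(t0: float) -> dict[str, tuple[float, float]]:
    """C1/Y/C2 intervals for one yawn; they partition [t0-90, t0+90)."""
    return {
        "C1": (t0 - 90.0, t0 - 30.0),
        "Y": (t0 - 30.0, t0 + 30.0),
        "C2": (t0 + 30.0, t0 + 90.0),
    }


# ---------------------------------------------------------------------------
# eligibility


def _merged_visible(visibility: pd.DataFrame, sessions: pd.DataFrame,
                    subject_id: str, session_id: str) -> list[tuple[float, float]]:
    vis = visibility[
        (visibility["subject_id"] == subject_id)
        & (visibility["session_id"] == session_id)
    ]
    if vis.empty:
        # no explicit visibility rows: assume fully visible for the session
        dur = float(sessions.set_index("session_id").loc[session_id, "duration_s"])
        return [(0.0, dur)]
    spans = sorted((float(r["start_s"]), float(r["end_s"])) for _, r in vis.iterrows())
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def eligible_yawns(
    yawns: pd.DataFrame,
    sessions: pd.DataFrame,
    visibility: pd.DataFrame,
    lead_s: float = SLOT_HALF_SPAN_S,
    tail_s: float = SLOT_HALF_SPAN_S,
) -> tuple[pd.DataFrame, list[Rejection]]:
    """Retain spontaneous yawns continuously visible >= 90 s around t0.

    Response yawns are rejected (``not_spontaneous``); visibility is checked
    against the merged visibility spans, falling back to full-session
    visibility when no spans are annotated.
    """
    retained_idx = []
    rejections: list[Rejection] = []
    for idx, row in yawns.iterrows():
        yid = str(row["yawn_id"])
        if str(row.get("status", "spontaneous")) == "response":
            rejections.append(Rejection(yid, "not_spontaneous"))
            continue
        t0 = float(row["start_s"])
        spans = _merged_visible(visibility, sessions, row["subject_id"], row["session_id"])
        span = next((sp for sp in spans if sp[0] <= t0 < sp[1]), None)
        if span is None:
            rejections.append(Rejection(yid, "not_visible"))
            continue
        if t0 - span[0] < lead_s:
            rejections.append(Rejection(yid, "insufficient_lead"))
            continue
        if span[1] - t0 < tail_s:
            rejections.append(Rejection(yid, "insufficient_tail"))
            continue
        retained_idx.append(idx)
    return yawns.loc[retained_idx].copy(), rejections


def flag_overlapping_slots(retained: pd.DataFrame) -> set[str]:
    """Yawn ids whose C1/Y/C2 span overlaps a neighboring yawn's span."""
    flagged: set[str] = set()
    for sid, grp in retained.groupby("session_id"):
        g = grp.sort_values("start_s")
        rows = list(g.itertuples())
        for a, b in zip(rows, rows[1:]):
            if float(b.start_s) - float(a.start_s) < 2 * SLOT_HALF_SPAN_S:
                flagged.add(str(a.yawn_id))
                flagged.add(str(b.yawn_id))
    return flagged


# ---------------------------------------------------------------------------
# state queries


def _intervals_for(state_intervals: pd.DataFrame, subject_id: str,
                   session_id: str) -> pd.DataFrame:
    return state_intervals[
        (state_intervals["subject_id"] == subject_id)
        & (state_intervals["session_id"] == session_id)
    ].sort_values("start_s")


def state_at(state_intervals: pd.DataFrame, subject_id: str, session_id: str,
             t: float) -> str | None:
    g = _intervals_for(state_intervals, subject_id, session_id)
    hit = g[(g["start_s"].astype(float) <= t) & (g["end_s"].astype(float) > t)]
    return None if hit.empty else str(hit.iloc[0]["state"])


def detect_shift(state_intervals: pd.DataFrame, subject_id: str, session_id: str,
                 interval: tuple[float, float]) -> bool:
    """True iff the subject's state changes at least once within [a, b).

    A transition at time t counts iff a <= t < b: a change exactly at the
    interval end does not count (half-open convention); one exactly at the
    start does, so a change at t0 itself lands in the post-yawn half.
    """
    a, b = float(interval[0]), float(interval[1])
    g = _intervals_for(state_intervals, subject_id, session_id)
    # keep the interval that ends exactly at a: a transition at the window's
    # left edge is between it and its successor
    cover = g[(g["start_s"].astype(float) < b) & (g["end_s"].astype(float) >= a)]
    if cover.empty:
        raise StateGapError(f"state_gap: no coverage of [{a}, {b}) for {subject_id}")
    spans = [(float(r["start_s"]), float(r["end_s"]), str(r["state"]))
             for _, r in cover.iterrows()]
    if spans[0][0] > a + 1e-9 or spans[-1][1] < b - 1e-9:
        raise StateGapError(f"state_gap: [{a}, {b}) not fully covered for {subject_id}")
    for (s1, e1, st1), (s2, e2, st2) in zip(spans, spans[1:]):
        if s2 > e1 + 1e-9:
            raise StateGapError(f"state_gap: hole at {e1} for {subject_id}")
        t_change = s2
        if st2 != st1 and a <= t_change < b:
            return True
    return False


# ---------------------------------------------------------------------------
# baseline selection


def select_baseline(
    yawn: pd.Series,
    state_intervals: pd.DataFrame,
    day_sessions: pd.DataFrame,
    day_yawns: pd.DataFrame,
    rng: np.random.Generator,
    forbid: list[tuple[str, float, float]] | None = None,
) -> tuple[str, float, float] | None:
    """Pick a 60-s baseline block for one yawn, or None when impossible.

    Candidates are integer-second starts within the same subject's sessions
    of the same date whose state at the start equals the state at t0, that
    contain no yawn, and that avoid every window in ``forbid`` (by default
    the C1/Y/C2 spans of all of the day's yawns).  Ties are broken uniformly
    at random with the caller's seeded generator.
    """
    subject = yawn["subject_id"]
    t0 = float(yawn["start_s"])
    anchor_state = state_at(state_intervals, subject, yawn["session_id"], t0)
    if anchor_state is None:
        return None
    forbid = forbid or []
    candidates: list[tuple[str, float]] = []
    for _, sess in day_sessions.iterrows():
        sid = sess["session_id"]
        dur = float(sess["duration_s"])
        g = _intervals_for(state_intervals, subject, sid)
        sess_yawn_times = [
            float(r["start_s"]) for _, r in day_yawns.iterrows()
            if r["session_id"] == sid
        ]
        sess_forbid = [(s, e) for fsid, s, e in forbid if fsid == sid]
        for _, iv in g.iterrows():
            if str(iv["state"]) != anchor_state:
                continue
            lo = int(np.ceil(float(iv["start_s"])))
            hi = int(np.floor(min(float(iv["end_s"]), dur)))
            for start in range(lo, hi):
                end = start + SLOT_LEN_S
                if end > dur:
                    break
                if any(start < t < end or start <= t < end for t in sess_yawn_times):
                    continue
                if any(start < fe and fs < end for fs, fe in sess_forbid):
                    continue
                candidates.append((sid, float(start)))
    if not candidates:
        return None
    sid, start = candidates[int(rng.integers(len(candidates)))]
    return sid, start, start + SLOT_LEN_S


# ---------------------------------------------------------------------------
# long-format datasets


@dataclass
class ShiftDatasets:
    slots: pd.DataFrame     # yawn_id, condition, shift, sex, adi, morph
    y_halves: pd.DataFrame  # yawn_id, y_condition (pre/post), shift, sex, adi, morph
    rejections: list[Rejection]
    missing_baseline: list[str]
    overlap_flagged: set[str]


def build_shift_datasets(bundle, adi_table: pd.DataFrame, seed: int = 0) -> ShiftDatasets:
    """Assemble the per-condition and Y-half shift datasets for the models."""
    subjects = bundle.subjects.set_index("subject_id")
    adi_map = adi_table.set_index("subject_id")["adi"] if len(adi_table) else pd.Series(dtype=float)
    sessions = bundle.sessions
    retained, rejections = eligible_yawns(bundle.yawns, sessions, bundle.visibility)
    overlap_flagged = flag_overlapping_slots(retained)
    rng = np.random.default_rng(seed)

    # per (subject, date): sessions, yawns and forbidden windows
    sess_by_id = sessions.set_index("session_id")
    date_of = sess_by_id["date"].to_dict()
    slot_rows, half_rows, missing_bl = [], [], []
    for _, yawn in retained.iterrows():
        yid = str(yawn["yawn_id"])
        subj = yawn["subject_id"]
        t0 = float(yawn["start_s"])
        sid = yawn["session_id"]
        slots = build_slots(t0)
        sex = subjects.loc[subj, "sex"]
        adi_val = float(adi_map.get(subj, np.nan))
        morph = yawn.get("morph", "unknown")
        try:
            shifts = {
                cond: detect_shift(bundle.state_intervals, subj, sid, iv)
                for cond, iv in slots.items()
            }
            pre = detect_shift(bundle.state_intervals, subj, sid, (t0 - 30.0, t0))
            post = detect_shift(bundle.state_intervals, subj, sid, (t0, t0 + 30.0))
        except StateGapError:
            rejections.append(Rejection(yid, "state_gap"))
            continue

        date = date_of[sid]
        day_sessions = sessions[sessions["date"] == date]
        day_session_ids = set(day_sessions["session_id"])
        day_yawns = bundle.yawns[bundle.yawns["session_id"].isin(day_session_ids)
                                 & (bundle.yawns["subject_id"] == subj)]
        forbid = []
        for _, oy in day_yawns.iterrows():
            ot0 = float(oy["start_s"])
            forbid.append((oy["session_id"], ot0 - 90.0, ot0 + 90.0))
        bl = select_baseline(yawn, bundle.state_intervals, day_sessions, day_yawns,
                             rng, forbid=forbid)
        bl_shift = None
        if bl is not None:
            try:
                bl_shift = detect_shift(bundle.state_intervals, subj, bl[0], (bl[1], bl[2]))
            except StateGapError:
                bl = None
        if bl is None:
            missing_bl.append(yid)

        for cond in ("C1", "Y", "C2"):
            slot_rows.append({"yawn_id": yid, "condition": cond,
                              "shift": int(shifts[cond]), "sex": sex,
                              "adi": adi_val, "morph": morph})
        if bl_shift is not None:
            slot_rows.append({"yawn_id": yid, "condition": "BL",
                              "shift": int(bl_shift), "sex": sex,
                              "adi": adi_val, "morph": morph})
        for half, val in (("pre", pre), ("post", post)):
            half_rows.append({"yawn_id": yid, "y_condition": half,
                              "shift": int(val), "sex": sex,
                              "adi": adi_val, "morph": morph})

    return ShiftDatasets(
        slots=pd.DataFrame(slot_rows, columns=["yawn_id", "condition", "shift", "sex", "adi", "morph"]),
        y_halves=pd.DataFrame(half_rows, columns=["yawn_id", "y_condition", "shift", "sex", "adi", "morph"]),
        rejections=rejections,
        missing_baseline=missing_bl,
        overlap_flagged=overlap_flagged,
    )


# ---------------------------------------------------------------------------
# summaries


def summarize_shift_shares(counts: dict[str, int]) -> dict[str, int]:
    """Each condition's share of all shifts, as nearest-integer percents."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero total shifts: shares undefined")
    return {cond: int(round(100.0 * n / total)) for cond, n in counts.items()}


def shift_share_report(counts: dict[str, int]) -> pd.DataFrame:
    """Shares under both nearest-integer and floor rounding, for transparency."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero total shifts: shares undefined")
    rows = []
    for cond, n in counts.items():
        raw = 100.0 * n / total
        rows.append({"condition": cond, "n_shifts": n, "share_raw": raw,
                     "share_nearest": int(round(raw)), "share_floor": int(np.floor(raw))})
    return pd.DataFrame(rows)
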