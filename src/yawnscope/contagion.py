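"""Yawn-response attribution within the 3-min window and exposure rates.

A receiver's yawn is a response when it falls in the half-open-left window
``(t_trigger, t_trigger + 180]`` after a *seen* trigger yawn; every such
yawn leaves the spontaneous pool.  Exposure records whose receiver was not
followable for the full window and showed no response are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ethogram_model as em
from .errors import Rejection

RESPONSE_WINDOW_S = 180.0


def sex_combination(trigger_sex: str, receiver_sex: str) -> str:
    """Ordered trigger-first pair code: MM, MF, FM or FF."""
    codes = {"male": "M", "female": "F"}
    if trigger_sex not in codes or receiver_sex not in codes:
        raise ValueError(f"unknown sex: {trigger_sex!r}/{receiver_sex!r}")
    return codes[trigger_sex] + codes[receiver_sex]


@dataclass
class AttributionResult:
    records: pd.DataFrame           # one row per retained exposure
    statuses: pd.Series             # yawn_id -> spontaneous | response | unassigned
    dropped: list[Rejection]        # censored exposure records
    chain_depth: dict[str, int] = field(default_factory=dict)


def attribute_responses(
    yawns: pd.DataFrame,
    exposures: pd.DataFrame,
    sessions: pd.DataFrame,
    subjects: pd.DataFrame,
    adi_table: pd.DataFrame | None = None,
    window_s: float = RESPONSE_WINDOW_S,
    chain: bool = True,
) -> AttributionResult:
    """Attribute responses to triggers and partition yawn statuses.

    Multi-trigger ties go to the earliest seen trigger.  With ``chain`` on
    (default) a response yawn may itself trigger further receivers; chain
    depths are logged.  Yawns preceded within the window by another
    subject's yawn that carries no exposure annotation for this receiver are
    left ``unassigned`` (their exposure is unknown, not absent).
    """
    y = yawns.copy()
    y["t_abs"] = em.absolute_event_times(y, sessions)
    y = y.sort_values("t_abs").reset_index(drop=True)
    sex_of = subjects.set_index("subject_id")["sex"].to_dict()
    adi_of = (adi_table.set_index("subject_id")["adi"].to_dict()
              if adi_table is not None and len(adi_table) else {})
    yawn_by_id = y.set_index("yawn_id")

    seen_map: dict[tuple[str, str], pd.Series] = {}
    annotated: dict[str, set[str]] = {}
    for _, ex in exposures.iterrows():
        tid, rid = str(ex["trigger_yawn_id"]), str(ex["receiver_id"])
        annotated.setdefault(tid, set()).add(rid)
        if str(ex["seen"]).lower() == "yes":
            seen_map[(tid, rid)] = ex

    # --- status labeling, in time order so chained triggers are resolved
    status: dict[str, str] = {}
    depth: dict[str, int] = {}
    for _, row in y.iterrows():
        yid, subj, t = str(row["yawn_id"]), row["subject_id"], row["t_abs"]
        label, src_depth = "spontaneous", 0
        best_trigger_t = None
        unknown_exposure = False
        earlier = y[(y["t_abs"] < t) & (y["subject_id"] != subj)]
        for _, prev in earlier.iterrows():
            dt_s = (t - prev["t_abs"]).total_seconds()
            if not (0 < dt_s <= window_s):
                continue
            pid = str(prev["yawn_id"])
            if not chain and status.get(pid) != "spontaneous":
                continue
            if (pid, subj) in seen_map:
                if best_trigger_t is None or prev["t_abs"] < best_trigger_t:
                    best_trigger_t = prev["t_abs"]
                    label = "response"
                    src_depth = depth.get(pid, 0) + 1
            elif subj not in annotated.get(pid, set()):
                unknown_exposure = True
        if label != "response" and unknown_exposure:
            label = "unassigned"
        status[yid] = label
        depth[yid] = src_depth

    # --- exposure-level response records
    records, dropped = [], []
    for _, ex in exposures.iterrows():
        tid, rid = str(ex["trigger_yawn_id"]), str(ex["receiver_id"])
        if tid not in yawn_by_id.index:
            dropped.append(Rejection(f"{tid}->{rid}", "unknown_trigger"))
            continue
        trig = yawn_by_id.loc[tid]
        if not chain and status.get(tid) != "spontaneous":
            dropped.append(Rejection(f"{tid}->{rid}", "chained_trigger_excluded"))
            continue
        t_trig = trig["t_abs"]
        rec_yawns = y[(y["subject_id"] == rid) & (y["t_abs"] > t_trig)]
        latency = None
        for _, ry in rec_yawns.iterrows():
            dt_s = (ry["t_abs"] - t_trig).total_seconds()
            if 0 < dt_s <= window_s:
                latency = dt_s
                break
            if dt_s > window_s:
                break
        observable = float(ex["observable_for_s"]) if str(ex["observable_for_s"]) != "" else window_s
        if latency is None and observable < window_s:
            dropped.append(Rejection(f"{tid}->{rid}", "censored"))
            continue
        t_sex, r_sex = sex_of.get(trig["subject_id"]), sex_of.get(rid)
        adi_t, adi_r = adi_of.get(trig["subject_id"], np.nan), adi_of.get(rid, np.nan)
        records.append({
            "trigger_yawn_id": tid,
            "trigger_subject_id": trig["subject_id"],
            "receiver_id": rid,
            "seen": str(ex["seen"]).lower(),
            "response": latency is not None,
            "latency_s": latency if latency is not None else np.nan,
            "sex_combination": (sex_combination(t_sex, r_sex)
                                if t_sex in ("male", "female") and r_sex in ("male", "female")
                                else ""),
            "delta_adi": abs(adi_t - adi_r) if np.isfinite(adi_t) and np.isfinite(adi_r) else np.nan,
            "trigger_morph": trig.get("morph", "unknown"),
            "trigger_context": trig.get("context", ""),
        })
    rec_df = pd.DataFrame(records, columns=[
        "trigger_yawn_id", "trigger_subject_id", "receiver_id", "seen",
        "response", "latency_s", "sex_combination", "delta_adi",
        "trigger_morph", "trigger_context",
    ])
    return AttributionResult(
        records=rec_df,
        statuses=pd.Series(status, name="status"),
        dropped=dropped,
        chain_depth=depth,
    )


def response_rates(records: pd.DataFrame) -> dict:
    """Response proportions per exposure class, plus latency mean +/- SE.

    Percentages are rounded to two decimals; an empty class is reported as
    None and flagged.
    """
    out: dict = {"flags": []}
    for cls, key in (("yes", "seen"), ("no", "not_seen")):
        sub = records[records["seen"] == cls]
        if len(sub) == 0:
            out[key] = None
            out["flags"].append(f"empty_class:{key}")
            continue
        n_resp = int(sub["response"].sum())
        prop = n_resp / len(sub)
        out[key] = {"n": int(len(sub)), "n_responses": n_resp,
                    "proportion": prop, "pct": round(100.0 * prop, 2)}
    lat = records.loc[records["response"] == True, "latency_s"].dropna()  # noqa: E712
    if len(lat):
        out["latency_mean_s"] = float(lat.mean())
        out["latency_se_s"] = float(lat.std(ddof=1) / np.sqrt(len(lat))) if len(lat) > 1 else 0.0
    else:
        out["latency_mean_s"] = None
        out["latency_se_s"] = None
    return out


def build_response_dataset(records: pd.DataFrame) -> pd.DataFrame:
    """Model-ready rows: outcome, seen flag, sex combination, |dADI|, morph, context.

    Rows missing sex combination or dADI are excluded, mirroring the
    treatment of subjects without a defined dominance index.
    """
    d = records.copy()
    d["response"] = d["response"].astype(int)
    d["pair_id"] = d["trigger_subject_id"].map(str) + "x" + d["receiver_id"].map(str)
    d = d[(d["sex_combination"] != "") & d["delta_adi"].notna()]
    return d.reset_index(drop=True)
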