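"""Seeded generator of complete ethogram bundles with known latent structure.

The generator emits exactly the file set consumed by the readers, plus a
ground-truth sidecar: every latent parameter and each yawn's true
spontaneous/response origin, so parameter-recovery tests can score the
pipeline against the truth.

Structure built in, at defaults:
  * two yawn morphs whose per-AU presence probabilities follow the published
    marginal frequencies (free AUs independent Bernoulli within morph);
  * sex-dependent morph odds and log-normal durations with a sex effect;
  * a boosted state-change hazard in the 30 s after each yawn;
  * a seen-conditional yawn-response process with latencies in (0, 180].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ethogram_model as em
from .errors import GeneratorConfigError
from .facs_morphology import AU_VOCABULARY, AUConfiguration, format_au_string

# Published per-morph AU counts (out of 25 covered-teeth / 39 uncovered-teeth
# configurations) used both for the reconstruction fixture and as default
# presence probabilities.
N_CT, N_UCT = 25, 39
AU_COUNTS_CT = {
    "AU1/2": 2, "AU6": 2, "AU8": 7, "AU9+10": 0, "AU12": 0, "AU16": 0,
    "AU25+26": 25, "AU25+27": 0, "AU43": 4, "AU45": 0, "AD101": 0, "EAD3": 0,
}
AU_COUNTS_UCT = {
    "AU1/2": 0, "AU6": 35, "AU8": 0, "AU9+10": 39, "AU12": 39, "AU16": 39,
    "AU25+26": 0, "AU25+27": 39, "AU43": 5, "AU45": 24, "AD101": 31, "EAD3": 39,
}

STATES = ("lying", "sitting", "standing", "walking")


@dataclass
class GeneratorConfig:
    """All latent knobs of the synthetic ethogram."""

    # group composition
    n_adults: int = 4
    n_juveniles: int = 5
    n_infants: int = 2

    # session schedule
    n_days: int = 8
    sessions_per_day: int = 4
    session_duration_s: float = 900.0
    first_session_clock: str = "08:30"
    inter_session_gap_s: float = 1800.0

    # posture semi-Markov dwell means (s) per state
    dwell_mean_s: dict = field(default_factory=lambda: {
        "lying": 300.0, "sitting": 180.0, "standing": 120.0, "walking": 90.0})

    # aggression process
    aggression_rate_per_session: float = 0.8
    p_decided: float = 0.9
    p_contact: float = 0.4
    p_win_dominant: float = 0.8
    witness_prob: float = 0.5

    # spontaneous yawning
    yawn_rate_per_hour: float = 1.5
    morph_uct_logit_female: float = -0.6   # P(UCT | female) ~ 0.35
    morph_uct_logodds_male: float = 2.8    # males shifted toward UCT
    log_duration_mean: float = 0.94        # log-seconds, CT female
    log_duration_sex_effect: float = 0.21  # added for males
    log_duration_morph_effect: float = 0.21  # added for UCT
    log_duration_sd: float = 0.35

    # per-morph AU presence probabilities (defaults: published marginals)
    au_probs_ct: dict = field(default_factory=lambda: {
        k: v / N_CT for k, v in AU_COUNTS_CT.items()})
    au_probs_uct: dict = field(default_factory=lambda: {
        k: v / N_UCT for k, v in AU_COUNTS_UCT.items()})

    # post-yawn state-change boost: multiplies the baseline transition hazard
    # inside (t0, t0+30]
    post_yawn_hazard_multiplier: float = 6.0

    # contagion
    exposure_prob: float = 0.6
    seen_prob: float = 0.5
    p_response_baseline: float = 0.05
    p_response_seen: float = 0.25
    latency_mean_s: float = 25.0
    observable_full_prob: float = 0.9

    # visibility and coders
    visible_full_prob: float = 0.85
    coder_flip_epsilon: float = 0.05

    def validate(self) -> None:
        probs = [self.p_decided, self.p_contact, self.p_win_dominant,
                 self.witness_prob, self.exposure_prob, self.seen_prob,
                 self.p_response_baseline, self.p_response_seen,
                 self.observable_full_prob, self.visible_full_prob,
                 self.coder_flip_epsilon,
                 *self.au_probs_ct.values(), *self.au_probs_uct.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise GeneratorConfigError("all probabilities must lie in [0, 1]")
        rates = [self.aggression_rate_per_session, self.yawn_rate_per_hour,
                 self.latency_mean_s, self.log_duration_sd,
                 self.post_yawn_hazard_multiplier,
                 *self.dwell_mean_s.values()]
        if any(r <= 0 for r in rates):
            raise GeneratorConfigError("rates, dwell means and multipliers must be positive")
        if self.session_duration_s < 60:
            raise GeneratorConfigError("sessions must last at least 60 s")
        # a session must be able to hold its expected yawns
        expected = self.yawn_rate_per_hour * self.session_duration_s / 3600.0
        if expected > self.session_duration_s / 10.0:
            raise GeneratorConfigError(
                "yawn rate incompatible with session length")
        if self.n_adults + self.n_juveniles < 2:
            raise GeneratorConfigError("need at least 2 non-infant subjects")


# ---------------------------------------------------------------------------
# pieces


def _make_subjects(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    rows = []
    counter = 0
    for n, age_class, age_lo, age_hi in (
        (cfg.n_adults, "adult", 8.0, 20.0),
        (cfg.n_juveniles, "juvenile", 2.0, 5.0),
        (cfg.n_infants, "infant", 0.3, 1.0),
    ):
        for i in range(n):
            counter += 1
            rows.append({
                "subject_id": f"S{counter:02d}",
                "sex": "male" if (counter % 2) else "female",
                "age_years": round(float(rng.uniform(age_lo, age_hi)), 1),
                "age_class": age_class,
            })
    return pd.DataFrame(rows)


def _make_sessions(cfg: GeneratorConfig) -> pd.DataFrame:
    start = em.parse_clock(cfg.first_session_clock)
    base_s = start.hour * 3600 + start.minute * 60
    rows = []
    for day in range(cfg.n_days):
        date = f"2020-09-{day + 1:02d}"
        t = base_s
        for k in range(cfg.sessions_per_day):
            clock = f"{int(t // 3600):02d}:{int((t % 3600) // 60):02d}:{int(t % 60):02d}"
            rows.append({
                "session_id": f"D{day + 1:02d}V{k + 1}",
                "date": date,
                "start_clock": clock,
                "duration_s": cfg.session_duration_s,
            })
            t += cfg.session_duration_s + cfg.inter_session_gap_s
    return pd.DataFrame(rows)


def _simulate_states(cfg: GeneratorConfig, rng, duration: float) -> list[list]:
    """One subject-session semi-Markov posture track covering [0, duration)."""
    state = STATES[int(rng.integers(len(STATES)))]
    t = 0.0
    track = []
    while t < duration:
        dwell = float(rng.exponential(cfg.dwell_mean_s[state]))
        dwell = max(dwell, 1.0)
        end = min(t + dwell, duration)
        track.append([t, end, state])
        t = end
        others = [s for s in STATES if s != state]
        state = others[int(rng.integers(3))]
    return track


def _inject_transition(track: list[list], at: float, rng, duration: float) -> bool:
    """Force a state change at time ``at`` by splitting the covering interval."""
    for i, (s, e, st) in enumerate(track):
        if s <= at < e:
            if at - s < 1.0 or e - at < 1.0:
                return False  # too close to an existing boundary
            others = [x for x in STATES if x != st]
            new_state = others[int(rng.integers(3))]
            track[i] = [s, at, st]
            track.insert(i + 1, [at, e, new_state])
            return True
    return False


def _state_at(track: list[list], t: float) -> str:
    for s, e, st in track:
        if s <= t < e:
            return st
    return track[-1][2]


def _draw_au_config(cfg: GeneratorConfig, morph: str, rng) -> frozenset:
    probs = cfg.au_probs_ct if morph == "CT" else cfg.au_probs_uct
    present = {code for code in AU_VOCABULARY
               if rng.random() < probs.get(code, 0.0)}
    # keep the mouth-opening codes mutually exclusive and morph-consistent
    present.discard("AU25+26")
    present.discard("AU25+27")
    mouth = "AU25+26" if morph == "CT" else "AU25+27"
    if rng.random() < probs.get(mouth, 1.0):
        present.add(mouth)
    return frozenset(present)


# ---------------------------------------------------------------------------
# main entry


def generate_bundle(cfg: GeneratorConfig, seed: int) -> tuple[em.EthogramBundle, dict]:
    """Simulate one full bundle; identical (config, seed) -> identical output."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    subjects = _make_subjects(cfg, rng)
    sessions = _make_sessions(cfg)
    non_infants = subjects[subjects["age_class"] != "infant"]["subject_id"].tolist()
    sex_of = subjects.set_index("subject_id")["sex"].to_dict()
    rank = {s: i for i, s in enumerate(non_infants)}  # low index = dominant

    tracks: dict[tuple[str, str], list[list]] = {}
    for _, sess in sessions.iterrows():
        for subj in subjects["subject_id"]:
            tracks[(subj, sess["session_id"])] = _simulate_states(
                cfg, rng, float(sess["duration_s"]))

    # --- aggressions
    agg_rows = []
    truth_yawns: dict[str, dict] = {}
    eid = 0
    for _, sess in sessions.iterrows():
        n = rng.poisson(cfg.aggression_rate_per_session)
        for _ in range(n):
            pair = rng.choice(len(non_infants), size=2, replace=False)
            a, b = non_infants[pair[0]], non_infants[pair[1]]
            dom, sub = (a, b) if rank[a] < rank[b] else (b, a)
            winner, loser = (dom, sub) if rng.random() < cfg.p_win_dominant else (sub, dom)
            start = float(rng.uniform(0, float(sess["duration_s"]) - 30))
            end = start + float(rng.uniform(5, 30))
            witnesses = [s for s in non_infants
                         if s not in (winner, loser) and rng.random() < cfg.witness_prob]
            eid += 1
            agg_rows.append({
                "event_id": f"A{eid:04d}", "session_id": sess["session_id"],
                "winner_id": winner, "loser_id": loser,
                "start_s": round(start, 2), "end_s": round(end, 2),
                "intensity": "contact" if rng.random() < cfg.p_contact else "no_contact",
                "decided": bool(rng.random() < cfg.p_decided),
                "witnesses": em.join_ids(witnesses),
            })

    # --- spontaneous yawns
    yawn_rows = []
    yid = 0

    def _new_yawn(subj, sess_row, t0, origin, trigger=None):
        nonlocal yid
        yid += 1
        name = f"Y{yid:04d}"
        sex = sex_of[subj]
        logit = cfg.morph_uct_logit_female + (
            cfg.morph_uct_logodds_male if sex == "male" else 0.0)
        morph = "UCT" if rng.random() < 1 / (1 + np.exp(-logit)) else "CT"
        mu = (cfg.log_duration_mean
              + (cfg.log_duration_sex_effect if sex == "male" else 0.0)
              + (cfg.log_duration_morph_effect if morph == "UCT" else 0.0))
        duration = float(np.exp(rng.normal(mu, cfg.log_duration_sd)))
        duration = min(duration, 15.0)
        track = tracks[(subj, sess_row["session_id"])]
        yawn_rows.append({
            "yawn_id": name, "subject_id": subj, "session_id": sess_row["session_id"],
            "start_s": round(t0, 2), "end_s": round(t0 + duration, 2),
            "morph": morph,
            "au_config": format_au_string(_draw_au_config(cfg, morph, rng)),
            "posture": _state_at(track, t0),
            "context": "", "daytime_bin": "", "status": "",
        })
        truth_yawns[name] = {"origin": origin, "trigger": trigger,
                             "sex": sex, "morph": morph,
                             "injected_shift": False}
        # post-yawn hazard boost: extra transition probability in (t0, t0+30]
        m = cfg.post_yawn_hazard_multiplier
        if m > 1.0:
            state = _state_at(track, t0)
            h0 = 1.0 / cfg.dwell_mean_s[state]
            p_extra = 1.0 - np.exp(-(m - 1.0) * h0 * 30.0)
            if rng.random() < p_extra:
                at = t0 + float(rng.uniform(1.0, 29.0))
                if at < float(sess_row["duration_s"]):
                    if _inject_transition(track, at, rng, float(sess_row["duration_s"])):
                        truth_yawns[name]["injected_shift"] = True
        return name, t0

    spont: list[tuple[str, str, pd.Series, float]] = []  # (yawn_id, subj, sess, t0)
    for _, sess in sessions.iterrows():
        lam = cfg.yawn_rate_per_hour * float(sess["duration_s"]) / 3600.0
        for subj in non_infants:
            n = rng.poisson(lam)
            times = np.sort(rng.uniform(0, float(sess["duration_s"]) - 16.0, size=n))
            for t0 in times:
                name, _ = _new_yawn(subj, sess, float(t0), "spontaneous")
                spont.append((name, subj, sess, float(t0)))

    # --- contagion: exposures of other subjects to each spontaneous yawn
    exp_rows = []
    for name, subj, sess, t0 in spont:
        for other in non_infants:
            if other == subj or rng.random() >= cfg.exposure_prob:
                continue
            seen = rng.random() < cfg.seen_prob
            p_resp = cfg.p_response_seen if seen else cfg.p_response_baseline
            responded = rng.random() < p_resp
            latency = np.nan
            if responded:
                latency = float(rng.exponential(cfg.latency_mean_s))
                while latency > 180.0:
                    latency = float(rng.exponential(cfg.latency_mean_s))
                t_resp = t0 + latency
                if t_resp + 16.0 < float(sess["duration_s"]):
                    _new_yawn(other, sess, t_resp, "response", trigger=name)
                else:
                    responded = False
            if responded or rng.random() < cfg.observable_full_prob:
                observable = 180.0
            else:
                observable = round(float(rng.uniform(30.0, 179.0)), 2)
            exp_rows.append({
                "trigger_yawn_id": name, "receiver_id": other,
                "seen": "yes" if seen else "no",
                "observable_for_s": observable,
            })

    # --- state interval and visibility tables from the (possibly modified) tracks
    state_rows, vis_rows = [], []
    for (subj, sid), track in sorted(tracks.items()):
        for s, e, st in track:
            state_rows.append({"subject_id": subj, "session_id": sid,
                               "state": st, "start_s": round(s, 2),
                               "end_s": round(e, 2)})
        dur = float(sessions.set_index("session_id").loc[sid, "duration_s"])
        if rng.random() < cfg.visible_full_prob:
            vis_rows.append({"subject_id": subj, "session_id": sid,
                             "start_s": 0.0, "end_s": dur})
        else:
            s = round(float(rng.uniform(0, dur / 3)), 2)
            e = round(float(rng.uniform(2 * dur / 3, dur)), 2)
            vis_rows.append({"subject_id": subj, "session_id": sid,
                             "start_s": s, "end_s": e})

    bundle = em.EthogramBundle(
        subjects=subjects,
        sessions=sessions,
        state_intervals=pd.DataFrame(state_rows, columns=em.TABLE_COLUMNS["state_intervals"]),
        yawns=pd.DataFrame(yawn_rows, columns=em.TABLE_COLUMNS["yawns"]),
        aggressions=pd.DataFrame(agg_rows, columns=em.TABLE_COLUMNS["aggressions"]),
        exposures=pd.DataFrame(exp_rows, columns=em.TABLE_COLUMNS["exposures"]),
        visibility=pd.DataFrame(vis_rows, columns=em.TABLE_COLUMNS["visibility"]),
    )
    ground_truth = {
        "seed": int(seed),
        "config": _config_dict(cfg),
        "yawns": truth_yawns,
        "dominance_order": non_infants,
    }
    return bundle, ground_truth


def _config_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)


def write_ground_truth(truth: dict, outdir: str | Path) -> Path:
    path = Path(outdir) / "ground_truth.json"
    path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# published-marginals reconstruction fixture


def fixture_table3(seed: int = 0) -> list[AUConfiguration]:
    """25 CT + 39 UCT configurations whose AU column sums match the published
    per-morph counts exactly; deterministic AUs are fixed, free AUs are
    assigned to rows by a seeded draw."""
    rng = np.random.default_rng(seed)
    configs = []
    for label, n, counts in (("CT", N_CT, AU_COUNTS_CT), ("UCT", N_UCT, AU_COUNTS_UCT)):
        rows: list[set] = [set() for _ in range(n)]
        for code in AU_VOCABULARY:
            k = counts[code]
            if k == 0:
                continue
            if k == n:
                for r in rows:
                    r.add(code)
            else:
                chosen = rng.choice(n, size=k, replace=False)
                for i in chosen:
                    rows[int(i)].add(code)
        for i, present in enumerate(rows):
            configs.append(AUConfiguration(
                yawn_id=f"{label}{i + 1:02d}",
                present=frozenset(present),
                apriori_label=label,
            ))
    return configs


# ---------------------------------------------------------------------------
# simulated second coder for reliability checks


def simulate_second_coder(
    configs: list[AUConfiguration], epsilon: float, seed: int = 0
) -> list[AUConfiguration]:
    """Flip each AU's presence independently with probability ``epsilon``."""
    rng = np.random.default_rng(seed)
    out = []
    for cfg_ in configs:
        present = set(cfg_.present)
        for code in AU_VOCABULARY:
            if code in ("AU25+26", "AU25+27"):
                continue  # keep the mouth code fixed: it defines codability
            if rng.random() < epsilon:
                present.symmetric_difference_update({code})
        out.append(AUConfiguration(cfg_.yawn_id, frozenset(present), cfg_.apriori_label))
    return out
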