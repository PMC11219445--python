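import pandas as pd
import pytest

from yawnscope import dominance as dom
from yawnscope import ethogram_model as em
from yawnscope import synthetic_data as syn


@pytest.fixture(scope="session")
def default_bundle():
    bundle, truth = syn.generate_bundle(syn.GeneratorConfig(), seed=1)
    return bundle, truth


@pytest.fixture(scope="session")
def annotated_bundle(default_bundle):
    bundle, truth = default_bundle
    bundle = em.EthogramBundle(**{k: v.copy() for k, v in bundle.tables().items()})
    bundle, _ = em.annotate_bundle(bundle)
    return bundle, truth


@pytest.fixture(scope="session")
def adi_table(annotated_bundle):
    bundle, _ = annotated_bundle
    matrix, _ = dom.build_conflict_matrix(
        bundle.aggressions, bundle.subjects["subject_id"].tolist())
    return dom.adi(matrix)


@pytest.fixture(scope="session")
def table3_configs():
    return syn.fixture_table3(seed=0)


def make_tiny_bundle(
    yawns=None, aggressions=None, state_intervals=None, visibility=None,
    subjects=None, sessions=None,
):
    """Minimal hand-built bundle for unit tests; every argument is a list of dicts."""
    if subjects is None:
        subjects = [
            {"subject_id": "A", "sex": "male", "age_years": 10.0, "age_class": "adult"},
            {"subject_id": "B", "sex": "female", "age_years": 8.0, "age_class": "adult"},
            {"subject_id": "C", "sex": "male", "age_years": 3.0, "age_class": "juvenile"},
        ]
    if sessions is None:
        sessions = [{"session_id": "V1", "date": "2020-09-01",
                     "start_clock": "09:00:00", "duration_s": 600.0}]
    frames = {
        "subjects": pd.DataFrame(subjects),
        "sessions": pd.DataFrame(sessions),
        "state_intervals": pd.DataFrame(
            state_intervals or [], columns=em.TABLE_COLUMNS["state_intervals"]),
        "yawns": pd.DataFrame(yawns or [], columns=em.TABLE_COLUMNS["yawns"]),
        "aggressions": pd.DataFrame(
            aggressions or [], columns=em.TABLE_COLUMNS["aggressions"]),
        "visibility": pd.DataFrame(
            visibility or [], columns=em.TABLE_COLUMNS["visibility"]),
    }
    return em.EthogramBundle(**frames)


def yawn_row(yawn_id="Y1", subject_id="A", session_id="V1", start_s=100.0,
             end_s=103.0, morph="CT", **kw):
    row = {
        "yawn_id": yawn_id, "subject_id": subject_id, "session_id": session_id,
        "start_s": start_s, "end_s": end_s, "morph": morph,
        "au_config": "", "posture": "", "context": "", "daytime_bin": "",
        "status": "",
    }
    row.update(kw)
    return row


def aggression_row(event_id="A1", session_id="V1", winner_id="A", loser_id="B",
                   start_s=50.0, end_s=60.0, intensity="contact", decided=True,
                   witnesses=""):
    return {
        "event_id": event_id, "session_id": session_id, "winner_id": winner_id,
        "loser_id": loser_id, "start_s": start_s, "end_s": end_s,
        "intensity": intensity, "decided": decided, "witnesses": witnesses,
    }
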