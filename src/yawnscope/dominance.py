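"""Decided-conflict matrices and the Average Dominance Index (ADI).

ADI for subject *i* is the mean, over the opponents *j* with whom *i* has at
least one decided conflict, of the proportion of those conflicts won by *i*.
Dyads with no decided conflicts are excluded from the mean, which removes
the bias that unknown relationships introduce in score-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationIssue


@dataclass
class ConflictMatrix:
    subjects: list[str]
    wins: np.ndarray  # wins[i][j] = decided conflicts where i beat j

    def __post_init__(self):
        self.wins = np.asarray(self.wins, dtype=int)
        n = len(self.subjects)
        if self.wins.shape != (n, n):
            raise ValueError("wins matrix must be square over the subject list")
        if np.any(np.diag(self.wins) != 0):
            raise ValueError("diagonal of the conflict matrix must be zero")
        if np.any(self.wins < 0):
            raise ValueError("conflict counts must be non-negative")


def build_conflict_matrix(
    aggressions: pd.DataFrame,
    subjects: list[str],
    contact_only: bool = False,
) -> tuple[ConflictMatrix, list[ValidationIssue]]:
    """Count decided conflicts into a winner x loser matrix.

    Undecided events contribute nothing.  ``contact_only`` restricts to
    contact-intensity events (both intensities count by default).
    """
    idx = {s: i for i, s in enumerate(subjects)}
    wins = np.zeros((len(subjects), len(subjects)), dtype=int)
    issues: list[ValidationIssue] = []
    for _, row in aggressions.iterrows():
        if not bool(row["decided"]):
            continue
        if contact_only and row.get("intensity") != "contact":
            continue
        w, l = str(row["winner_id"]), str(row["loser_id"])
        if w == l:
            issues.append(ValidationIssue(
                "winner_equals_loser", "aggressions", str(row.get("event_id", "?")), w))
            continue
        if w not in idx or l not in idx:
            issues.append(ValidationIssue(
                "unknown_subject", "aggressions", str(row.get("event_id", "?")), f"{w}/{l}"))
            continue
        wins[idx[w], idx[l]] += 1
    return ConflictMatrix(list(subjects), wins), issues


def adi(matrix: ConflictMatrix) -> pd.DataFrame:
    """Per-subject ADI table: adi (NaN where undefined), known dyads, conflicts.

    A subject with no decided conflict against any opponent has no defined
    ADI and is reported with a missing value, to be excluded downstream.
    """
    W = matrix.wins
    totals = W + W.T
    rows = []
    for i, subj in enumerate(matrix.subjects):
        known = np.flatnonzero(totals[i] > 0)
        known = known[known != i]
        if len(known) == 0:
            value = np.nan
        else:
            value = float(np.mean(W[i, known] / totals[i, known]))
        rows.append({
            "subject_id": subj,
            "adi": value,
            "n_known_dyads": int(len(known)),
            "n_decided_conflicts": int(totals[i].sum()),
        })
    return pd.DataFrame(rows)
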