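"""Action-unit configurations, morph discovery and per-AU contrasts.

The clustering step runs directly on the one-hot encoded indicator matrix;
the mixed-data projection (which reduces to multiple correspondence analysis
for all-categorical input) is used for the 2-D visualization coordinates
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import (
    DegenerateInputError,
    InsufficientDistinctPointsError,
    UnknownAUCodeError,
)
from .inference import fisher_exact_2x2

#: The 12-code vocabulary of facial movements coded at gape peak.
AU_VOCABULARY = (
    "AU1/2", "AU6", "AU8", "AU9+10", "AU12", "AU16",
    "AU25+26", "AU25+27", "AU43", "AU45", "AD101", "EAD3",
)

_MUTUALLY_EXCLUSIVE = ("AU25+26", "AU25+27")

# primitive tokens that make up compound codes, used by the string codec
_COMPOUND_PARTS = {
    "AU1/2": ("AU1", "AU2"),
    "AU9+10": ("AU9", "AU10"),
    "AU25+26": ("AU25", "AU26"),
    "AU25+27": ("AU25", "AU27"),
}
_PART_LOOKUP = {parts: code for code, parts in _COMPOUND_PARTS.items()}


@dataclass(frozen=True)
class AUConfiguration:
    """The set of action units active at one yawn's gape peak."""

    yawn_id: str
    present: frozenset[str]
    apriori_label: str | None = None  # "CT" | "UCT"

    def __post_init__(self):
        unknown = self.present - set(AU_VOCABULARY)
        if unknown:
            raise UnknownAUCodeError(f"unknown AU code(s): {sorted(unknown)}")
        if set(_MUTUALLY_EXCLUSIVE) <= self.present:
            raise ValueError("AU25+26 and AU25+27 are mutually exclusive")

    @property
    def mouth_coded(self) -> bool:
        """A codable yawn must carry exactly one mouth-opening code."""
        return len(self.present & set(_MUTUALLY_EXCLUSIVE)) == 1


def parse_au_string(text: str) -> frozenset[str]:
    """Parse a '+'-joined AU string into vocabulary codes.

    Accepts both primitive-token form (``"AU25+AU27+AU12+EAD3"``) and
    canonical compound codes (``"AU25+27"``, where the bare-number token is
    merged with the preceding AU token).
    """
    text = str(text).strip()
    if not text:
        return frozenset()
    raw = [t.strip() for t in text.split("+") if t.strip()]
    tokens: list[str] = []
    for t in raw:
        if t.isdigit() and tokens:  # continuation of a compound code: "AU25+27"
            tokens[-1] = f"{tokens[-1]}+{t}"
        else:
            tokens.append(t)
    codes: set[str] = set()
    pending: list[str] = []
    for t in tokens:
        if t in AU_VOCABULARY:
            codes.add(t)
        elif t in {p for parts in _COMPOUND_PARTS.values() for p in parts}:
            pending.append(t)
        else:
            raise UnknownAUCodeError(f"unknown AU token: {t!r} in {text!r}")
    # pair up primitive tokens into compound codes
    remaining = list(pending)
    for parts, code in _PART_LOOKUP.items():
        if all(p in remaining for p in parts):
            for p in parts:
                remaining.remove(p)
            codes.add(code)
    if remaining:
        raise UnknownAUCodeError(f"unpaired AU token(s): {remaining} in {text!r}")
    return frozenset(codes)


def format_au_string(present: frozenset[str]) -> str:
    """Serialize codes as '+'-joined primitive tokens, in vocabulary order."""
    parts: list[str] = []
    for code in AU_VOCABULARY:
        if code in present:
            parts.extend(_COMPOUND_PARTS.get(code, (code,)))
    return "+".join(parts)


# ---------------------------------------------------------------------------
# one-hot encoding


def one_hot_columns(vocab: tuple[str, ...] = AU_VOCABULARY) -> list[str]:
    return [f"{code}={v}" for code in vocab for v in (1, 0)]


def one_hot_encode(
    configs: list[AUConfiguration], vocab: tuple[str, ...] = AU_VOCABULARY
) -> np.ndarray:
    """Events x (2 * |vocab|) indicator matrix, one dummy per (code, value).

    Every row sums to ``|vocab|``: each code contributes exactly one of its
    present/absent dummies.
    """
    out = np.zeros((len(configs), 2 * len(vocab)))
    vocab_set = set(vocab)
    for i, cfg in enumerate(configs):
        unknown = cfg.present - vocab_set
        if unknown:
            raise UnknownAUCodeError(f"unknown AU code(s): {sorted(unknown)}")
        for j, code in enumerate(vocab):
            if code in cfg.present:
                out[i, 2 * j] = 1.0
            else:
                out[i, 2 * j + 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# mixed-data projection (MCA special case for all-categorical dummies)


@dataclass
class MixedPCAResult:
    coordinates: np.ndarray       # events x n_dims principal coordinates
    variance_fractions: np.ndarray
    column_coordinates: np.ndarray
    column_names: list[str]


def project_mixed_pca(matrix: np.ndarray, n_dims: int = 2,
                      column_names: list[str] | None = None) -> MixedPCAResult:
    """Correspondence-analysis projection of a 0/1 indicator matrix.

    With purely categorical dummies this is multiple correspondence analysis:
    a generalized SVD of the centered, mass-standardized indicator matrix.
    Constant (zero-mass) dummy columns are dropped with a warning.
    """
    Z = np.asarray(matrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3:
        raise DegenerateInputError("degenerate_input: need >= 3 events")
    names = column_names or [f"col{j}" for j in range(Z.shape[1])]
    keep = Z.sum(axis=0) > 0
    if keep.sum() < Z.shape[1]:
        warnings.warn(f"dropping {int((~keep).sum())} empty dummy column(s)", stacklevel=2)
        Z = Z[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    col_var = Z.var(axis=0)
    if (col_var > 1e-12).sum() < 2:
        raise DegenerateInputError("degenerate_input: fewer than 2 non-constant dummies")

    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, svals, Vt = np.linalg.svd(S, full_matrices=False)
    nz = svals > 1e-12
    U, svals, Vt = U[:, nz], svals[nz], Vt[nz]
    inertia = svals**2
    fractions = inertia / inertia.sum()
    row_coords = (U * svals) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * svals) / np.sqrt(c)[:, None]
    k = min(n_dims, len(svals))
    return MixedPCAResult(
        coordinates=row_coords[:, :k],
        variance_fractions=fractions[:k],
        column_coordinates=col_coords[:, :k],
        column_names=names,
    )


# ---------------------------------------------------------------------------
# clustering


def cluster_kmeans(matrix: np.ndarray, k: int = 2, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """k-means partition of the one-hot rows; deterministic given seed."""
    X = np.asarray(matrix, dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise InsufficientDistinctPointsError(
            f"insufficient_distinct_points: k={k} > {n_distinct} distinct rows"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)


def cluster_purity(labels, apriori_labels) -> float:
    """Percent agreement under the best cluster-to-class mapping (0..100)."""
    labels = np.asarray(labels)
    apriori = np.asarray(apriori_labels)
    if len(labels) != len(apriori):
        raise ValueError("length mismatch between labels and a-priori labels")
    clusters = np.unique(labels)
    classes = np.unique(apriori)
    conf = np.zeros((len(clusters), len(classes)))
    for i, cl in enumerate(clusters):
        for j, cs in enumerate(classes):
            conf[i, j] = np.sum((labels == cl) & (apriori == cs))
    rows, cols = linear_sum_assignment(-conf)
    return float(100.0 * conf[rows, cols].sum() / len(labels))


@dataclass
class MorphClusteringResult:
    one_hot: np.ndarray
    labels: np.ndarray
    projection: MixedPCAResult
    purity: float
    cluster_sizes: dict[int, int] = field(default_factory=dict)


def discover_morphs(configs: list[AUConfiguration], k: int = 2, seed: int = 0,
                    n_init: int = 10) -> MorphClusteringResult:
    """One-hot encode, cluster on the dummies, project for display, score purity."""
    X = one_hot_encode(configs)
    labels = cluster_kmeans(X, k=k, seed=seed, n_init=n_init)
    proj = project_mixed_pca(X, column_names=one_hot_columns())
    apriori = [c.apriori_label for c in configs]
    purity = (cluster_purity(labels, apriori)
              if all(a is not None for a in apriori) else float("nan"))
    sizes = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    return MorphClusteringResult(one_hot=X, labels=labels, projection=proj,
                                 purity=purity, cluster_sizes=sizes)


# ---------------------------------------------------------------------------
# per-AU contrasts


def au_contrast_table(
    configs_ct: list[AUConfiguration], configs_uct: list[AUConfiguration]
) -> pd.DataFrame:
    """Per-AU 2x2 contrast (present/absent x morph) with two-sided Fisher p.

    Percentages are within-group and rounded to two decimals, matching the
    reporting convention of the source tables.
    """
    if not configs_ct or not configs_uct:
        raise ValueError("both groups must be non-empty")
    n_ct, n_uct = len(configs_ct), len(configs_uct)
    rows = []
    for code in AU_VOCABULARY:
        a = sum(code in c.present for c in configs_ct)
        c_ = sum(code in c.present for c in configs_uct)
        p = fisher_exact_2x2(a, n_ct - a, c_, n_uct - c_)
        rows.append({
            "au_code": code,
            "n_ct": a, "pct_ct": round(100.0 * a / n_ct, 2),
            "n_uct": c_, "pct_uct": round(100.0 * c_ / n_uct, 2),
            "p_value": p,
        })
    return pd.DataFrame(rows)
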