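"""Inter-observer reliability: Cohen's kappa and the per-expression AU agreement.

The AU agreement for one expression is 2|A∩B| / (|A| + |B|) over the two
coders' AU sets, averaged (unweighted) over expressions for each coder pair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def cohens_kappa(labels1, labels2) -> float:
    """Cohen's kappa for two categorical label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from marginal
    products.  When both coders are constant and identical (p_e = 1) kappa
    is defined as 1, with a warning.
    """
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if len(l1) != len(l2):
        raise ValueError("label vectors must have equal length")
    if len(l1) < 2:
        raise ValueError("need at least 2 items")
    n = len(l1)
    cats = np.unique(np.concatenate([l1, l2]))
    p_o = float(np.mean(l1 == l2))
    p_e = float(sum(np.mean(l1 == c) * np.mean(l2 == c) for c in cats))
    if p_e >= 1.0 - 1e-12:
        warnings.warn("both coders constant and equal: kappa defined as 1", stacklevel=2)
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def facs_agreement(set1, set2) -> float:
    """Per-expression agreement ratio 2|A∩B| / (|A| + |B|), in [0, 1]."""
    s1, s2 = set(set1), set(set2)
    if not s1 and not s2:
        warnings.warn("both AU sets empty: agreement defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))


def mean_facs_agreement(pairs: list[tuple[set, set]]) -> float:
    """Unweighted mean agreement over expressions for one coder pair."""
    if not pairs:
        raise ValueError("no coded expressions")
    return float(np.mean([facs_agreement(a, b) for a, b in pairs]))


def agreement_report(coder_tables: dict[str, list[frozenset]]) -> pd.DataFrame:
    """Pairwise mean agreement for every dyad of coders.

    ``coder_tables`` maps coder name to a list of AU sets over the same
    shared items, in the same order.
    """
    names = sorted(coder_tables)
    lengths = {len(v) for v in coder_tables.values()}
    if len(lengths) != 1:
        raise ValueError("coders must cover the same items")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs = list(zip(coder_tables[a], coder_tables[b]))
            rows.append({"coder_1": a, "coder_2": b,
                         "mean_agreement": mean_facs_agreement(pairs),
                         "n_items": len(pairs)})
    return pd.DataFrame(rows)
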