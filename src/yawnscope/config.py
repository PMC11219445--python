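"""Run-time configuration: time conventions, bin edges, window lengths.

Every default records its provenance so reports can state where a number
came from (published design value vs. package decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    tension_tail_s: float = 180.0        # 3-min block after an aggression
    response_window_s: float = 180.0     # 3-min yawn-response window
    slot_len_s: float = 60.0             # 1-min condition slots
    slot_half_span_s: float = 90.0       # visibility required each side of t0
    chain_contagion: bool = True         # responses may trigger further responses
    baseline_avoid_slots: bool = True    # BL may not overlap any C1/Y/C2
    provenance: dict = field(default_factory=lambda: {
        "tension_tail_s": "published design: 3-min block following the aggression",
        "response_window_s": "published design: 3-min response window",
        "slot_len_s": "published design: 1-min slots",
        "slot_half_span_s": "published design: 90 s visibility each side",
        "chain_contagion": "package decision: chained attribution on by default",
        "baseline_avoid_slots": "package decision: stricter than source protocol",
    })


def load_config(path: str | Path | None) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = AnalysisConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key: {key}")
        setattr(cfg, key, value)
        cfg.provenance[key] = f"user config file: {path}"
    return cfg
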