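"""Binary remission labels from endpoint depression-scale scores.

Remission is the gold-standard binary trial outcome: an endpoint severity
score at or below a scale-specific cutoff (MADRS <= 10, HAM-D <= 7).
"""

from __future__ import annotations

import numpy as np

__all__ = ["label_remission", "SCALE_RANGES", "DEFAULT_CUTOFFS"]

SCALE_RANGES = {"MADRS": (0, 60), "HAMD": (0, 52)}
DEFAULT_CUTOFFS = {"MADRS": 10, "HAMD": 7}

_ALIASES = {"HAM-D": "HAMD", "HAM_D": "HAMD", "HDRS": "HAMD"}


def label_remission(scale_name: str, endpoint_score, cutoffs: dict | None = None):
    """True iff ``endpoint_score`` is at or below the scale's remission cutoff.

    Accepts a scalar or array of scores; cutoffs are configurable but
    default to MADRS <= 10 and HAM-D <= 7.
    """
    key = _ALIASES.get(str(scale_name).upper(), str(scale_name).upper())
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    if key not in cutoffs or key not in SCALE_RANGES:
        raise ValueError(f"unknown rating scale {scale_name!r}")
    lo, hi = SCALE_RANGES[key]
    score = np.asarray(endpoint_score)
    if ((score < lo) | (score > hi)).any():
        raise ValueError(f"{key} score out of admissible range [{lo}, {hi}]")
    result = score <= cutoffs[key]
    return bool(result) if np.ndim(endpoint_score) == 0 else result
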