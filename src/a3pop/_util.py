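"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the published tables;
    Python's built-in ``round`` is banker's rounding)."""
    factor = 10 ** ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor if ndigits else float(rounded)
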