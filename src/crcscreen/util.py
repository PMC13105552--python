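"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (commercial rounding)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x))
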