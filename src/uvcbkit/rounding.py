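"""Report rounding helpers."""

from __future__ import annotations

import math

__all__ = ["round_sig"]


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (half-to-even, like round)."""
    if x == 0:
        return 0.0
    if sig < 1:
        raise ValueError("sig must be >= 1")
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)
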