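"""Half-up rounding at the precision the study reports its numbers at.

Python's builtin ``round`` is banker's rounding; reported tables round halves
away from zero (93.65 -> 93.7, 89 655.75 -> 89 656), so every user-facing
percentage and average goes through these helpers.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, halves away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up_int(value: float) -> int:
    return int(round_half_up(value, 0))
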