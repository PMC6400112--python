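"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

#: Internal upper age (exclusive) used to close open-ended "x+" age bands.
AGE_CAP = 120


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of the published tables (e.g. 82.75 -> 82.8).
    """
    if not math.isfinite(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 0) -> float:
    """Truncate toward zero at ``ndigits`` decimal places."""
    factor = 10.0 ** ndigits
    return math.trunc(x * factor) / factor
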