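"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention).

    Python's built-in ``round`` is banker's rounding; reported tables in this
    domain use the conventional half-up rule. ``repr`` is taken first so the
    decimal expansion of the float does not leak into the rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
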