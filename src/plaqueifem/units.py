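"""Unit conventions.

All internal quantities are kPa and mm.  Pressures in configuration files
and CLI options are given in mmHg (the clinical convention) and converted
once, here.
"""

from decimal import ROUND_HALF_UP, Decimal

#: 1 mmHg in kPa.  Single definition used everywhere.
MMHG_TO_KPA = 0.1333224


def mmhg_to_kpa(p_mmhg):
    return p_mmhg * MMHG_TO_KPA


def kpa_to_mmhg(p_kpa):
    return p_kpa / MMHG_TO_KPA


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed summary tables do.

    numpy/python ``round`` is banker's rounding; report tables use the
    conventional half-up rule, so summaries go through this helper.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
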