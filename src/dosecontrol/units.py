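"""Centralized time-unit conversions.

All pharmacokinetic computation is carried out in hours (absorption and
elimination rates are hourly); cell-population dynamics and tumor-burden
series are day-denominated.  Every day<->hour conversion in the package
goes through these two helpers.
"""

HOURS_PER_DAY = 24.0


def days_to_hours(days: float) -> float:
    return days * HOURS_PER_DAY


def hours_to_days(hours: float) -> float:
    return hours / HOURS_PER_DAY
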