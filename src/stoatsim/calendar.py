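"""365-day simulation calendar.

The model runs on an idealised calendar with no leap days.  Dates are
(year, day-of-year) pairs with 1 January = day 1.  All seasonal events are
fixed dates:

* oestrous (mating) window: 15 September - 15 January
* decoy deployments: 15 September and (optionally) 15 November
* births: 30 October; dams re-enter oestrus 10 days later (9 November)
* kit dispersal: 16 January
* trap sessions: 14 days starting 20 January, 20 July and 20 November

Simulations start on 15 September of year 0; absolute day index 0 maps to
that date.
"""

from __future__ import annotations

DAYS_PER_YEAR = 365

# day-of-year constants (non-leap year)
OESTRUS_START = 258   # 15 September
OESTRUS_END = 15      # 15 January (inclusive)
DISPERSAL_DAY = 16    # 16 January
BIRTH_DAY = 303       # 30 October
REDEPLOY_DAY = 319    # 15 November
DAM_OESTRUS_DAY = 313  # 9 November: birth + 10 days
SESSION_STARTS = (20, 201, 324)  # 20 January, 20 July, 20 November
SESSION_LENGTH = 14

SIM_START_DOY = OESTRUS_START  # simulations begin on 15 September


def to_date(day_index: int) -> tuple[int, int]:
    """Absolute day index (0 = 15 Sep of year 0) -> (year, day-of-year)."""
    absolute = SIM_START_DOY - 1 + day_index
    return absolute // DAYS_PER_YEAR, absolute % DAYS_PER_YEAR + 1


def to_day_index(year: int, doy: int) -> int:
    return year * DAYS_PER_YEAR + (doy - 1) - (SIM_START_DOY - 1)


def in_oestrous_window(doy: int) -> bool:
    """True during the 15 Sep - 15 Jan receptive window (inclusive)."""
    return doy >= OESTRUS_START or doy <= OESTRUS_END


def season_start_year(year: int, doy: int) -> int:
    """Year in which the oestrous season containing this date began.

    Dates outside the window are assigned to the season that most recently
    began (used only for due-date arithmetic on mating dates, which always
    fall inside the window).
    """
    return year if doy >= OESTRUS_START else year - 1


def traps_active(doy: int) -> bool:
    """True while any trapping session has attractive bait.

    Bait is refreshed on 20 January, 20 July and 20 November and stays
    attractive for 14 days.
    """
    for start in SESSION_STARTS:
        if start <= doy <= start + SESSION_LENGTH - 1:
            return True
    return False
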