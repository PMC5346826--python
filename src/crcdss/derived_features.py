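"""Derived patient features: BMI category, Persian-calendar conversion, age category.

The screening system stores Persian (Jalali/Solar Hijri) birthdates and derives
two coded features from raw anthropometry and the birthdate:

* a four-level BMI category with cut points 18.5 / 24.9 / 29.9 kg/m², applied as
  a strict ``<`` chain;
* a three-level age category (<45, 45–64, ≥65 years), with age computed as the
  difference between a Gregorian reference year and the Gregorian birth year.

Both derivations ship in two modes.  ``faithful`` reproduces the deployed
system's exact control flow, including its quirks: an undefined BMI (missing or
zero weight/height) fails every ``<`` comparison and falls through to category
4, and age ignores month and day.  ``strict`` returns a missing sentinel for
undefined BMI and is otherwise identical.  ``compute_age_category`` likewise
offers a ``corrected`` flag that subtracts one year when the birthday has not
yet occurred in the reference year; it is off by default.

Calendar conversion uses the arithmetic 33-year-cycle leap rule (a Persian year
``y`` is leap iff ``(25*y + 11) % 33 < 8``), which agrees with astronomical
reckoning throughout the supported range 1300–1450 AP.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import DateError

MISSING = -1
"""Sentinel for a missing coded value; distinct from every live code (0 codes "No")."""

#: BMI thresholds of the strict-< classification chain, category i+1 applies below them.
BMI_THRESHOLDS = (18.5, 24.9, 29.9)

#: Age-category thresholds in years: <45 -> 1, <65 -> 2, else 3.
AGE_THRESHOLDS = (45, 65)

JALALI_MIN_YEAR = 1300
JALALI_MAX_YEAR = 1450

_DATE_RE = re.compile(r"^(\d{3,4})-(\d{1,2})-(\d{1,2})$")


@dataclass(frozen=True)
class BmiResult:
    """Body-mass index in kg/m² (None when undefined) and its category code."""

    bmi: Optional[float]
    category: int

    def __post_init__(self):
        if self.bmi is not None and self.category not in (1, 2, 3, 4):
            raise ValueError("category must be 1..4 when bmi is defined")


@dataclass(frozen=True)
class AgeResult:
    gregorian_birthdate: _dt.date
    age: int
    category: int


def compute_bmi(weight: Optional[float], height: Optional[float], mode: str = "strict") -> BmiResult:
    """Classify BMI = weight / (height/100)² into categories 1–4.

    Parameters
    ----------
    weight : float or None
        Body weight in kilograms.
    height : float or None
        Standing height in centimetres.
    mode : {"strict", "faithful"}
        ``strict`` returns the missing sentinel category when BMI is undefined;
        ``faithful`` replicates the deployed conditional chain, where an
        undefined BMI fails every ``<`` test and lands in category 4.
    """
    if mode not in ("strict", "faithful"):
        raise ValueError(f"unknown mode {mode!r}")
    if (weight is not None and weight < 0) or (height is not None and height < 0):
        raise ValueError("weight and height must be nonnegative")
    if weight and height:
        bmi = weight / (height / 100.0) ** 2
        if bmi < BMI_THRESHOLDS[0]:
            return BmiResult(bmi, 1)
        elif bmi < BMI_THRESHOLDS[1]:
            return BmiResult(bmi, 2)
        elif bmi < BMI_THRESHOLDS[2]:
            return BmiResult(bmi, 3)
        return BmiResult(bmi, 4)
    # weight/height missing or zero: BMI undefined
    if mode == "faithful":
        return BmiResult(None, 4)
    return BmiResult(None, MISSING)


# ---------------------------------------------------------------------------
# Persian (Jalali) <-> Gregorian calendar arithmetic.
# Day counting against a fixed anchor: 1 Farvardin 1370 AP == 1991-03-21.
# ---------------------------------------------------------------------------


def is_jalali_leap(year: int) -> bool:
    """Arithmetic 33-year-cycle leap rule for the Solar Hijri calendar."""
    return (25 * year + 11) % 33 < 8


def _leaps_through(year: int) -> int:
    # number of leap years among 1..year under the 33-year rule (closed form)
    return (8 * year + 29) // 33


def _jalali_day_number(year: int, month: int, day: int) -> int:
    month_offset = 31 * (month - 1) if month <= 7 else 186 + 30 * (month - 7)
    return 365 * (year - 1) + _leaps_through(year - 1) + month_offset + day


_ANCHOR_DN = _jalali_day_number(1370, 1, 1)
_ANCHOR_GREGORIAN = _dt.date(1991, 3, 21)


def _month_length(year: int, month: int) -> int:
    if month <= 6:
        return 31
    if month <= 11:
        return 30
    return 30 if is_jalali_leap(year) else 29


def _check_jalali(year: int, month: int, day: int) -> None:
    if not (JALALI_MIN_YEAR <= year <= JALALI_MAX_YEAR):
        raise DateError(f"Persian year {year} outside supported range "
                        f"{JALALI_MIN_YEAR}-{JALALI_MAX_YEAR}")
    if not 1 <= month <= 12:
        raise DateError(f"Persian month {month} out of range 1-12")
    if not 1 <= day <= _month_length(year, month):
        raise DateError(f"day {day} invalid for Persian month {year}-{month}")


def jalali_to_gregorian(year: int, month: int, day: int) -> _dt.date:
    """Convert a Persian civil date to the corresponding Gregorian date."""
    _check_jalali(year, month, day)
    return _ANCHOR_GREGORIAN + _dt.timedelta(days=_jalali_day_number(year, month, day) - _ANCHOR_DN)


def gregorian_to_jalali(date: _dt.date) -> Tuple[int, int, int]:
    """Inverse of :func:`jalali_to_gregorian` (exact over the supported range)."""
    target = (date - _ANCHOR_GREGORIAN).days + _ANCHOR_DN
    year = max(1, (target * 33) // (33 * 365 + 8))
    while _jalali_day_number(year + 1, 1, 1) <= target:
        year += 1
    while _jalali_day_number(year, 1, 1) > target:
        year -= 1
    rem = target - _jalali_day_number(year, 1, 1)  # zero-based day of year
    if rem < 186:
        month, day = rem // 31 + 1, rem % 31 + 1
    else:
        month, day = (rem - 186) // 30 + 7, (rem - 186) % 30 + 1
    return year, month, day


def parse_persian_date(text: str) -> Tuple[int, int, int]:
    """Parse a ``"YYYY-MM-DD"`` Persian date string, validating the calendar."""
    m = _DATE_RE.match(text.strip()) if isinstance(text, str) else None
    if m is None:
        raise DateError(f"cannot parse Persian date {text!r}; expected YYYY-MM-DD")
    year, month, day = (int(g) for g in m.groups())
    _check_jalali(year, month, day)
    return year, month, day


def age_category_from_age(age: int) -> int:
    if age < AGE_THRESHOLDS[0]:
        return 1
    elif age < AGE_THRESHOLDS[1]:
        return 2
    return 3


def compute_age_category(birthdate_persian: str, reference_year: int,
                         corrected: bool = False) -> AgeResult:
    """Derive age and its category from a Persian birthdate string.

    ``age`` is ``reference_year`` minus the Gregorian birth year — deliberately
    no month/day adjustment, matching the deployed system.  ``corrected=True``
    instead counts completed years as of July 1 of the reference year (a
    mid-year convention, since only a year is supplied): one year is subtracted
    when the birthday falls after July 1.
    """
    y, m, d = parse_persian_date(birthdate_persian)
    bdate = jalali_to_gregorian(y, m, d)
    age = reference_year - bdate.year
    if corrected and (bdate.month, bdate.day) > (7, 1):
        age -= 1
    return AgeResult(bdate, age, age_category_from_age(age))
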