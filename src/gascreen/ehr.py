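"""Keyword-based EHR shortlisting from clinic letters.

A plain substring search — case-insensitive, with internal whitespace
normalized — for a diagnosis keyword (default "geographic atrophy") across a
patient's letters.  The earliest matching letter's date flags the patient's
subsequent retinal scans (same-day scans count as subsequent, since letters
typically follow the visit that produced the scan).  No stemming, negation
handling or concept extraction: the point of this arm is to model what a
naive EHR search actually does.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date

DEFAULT_KEYWORD = "geographic atrophy"

_WS = re.compile(r"\s+")


def _normalize(text: str) -> str:
    return _WS.sub(" ", text).casefold().strip()


@dataclass(frozen=True)
class EHRFlag:
    """Outcome of the keyword search for one patient.

    ``matched`` iff the keyword appears in at least one letter;
    ``earliest_date`` is the date of the earliest matching letter (present
    exactly when ``matched``).
    """

    patient_id: str
    matched: bool
    earliest_date: date | None = None

    def __post_init__(self) -> None:
        if self.matched != (self.earliest_date is not None):
            raise ValueError("matched <=> earliest_date present")


def keyword_search(
    letters: list[tuple[date, str]],
    keyword: str = DEFAULT_KEYWORD,
    patient_id: str = "",
) -> EHRFlag:
    """Search a patient's letters for the keyword.

    Matching is a case-insensitive substring test after collapsing runs of
    whitespace in both the letter text and the keyword, so "Geographic
    Atrophy" and a line-wrapped "geographic\\natrophy" both match.
    """
    needle = _normalize(keyword)
    match_dates = [d for d, text in letters if needle in _normalize(text)]
    if not match_dates:
        return EHRFlag(patient_id=patient_id, matched=False)
    return EHRFlag(patient_id=patient_id, matched=True, earliest_date=min(match_dates))


def flag_scans(flag: EHRFlag, scan_dates: list[date]) -> list[bool]:
    """Flag each scan acquired on or after the earliest keyword mention."""
    if not flag.matched:
        return [False] * len(scan_dates)
    return [d >= flag.earliest_date for d in scan_dates]
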