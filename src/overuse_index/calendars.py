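"""Study calendar: quarter indexing and the eligibility lookback window.

The study window is divided into consecutive calendar quarters indexed
1..n_quarters (default 12, i.e. 2016Q1-2018Q4).  Claims dated before the
study start but on/after the lookback start may establish eligibility but
never contribute events.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = ["StudyCalendar", "DEFAULT_CALENDAR"]


@dataclass(frozen=True)
class StudyCalendar:
    """Maps calendar dates to 1-based quarter indices.

    Parameters
    ----------
    study_start : date
        First day of quarter 1.  Must be the first day of a calendar quarter.
    n_quarters : int
        Number of quarters in the study window.
    lookback_start : date
        Earliest date at which claims may establish eligibility.
    """

    study_start: date = date(2016, 1, 1)
    n_quarters: int = 12
    lookback_start: date = date(2015, 7, 1)

    def __post_init__(self) -> None:
        if self.study_start.month not in (1, 4, 7, 10) or self.study_start.day != 1:
            raise ValueError("study_start must be the first day of a calendar quarter")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")
        if self.lookback_start > self.study_start:
            raise ValueError("lookback_start must not be after study_start")

    @property
    def study_end(self) -> date:
        """Last day of the final quarter."""
        return self.quarter_end(self.n_quarters)

    def quarter_start(self, q: int) -> date:
        self._check_quarter(q)
        month0 = (self.study_start.month - 1) + 3 * (q - 1)
        return date(self.study_start.year + month0 // 12, month0 % 12 + 1, 1)

    def quarter_end(self, q: int) -> date:
        self._check_quarter(q)
        month0 = (self.study_start.month - 1) + 3 * q
        nxt = date(self.study_start.year + month0 // 12, month0 % 12 + 1, 1)
        return nxt - pd.Timedelta(days=1).to_pytimedelta()

    def quarter_of(self, dates) -> np.ndarray:
        """Quarter index for each date; 0 for dates outside the study window.

        Accepts anything convertible by :func:`pandas.to_datetime`.
        """
        d = pd.to_datetime(pd.Series(dates))
        start = pd.Timestamp(self.study_start)
        months = (d.dt.year - start.year) * 12 + (d.dt.month - start.month)
        q = months // 3 + 1
        out = q.where((q >= 1) & (q <= self.n_quarters), 0)
        return out.to_numpy(dtype=np.int64)

    def calendar_year(self, q: int) -> int:
        """Calendar year containing quarter ``q`` (used for linkage vintage)."""
        return self.quarter_start(q).year

    def _check_quarter(self, q: int) -> None:
        if not 1 <= q <= self.n_quarters:
            raise ValueError(f"quarter index {q} outside 1..{self.n_quarters}")


DEFAULT_CALENDAR = StudyCalendar()
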