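"""Calendar helpers for the quarterly study window.

Everything downstream works on integer quarter indices (0-based from the
first quarter of the window) and integer day offsets from the window start.
The default window is 2007Q1–2018Q4, i.e. 48 quarters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QuarterWindow:
    """A contiguous range of calendar quarters starting at Q1 of ``start_year``."""

    start_year: int = 2007
    n_quarters: int = 48

    def __post_init__(self) -> None:
        if self.n_quarters < 2:
            raise ValueError("window must span at least 2 quarters")

    @property
    def start_date(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_year, 1, 1)

    @property
    def end_date(self) -> pd.Timestamp:
        """Last calendar day of the final quarter (inclusive)."""
        y, q = divmod(self.n_quarters - 1, 4)[0], (self.n_quarters - 1) % 4
        return pd.Timestamp(self.start_year + y, 3 * q + 3, 1) + pd.offsets.MonthEnd(0)

    @property
    def n_days(self) -> int:
        return int((self.end_date - self.start_date).days) + 1

    @property
    def n_months(self) -> int:
        return 3 * self.n_quarters

    def quarter_of(self, dates) -> np.ndarray:
        """Quarter index of each date; may fall outside [0, n_quarters)."""
        d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
        return ((d.year - self.start_year) * 4 + (d.month - 1) // 3).to_numpy()

    def quarter_of_month(self, year, month) -> int:
        return (int(year) - self.start_year) * 4 + (int(month) - 1) // 3

    def month_index(self, year, month) -> int:
        return (int(year) - self.start_year) * 12 + int(month) - 1

    def day_index(self, dates) -> np.ndarray:
        """Day offset from window start (0 = first day of the window)."""
        d = np.asarray(dates, dtype="datetime64[D]")
        return (d - np.datetime64(self.start_date, "D")).astype(int)

    def quarter_of_day(self, day_idx) -> np.ndarray:
        """Quarter index for integer day offsets (vectorised)."""
        dates = np.datetime64(self.start_date, "D") + np.asarray(day_idx, dtype=int)
        return self.quarter_of(dates)

    def quarter_day_bounds(self) -> np.ndarray:
        """(n_quarters, 2) inclusive day-offset bounds of each quarter."""
        starts = [
            self.day_index(pd.Timestamp(self.start_year + q // 4, 3 * (q % 4) + 1, 1))
            for q in range(self.n_quarters)
        ]
        starts = np.array(starts).ravel()
        ends = np.r_[starts[1:] - 1, self.n_days - 1]
        return np.column_stack([starts, ends])

    def label(self, q: int) -> str:
        return f"{self.start_year + q // 4}Q{q % 4 + 1}"

    def month_label(self, m: int) -> str:
        return f"{self.start_year + m // 12}-{m % 12 + 1:02d}"
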