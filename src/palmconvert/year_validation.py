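"""Conversion-year detection from NBR time series and map-year agreement.

Clearing a closed-canopy stand drops the normalized burn ratio sharply and
persistently. The detector aggregates a site's multi-date NBR series to
annual means, scans consecutive-year drops, and attributes the conversion
to the first year at the lower level — provided the drop exceeds a
magnitude threshold and enough subsequent raw observations confirm the new
level. The agreement tabulation then compares detected (or visually
verified) years against the map's establishment years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default minimum annual-mean NBR decrease treated as a disturbance
DROP_THRESHOLD = 0.25
#: default number of confirming post-drop observations
PERSISTENCE = 2


def detect_conversion_year(series: pd.DataFrame,
                           drop_threshold: float = DROP_THRESHOLD,
                           persistence: int = PERSISTENCE) -> int | None:
    """Year of the largest qualifying NBR drop, or None.

    ``series`` has columns ``date`` (datetime-like) and ``nbr``. The series
    is averaged per calendar year; for each pair of successive observed
    years the drop in mean NBR is computed. A drop qualifies if it is at
    least ``drop_threshold`` NBR units and at least ``persistence`` raw
    observations from the drop year onward lie below the midpoint of the
    pre- and post-drop annual means. The largest qualifying drop wins and
    the post-drop year is returned. Fewer than 4 observations -> None
    (logged, never an exception).
    """
    if len(series) < 4:
        log.warning("NBR series too short (%d observations); no detection",
                    len(series))
        return None
    s = series.copy()
    s["date"] = pd.to_datetime(s["date"])
    if not s["date"].is_monotonic_increasing:
        s = s.sort_values("date")
    s["year"] = s["date"].dt.year
    annual = s.groupby("year")["nbr"].mean()
    if len(annual) < 2:
        return None
    years = annual.index.to_numpy()
    best_year, best_drop = None, 0.0
    for prev, cur in zip(years[:-1], years[1:]):
        drop = annual[prev] - annual[cur]
        if drop < drop_threshold:
            continue
        midpoint = (annual[prev] + annual[cur]) / 2.0
        confirming = int(((s["year"] >= cur) & (s["nbr"] < midpoint)).sum())
        if confirming < persistence:
            continue
        if drop > best_drop:
            best_year, best_drop = int(cur), float(drop)
    return best_year


@dataclass
class YearAgreement:
    """Contingency of |map year - reference year| over paired sites."""

    n: int
    n_exact: int
    n_off_by_one: int
    n_two_plus: int

    @property
    def pct_exact(self) -> float:
        return 100.0 * self.n_exact / self.n

    @property
    def pct_off_by_one(self) -> float:
        return 100.0 * self.n_off_by_one / self.n

    @property
    def pct_two_plus(self) -> float:
        return 100.0 * self.n_two_plus / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": ["exact", "off_by_one", "two_or_more"],
            "count": [self.n_exact, self.n_off_by_one, self.n_two_plus],
            "percent": [self.pct_exact, self.pct_off_by_one,
                        self.pct_two_plus],
        })


def year_agreement_table(map_years, reference_years) -> YearAgreement:
    """Tabulate exact / off-by-one / >=2-year differences between paired years."""
    map_years = np.asarray(map_years)
    reference_years = np.asarray(reference_years)
    if map_years.shape != reference_years.shape:
        raise ValueError("paired year lists differ in length")
    if map_years.size == 0:
        raise ValueError("no paired years supplied")
    diff = np.abs(map_years - reference_years)
    return YearAgreement(
        n=int(diff.size),
        n_exact=int((diff == 0).sum()),
        n_off_by_one=int((diff == 1).sum()),
        n_two_plus=int((diff >= 2).sum()))
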