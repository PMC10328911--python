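"""Season calendar shared by the simulator and the compositing stage.

The whole pipeline operates on a single April–November growing season,
addressed by day-of-year on a 365-day (no leap) calendar: Apr 1 = 91,
Nov 30 = 334.  Features are composited over four fixed two-month windows.
"""

from __future__ import annotations

SEASON_START_DOY = 91    # Apr 1
SEASON_END_DOY = 334     # Nov 30

#: The four two-month compositing windows (inclusive doy bounds).
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = (
    (91, 151),    # Apr 1 – May 31
    (152, 212),   # Jun 1 – Jul 31
    (213, 273),   # Aug 1 – Sep 30
    (274, 334),   # Oct 1 – Nov 30
)

PERIOD_NAMES = ("apr_may", "jun_jul", "aug_sep", "oct_nov")

BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
N_BANDS = len(BANDS)
N_PERIODS = len(DEFAULT_PERIODS)


def scene_dates(revisit_days: int) -> list[int]:
    """Acquisition days-of-year at a fixed revisit cadence across the season."""
    if revisit_days < 1:
        raise ValueError("revisit_days must be >= 1")
    return list(range(SEASON_START_DOY, SEASON_END_DOY + 1, revisit_days))
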