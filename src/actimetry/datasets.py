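"""Bundled reference data.

``EXAMPLE_WEEK`` is one week (9–15 May 2018) of hourly Activity Index
values recorded by a wrist-worn ±8 g accelerometer on a free-living
subject, arranged noon-to-noon (rows 12:00, 13:00, ..., 11:00; one column
per day).  It is the package's worked example for the Regularity Index:
running :func:`actimetry.regularity.ri_trend` over these columns yields
the day-to-day RI sequence 0.7078, 0.8386, 0.6484, 0.1430, 0.1105,
0.4395 for 10–15 May.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .activity_index import HourlyAIVector
from .raw_io import DayWindow

__all__ = ["EXAMPLE_WEEK", "EXAMPLE_WEEK_DATES", "load_example_week"]

EXAMPLE_WEEK_DATES = [dt.date(2018, 5, d) for d in range(9, 16)]

# rows: hours 12:00 ... 11:00 (noon-first); columns: 9 May ... 15 May 2018
EXAMPLE_WEEK = np.array([
    [91.6985, 7.9372, 52.1803, 39.1756, 16.1481, 120.7643, 7.4088],
    [68.0396, 155.7581, 104.2664, 20.2958, 190.7752, 68.5014, 59.4915],
    [60.9835, 132.4570, 209.2683, 47.8527, 165.0358, 24.0670, 79.0501],
    [127.9568, 97.1954, 152.4025, 63.6552, 72.7410, 17.4707, 110.0526],
    [50.0016, 37.5953, 5.2637, 20.1774, 34.5341, 125.6139, 55.4181],
    [52.6829, 63.8394, 5.0618, 40.1613, 60.5130, 50.6716, 35.2950],
    [58.4110, 44.1087, 15.8595, 39.5041, 35.8857, 16.3036, 43.0587],
    [30.3024, 11.9919, 23.8395, 20.0936, 34.3655, 24.9894, 19.2359],
    [32.9313, 44.0399, 19.5678, 19.0029, 49.1668, 21.5088, 42.3071],
    [25.9622, 20.2555, 32.2234, 16.1118, 45.0717, 18.5637, 26.7250],
    [13.7704, 16.6188, 12.7696, 9.2744, 26.0573, 9.6644, 16.1690],
    [8.8460, 11.4903, 13.3283, 9.6019, 16.6092, 8.3738, 10.8001],
    [9.1765, 8.0131, 11.8799, 9.2327, 12.3928, 7.2355, 7.0924],
    [11.7781, 13.9831, 9.7203, 7.5271, 18.6474, 12.4477, 7.9296],
    [7.1743, 25.7008, 6.9460, 10.2525, 9.9166, 7.7463, 15.6859],
    [6.9395, 16.4114, 8.0269, 7.3836, 13.6776, 7.3144, 8.6616],
    [6.9992, 18.5755, 10.9319, 6.9433, 13.1182, 7.3127, 11.0475],
    [6.6685, 66.1852, 33.5049, 10.2133, 87.0340, 81.8432, 69.0056],
    [51.9434, 60.5493, 53.4563, 45.3398, 28.0925, 201.7091, 43.4253],
    [60.3498, 146.4305, 152.9999, 199.2066, 72.4182, 161.1731, 138.3872],
    [146.0198, 185.8036, 184.6546, 132.9641, 95.0854, 98.3405, 239.4251],
    [109.5714, 126.9927, 105.3715, 178.1697, 16.5196, 96.5270, 150.3620],
    [50.1309, 97.9686, 48.7204, 84.0562, 42.8646, 131.4003, 77.6424],
    [53.7380, 95.5183, 34.1327, 74.0714, 37.0004, 53.0020, 78.3121],
])


def load_example_week() -> list[HourlyAIVector]:
    """The example week as chronologically ordered :class:`HourlyAIVector`\\ s."""
    out = []
    for j, date in enumerate(EXAMPLE_WEEK_DATES):
        start = pd.Timestamp.combine(date, dt.time(12, 0))
        win = DayWindow(day_label=date, start=start, end=start + pd.Timedelta(hours=24))
        out.append(HourlyAIVector(day=win, values=EXAMPLE_WEEK[:, j]))
    return out
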