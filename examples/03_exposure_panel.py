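"""Build previous-1-year exposure averages and a centered monthly panel.

For every month start, the exposure value is the mean of daily PM2.5 over
the 365 days ending the day before; months with under half the window
observed are dropped, which is why sites end up with varying record counts.
"""

import numpy as np
import pandas as pd

from bhpm.panel import center_within_location, previous_year_average

rng = np.random.default_rng(3)
days = pd.date_range("2000-01-01", "2003-12-31", freq="D")
daily = pd.Series(
    13.0 + 4 * np.sin(2 * np.pi * days.dayofyear / 365) + rng.normal(0, 4, len(days)),
    index=days,
)
daily = daily[rng.uniform(size=len(daily)) > 0.15]  # 15% missing days

starts = pd.date_range("2001-01-01", "2003-12-01", freq="MS")
monthly = previous_year_average(daily, starts, min_coverage=0.5)
print(f"{len(monthly)} of {len(starts)} month starts have enough daily coverage")
for month, x in monthly[:3]:
    print(f"  {month.date()}  previous-year average = {x:.2f} ug/m3")

panel = pd.DataFrame(
    {
        "location_id": "site01",
        "month_index": range(1, len(monthly) + 1),
        "deaths": rng.poisson(60, len(monthly)),
        "at_risk": 14500,
        "exposure": [x for _, x in monthly],
    }
)
panel, means = center_within_location(panel)
print(f"site mean exposure x-bar = {means['site01']:.2f} ug/m3; "
      f"centered exposures span {panel.exposure_centered.min():+.2f} to "
      f"{panel.exposure_centered.max():+.2f}")
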