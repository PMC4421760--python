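"""Generate a synthetic multi-site mortality study and summarize it.

The generator mirrors an eastern-US Medicare monitoring panel: each site
has 33-70 monthly records of deaths, population at risk and previous-year
PM2.5, plus 7-year-average constituent fields and community covariates.
"""

import numpy as np

import bhpm

truth = bhpm.SimulationTruth(n_locations=241, seed=7)
study = bhpm.simulate_study(truth)

panel = study.panel
per_site = panel.groupby("location_id").agg(
    months=("month_index", "size"),
    deaths=("deaths", "mean"),
    at_risk=("at_risk", "mean"),
    pm25=("exposure", "mean"),
)
print(f"{len(per_site)} monitoring locations, "
      f"{per_site.months.min()}-{per_site.months.max()} monthly records each")
print(f"population at risk   {per_site.at_risk.mean():9.0f} +- {per_site.at_risk.std():.0f} per month")
print(f"mortality count      {per_site.deaths.mean():9.1f} +- {per_site.deaths.std():.1f} per month")
print(f"previous-year PM2.5  {per_site.pm25.mean():9.2f} +- {per_site.pm25.std():.2f} ug/m3")
z = np.array([p.constituents for p in study.profiles])
for k, name in enumerate(bhpm.CONSTITUENTS):
    print(f"  {name:<4s} 7-yr average   {z[:, k].mean():6.2f} +- {z[:, k].std():.2f} ug/m3")

# the truth behind the draw: site mortality rates and exposure slopes
rate = 1000 * np.exp(study.alpha0)
slope_pct = 100 * (np.exp(study.alpha1) - 1)
print(f"true baseline rates: {rate.min():.2f}-{rate.max():.2f} deaths/month/1,000")
print(f"true PM2.5 slopes:   {slope_pct.min():.2f} to {slope_pct.max():.2f} % per ug/m3")
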