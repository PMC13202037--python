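"""Age-sex standardised stroke incidence, annual and monthly.

Rates are standardised to the adult European Standard Population by the
direct method with gamma confidence intervals; denominators are the
stroke-free person-time of the registered synthetic population.  The
monthly series is also plotted.
"""

import os

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from _common import CONFIG, RESULTS, get_results, save

from stroketrace import incidence_series

res = get_results()

annual = incidence_series(res["tables"], res["index_strokes"], CONFIG, freq="YS")
save(annual, "incidence_annual.csv")
print("\nannual standardised incidence per 100 000 person-years:")
for row in annual.itertuples():
    print(f"  {row.period}: {row.rate:.1f} ({row.ci_low:.1f}, {row.ci_high:.1f})"
          f"  crude {row.crude_rate:.1f}, events {row.events:.0f}")

monthly = incidence_series(res["tables"], res["index_strokes"], CONFIG, freq="MS")
save(monthly, "incidence_monthly.csv")

fig, ax = plt.subplots(figsize=(9, 4))
ax.plot(monthly["period"], monthly["rate"], marker="o", ms=3, lw=1)
ax.fill_between(monthly["period"], monthly["ci_low"], monthly["ci_high"], alpha=0.25)
ax.set_ylabel("standardised rate per 100 000 py")
ax.set_xlabel("month")
ax.set_xticks(monthly["period"][::6])
ax.tick_params(axis="x", rotation=45)
fig.tight_layout()
fig.savefig(os.path.join(RESULTS, "incidence_monthly.png"), dpi=120)
print("wrote results/incidence_monthly.png")
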