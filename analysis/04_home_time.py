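"""180-day home-time after non-fatal stroke: crude and adjusted means.

Home-time (days alive and out of hospital in the 180 days from stroke
onset) is summarised by age band, deprivation quintile and calendar year,
crude and adjusted with an ordinary linear model (g-computation marginal
means), restricted to non-fatal strokes captured in a living source.
"""

import pandas as pd

from _common import get_results, save

from stroketrace import mean_home_time

res = get_results()
strokes = res["index_strokes"]
nonfatal = strokes[~strokes["fatal"] & (strokes["sources"] != "ons")]

df = (res["outcomes"].merge(nonfatal[["person_id", "index_date"]], on="person_id")
      .merge(res["covariates"], on="person_id"))
df["year"] = pd.to_datetime(df["index_date"]).dt.year.astype(str)

print(f"\nnon-fatal strokes analysed: {len(df)}")
print(f"overall mean home-time: {df['home_days'].mean():.1f} days "
      f"(hospital {df['hospital_days'].mean():.1f}, dead {df['dead_days'].mean():.1f})")

frames = []
for stratum, adjust in [("age_band", ["sex", "charlson_category", "year"]),
                        ("imd_quintile", ["age_band", "sex", "charlson_category"]),
                        ("year", ["age_band", "sex", "charlson_category"])]:
    out = mean_home_time(df, stratum, adjust_for=adjust)
    out.insert(0, "stratum", stratum)
    out = out.rename(columns={stratum: "level"})
    frames.append(out)
    print(f"\nmean home-time by {stratum} (crude -> adjusted):")
    for row in out.itertuples():
        print(f"  {str(row.level):12s} n={row.n:5d}  {row.crude_mean:6.1f} "
              f"({row.ci_low:.1f}, {row.ci_high:.1f}) -> {row.adjusted_mean:6.1f}")

save(pd.concat(frames, ignore_index=True), "home_time_means.csv")
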