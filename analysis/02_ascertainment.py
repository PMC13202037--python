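"""Multi-source ascertainment: coverage, source overlap and date agreement.

Reports how many index strokes each source captures, the most frequent
exact source intersections (UpSet-style counts, stratified by fatality),
and the median inter-source difference in recorded onset dates.
"""

from _common import get_results, save

from stroketrace import coverage_table, date_discrepancy, source_intersections

res = get_results()
strokes = res["index_strokes"]

cov = coverage_table(strokes)
save(cov, "coverage.csv")
print(f"\nindex strokes ascertained: {len(strokes)}")
for row in cov.itertuples():
    print(f"  {row.source:8s} {row.count:6d} ({row.pct}%)  "
          f"ischaemic {row.pct_ischaemic}%  haemorrhagic {row.pct_haemorrhagic}%  "
          f"unknown {row.pct_unknown}%")

strokes = strokes.assign(fatality=strokes["fatal"].map({True: "fatal", False: "nonfatal"}))
inter = source_intersections(strokes, top_k=15, by=["fatality"])
save(inter, "source_intersections.csv")
fatal_total = (strokes["fatality"] == "fatal").sum()
only_ons = inter.query("fatality == 'fatal' and source_subset == 'ons'")["count"].sum()
print(f"\nfatal strokes seen only in death records: "
      f"{only_ons} of {fatal_total} ({100 * only_ons / fatal_total:.1f}%)")

disc = date_discrepancy(res["merged_records"])
save(disc, "date_discrepancy.csv")
print("\ninter-source onset-date differences (days):")
for row in disc.itertuples():
    print(f"  {row.source_a} vs {row.source_b}: median {row.median_days:.0f} "
          f"(IQR {row.iqr_low:.0f}-{row.iqr_high:.0f}), n={row.n}")
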