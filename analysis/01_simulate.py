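"""Generate the synthetic linked-EHR cohort and summarise what it contains.

Prints the cohort size, true stroke count, subtype mix and per-source
capture fractions against their configured values, and writes a one-row
summary table.
"""

import pandas as pd

from _common import CONFIG, get_results, save

res = get_results()
gt = res["ground_truth"]
ev = gt[gt["has_stroke"]]

print(f"persons simulated:      {CONFIG.n_persons}")
print(f"true first strokes:     {len(ev)} "
      f"({100 * len(ev) / CONFIG.n_persons:.2f}% over 4 years)")
print(f"fatal within 30 days:   {ev['fatal'].mean() * 100:.1f}%")
print("subtype mix (true):     "
      + ", ".join(f"{k} {v * 100:.1f}%" for k, v in
                  ev["subtype"].value_counts(normalize=True).items()))

rows = []
for src in ("gdppr", "hes_apc", "ssnap", "ons"):
    for status, sel in [("nonfatal", ~ev["fatal"]), ("fatal", ev["fatal"])]:
        observed = ev.loc[sel, f"cap_{src}"].mean()
        configured = CONFIG.capture_prob[(src, status)]
        rows.append({"source": src, "status": status,
                     "configured": configured, "observed": round(observed, 4)})
        print(f"capture {src:8s} {status:8s}: observed {observed:.3f} "
              f"(configured {configured:.2f})")
caps = pd.DataFrame(rows)
save(caps, "simulation_capture_check.csv")

summary = pd.DataFrame([{
    "n_persons": CONFIG.n_persons, "seed": CONFIG.seed,
    "true_strokes": len(ev), "fatal_pct": round(ev["fatal"].mean() * 100, 1),
    "hospitalised_pct": round(ev["hospitalised"].mean() * 100, 1),
}])
save(summary, "simulation_summary.csv")
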