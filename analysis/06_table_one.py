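"""Table-1-style cohort description, stratified by source membership.

Categorical covariates as n (%) and continuous measurements as median
(IQR), with explicit missing rows, for each source column and the union
cohort.  Disclosure rounding (multiples of 5) is off for synthetic data.
"""

from _common import get_results, save

from stroketrace import table_one

res = get_results()
covs = res["covariates"].merge(
    res["index_strokes"][["person_id", "stroke_type", "fatal"]], on="person_id")

t1 = table_one(
    covs, res["index_strokes"],
    categorical=["stroke_type", "sex", "age_band", "ethnicity", "imd_quintile",
                 "charlson_category", "hypertension", "diabetes", "af_mi"],
    continuous=["bmi", "sbp", "egfr", "total_cholesterol"],
)
save(t1, "table_one.csv")
print(t1.head(25).to_string(index=False))
print(f"... {len(t1)} rows total")
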