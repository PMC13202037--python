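"""Descriptive reporting: source overlap, coverage, date discrepancies,
Table-1-style summaries and disclosure-control rounding.

Fixed numeric conventions so printed values are exactly reproducible:
percentages round half-up to 1 decimal place; quantiles use linear
interpolation; disclosure rounding (off by default) rounds counts half to
even multiples of 5, the usual secure-data-environment output rule.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

SOURCES = ("gdppr", "hes_apc", "ssnap", "ons")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (71.45 -> 71.5), avoiding float banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """count/total as a percentage, rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        raise ValueError("percentage of an empty denominator")
    return round_half_up(100.0 * count / total, ndigits)


def disclosure_round(count: int, base: int = 5) -> int:
    """Round a count half-to-even to a multiple of ``base`` (303 -> 305)."""
    if count < 0:
        raise ValueError("counts cannot be negative")
    return int(base * np.rint(count / base))


# ----------------------------------------------------------------------


def source_intersections(index_strokes: pd.DataFrame, top_k: int = 15,
                         by: list | None = None) -> pd.DataFrame:
    """Exact source-subset counts (UpSet-style), optionally stratified.

    Each person contributes to exactly one subset — their exact source set
    — so counts partition the cohort.  Within each stratum the ``top_k``
    most frequent subsets are kept and the remainder pooled as "other".
    """
    df = index_strokes.copy()
    df["source_subset"] = df["sources"].map(
        lambda s: "|".join(sorted(s.split("|"))) if isinstance(s, str) else "|".join(sorted(s)))
    group_cols = (by or []) + ["source_subset"]
    counts = df.groupby(group_cols, observed=True).size().rename("count").reset_index()

    if by:
        frames = []
        for keys, grp in counts.groupby(by, observed=True):
            frames.append(_truncate_topk(grp, top_k, group_cols))
        out = pd.concat(frames, ignore_index=True)
    else:
        out = _truncate_topk(counts, top_k, group_cols)
    return out.reset_index(drop=True)


def _truncate_topk(grp: pd.DataFrame, top_k: int, group_cols) -> pd.DataFrame:
    grp = grp.sort_values(["count", "source_subset"], ascending=[False, True])
    head = grp.head(top_k)
    tail = grp.iloc[top_k:]
    if len(tail):
        pooled = head.iloc[:1].copy()
        pooled["source_subset"] = "other"
        pooled["count"] = tail["count"].sum()
        head = pd.concat([head, pooled], ignore_index=True)
    return head


def coverage_table(index_strokes: pd.DataFrame) -> pd.DataFrame:
    """Per-source membership counts, % of cohort, and subtype % by source.

    A person recorded in two sources counts once in each source column;
    subtype percentages use the source's own count as denominator.
    """
    total = len(index_strokes)
    if total == 0:
        raise ValueError("empty cohort")
    member = {src: index_strokes["sources"].str.contains(src, regex=False)
              for src in SOURCES}
    rows = []
    for src in SOURCES:
        m = index_strokes[member[src]]
        row = {"source": src, "count": len(m), "pct": percentage(len(m), total)}
        for st in ("ischaemic", "haemorrhagic", "unknown"):
            k = int((m["stroke_type"] == st).sum())
            row[f"n_{st}"] = k
            row[f"pct_{st}"] = percentage(k, len(m)) if len(m) else np.nan
        rows.append(row)
    row = {"source": "all", "count": total, "pct": 100.0}
    for st in ("ischaemic", "haemorrhagic", "unknown"):
        k = int((index_strokes["stroke_type"] == st).sum())
        row[f"n_{st}"] = k
        row[f"pct_{st}"] = percentage(k, total)
    rows.append(row)
    return pd.DataFrame(rows)


def date_discrepancy(merged_records: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of |date difference| between source pairs.

    For each event the earliest recorded date within each source is
    compared; pairs that never co-occur are absent from the output.
    Quantiles use linear interpolation.
    """
    rec = merged_records.copy()
    rec["event_date"] = pd.to_datetime(rec["event_date"])
    earliest = (rec.groupby(["person_id", "source"])["event_date"].min()
                .unstack("source"))
    rows = []
    for i, a in enumerate(SOURCES):
        for b in SOURCES[i + 1:]:
            if a not in earliest.columns or b not in earliest.columns:
                continue
            both = earliest[[a, b]].dropna()
            if both.empty:
                continue
            diff = (both[a] - both[b]).dt.days.abs().to_numpy()
            q25, q50, q75 = np.percentile(diff, [25, 50, 75])
            rows.append({"source_a": a, "source_b": b, "n": len(diff),
                         "median_days": q50, "iqr_low": q25, "iqr_high": q75})
    return pd.DataFrame(rows, columns=["source_a", "source_b", "n",
                                       "median_days", "iqr_low", "iqr_high"])


def table_one(covariates: pd.DataFrame, index_strokes: pd.DataFrame,
              categorical: list, continuous: list,
              disclosure: bool = False) -> pd.DataFrame:
    """Table-1-style summary stratified by source membership plus the union.

    Categorical rows are n (%); continuous rows are median (IQR) with an
    explicit "(missing)" count.  A person in two sources appears in both
    source columns.  With ``disclosure`` on, counts are rounded to
    multiples of 5 before percentages are computed.
    """
    df = covariates.merge(index_strokes[["person_id", "sources"]], on="person_id")
    columns = {src: df[df["sources"].str.contains(src, regex=False)] for src in SOURCES}
    columns["all"] = df

    def fmt_count(k, n):
        if disclosure:
            k, n = disclosure_round(k), disclosure_round(n)
        pct = percentage(k, n) if n else np.nan
        return f"{k} ({pct})"

    rows = []
    for var in categorical:
        levels = sorted(df[var].astype(str).fillna("(missing)").unique())
        for level in levels:
            row = {"variable": var, "level": level}
            for name, sub in columns.items():
                k = int((sub[var].astype(str) == level).sum())
                row[name] = fmt_count(k, len(sub))
            rows.append(row)
    for var in continuous:
        row = {"variable": var, "level": "median (IQR)"}
        miss_row = {"variable": var, "level": "(missing)"}
        for name, sub in columns.items():
            vals = pd.to_numeric(sub[var], errors="coerce").dropna()
            if len(vals):
                q25, q50, q75 = np.percentile(vals, [25, 50, 75])
                row[name] = f"{q50:.1f} ({q25:.1f}-{q75:.1f})"
            else:
                row[name] = ""
            miss_row[name] = fmt_count(int(sub[var].isna().sum()), len(sub))
        rows.append(row)
        rows.append(miss_row)
    return pd.DataFrame(rows)
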