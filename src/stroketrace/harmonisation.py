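"""Stroke subtype harmonisation across sources.

Raw codes (ICD-10, SNOMED CT, stroke-audit S2 field) are mapped to one of
three phenotypes — ischaemic, haemorrhagic, unknown — and a single subtype
per index event is resolved with a fixed source priority: the stroke audit
(SSNAP) is trusted over hospital admissions (HES-APC), over primary care
(GDPPR), over the death registration (ONS).  If the highest-priority source
present carries both ischaemic and haemorrhagic records, the harmonised
subtype is "unknown".
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: higher value = higher priority when consolidating subtype
SOURCE_PRIORITY = {"ssnap": 3, "hes_apc": 2, "gdppr": 1, "ons": 0}

VALID_SUBTYPES = ("ischaemic", "haemorrhagic", "unknown")


@dataclass(frozen=True)
class CodeList:
    """Mapping from raw clinical codes to stroke subtypes, per coding system.

    ICD-10 codes are matched by prefix (I639 matches the I63 entry); SNOMED
    and SSNAP S2 values are matched exactly.
    """

    entries: dict  # (coding_system, code) -> subtype

    def __post_init__(self):
        for (system, code), subtype in self.entries.items():
            if subtype not in VALID_SUBTYPES:
                raise ValueError(f"codelist maps {system}:{code} to invalid subtype {subtype!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodeList":
        entries = {(r.coding_system, str(r.code)): r.subtype for r in frame.itertuples()}
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "CodeList":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    @classmethod
    def default(cls) -> "CodeList":
        """The shipped toy codelist (I63/I61/I64 plus SNOMED and S2 entries)."""
        ref = importlib.resources.files("stroketrace.data") / "codelist_stroke.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def systems(self) -> set[str]:
        return {system for system, _ in self.entries}


def map_code(code: str, coding_system: str, codelist: CodeList) -> str | None:
    """Map one raw code to a subtype, or None for a non-stroke code.

    ICD-10 uses longest-prefix matching so that 4-character codes inherit
    their 3-character parent's subtype; other systems match exactly.
    """
    if coding_system not in ("icd10", "snomed", "ssnap_s2"):
        raise ValueError(f"unknown coding system: {coding_system!r}")
    code = str(code).strip()
    if coding_system == "icd10":
        best = None
        for (system, entry), subtype in codelist.entries.items():
            if system == "icd10" and code.startswith(entry):
                if best is None or len(entry) > len(best[0]):
                    best = (entry, subtype)
        return best[1] if best else None
    return codelist.entries.get((coding_system, code))


def resolve_type(records: Sequence) -> str:
    """Resolve one harmonised subtype from the merged records of an event.

    ``records`` is a sequence of objects (or 2-tuples) carrying ``source``
    and ``subtype``.  The highest-priority source present decides; within
    that source, a mix of ischaemic and haemorrhagic resolves to unknown,
    a single specific type wins (ignoring co-occurring "unknown" records),
    and only-unknown stays unknown.
    """
    pairs = []
    for rec in records:
        if isinstance(rec, tuple):
            source, subtype = rec
        else:
            source, subtype = rec.source, rec.subtype
        pairs.append((source, subtype))
    if not pairs:
        raise ValueError("cannot resolve subtype of an empty record set")
    top = max(SOURCE_PRIORITY[s] for s, _ in pairs)
    subtypes = {st for s, st in pairs if SOURCE_PRIORITY[s] == top}
    has_isch = "ischaemic" in subtypes
    has_haem = "haemorrhagic" in subtypes
    if has_isch and has_haem:
        return "unknown"
    if has_isch:
        return "ischaemic"
    if has_haem:
        return "haemorrhagic"
    return "unknown"


def resolve_types_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`resolve_type` over a record table.

    ``records`` needs columns person_id, source, subtype; returns a Series
    of harmonised subtype indexed by person_id.
    """
    df = records[["person_id", "source", "subtype"]].copy()
    df["prio"] = df["source"].map(SOURCE_PRIORITY)
    top = df.groupby("person_id")["prio"].transform("max")
    df = df[df["prio"] == top]
    flags = df.assign(
        isch=df["subtype"].eq("ischaemic"),
        haem=df["subtype"].eq("haemorrhagic"),
    ).groupby("person_id")[["isch", "haem"]].any()
    out = pd.Series("unknown", index=flags.index, name="stroke_type")
    out[flags["isch"] & ~flags["haem"]] = "ischaemic"
    out[flags["haem"] & ~flags["isch"]] = "haemorrhagic"
    return out
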