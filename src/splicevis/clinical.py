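"""Harmonization of raw TCGA-style clinical fields.

Raw per-sample attributes (free-text stage strings, pack-years, follow-up
days, ...) are mapped to small categorical vocabularies suitable for grouping,
and an overall-survival (time, event) pair is derived from ``day_to_death``
and ``days_to_last_follow-up``.  Unknown or indeterminate inputs land in the
literal category ``"UNDEFINED"`` rather than raising; rules are shipped as
data (a versioned JSON file) so per-tumor variable lists can be swapped
without code changes.

Transformation rules implemented:

1. pack-years smoked -> "less than 10" / "less than 100" / "greater than 100"
   (cutoffs 10 and 100; half-open bins, boundary to the upper bin)
2. overall survival: event = 1 iff a non-zero day_to_death exists, else
   censored (0); time = max of the present day values
3. tumor stage (pathology/clinical/masaoka) -> I / II / III / IV / X
4. liver-cancer risk factors: alpha-1 antitrypsin deficiency, hemochromatosis
   and "other" merged into "others"; alcohol consumption and hepatitis B/C
   kept as themselves
5. alcohol per day -> "0" / ">0"
6. number of pregnancies -> "1".."5" / ">5"
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

UNDEFINED = "UNDEFINED"

_INDETERMINATE = "indeterminate"

_STAGE_ROOTS = {"i": "I", "ii": "II", "iii": "III", "iv": "IV", "x": "X"}

_LIHC_MERGE_TO_OTHERS = {
    "alpha-1 antitrypsin deficiency",
    "hemochromatosis",
    "other",
}
_LIHC_KEEP = {
    "alcohol consumption": "Alcohol consumption",
    "hepatitis b": "hepatitis b",
    "hepatitis c": "hepatitis c",
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _as_number(value):
    """Numeric coercion; None for missing or unparseable."""
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def bin_pack_years(value) -> str:
    """Pack-years smoked into three half-open bins split at 10 and 100."""
    v = _as_number(value)
    if v is None:
        return UNDEFINED
    if v < 0:
        raise ValueError(f"pack-years cannot be negative: {value!r}")
    if v < 10:
        return "less than 10"
    if v < 100:
        return "less than 100"
    return "greater than 100"


def derive_survival(day_to_death, days_to_last_follow_up):
    """Overall-survival (time, event) from the two raw day counters.

    The event is death (1) only when a defined, non-zero day_to_death exists;
    otherwise the record is censored (0) provided any time information is
    present.  Time is the larger of the present values.  Both missing gives
    (None, None).
    """
    d = _as_number(day_to_death)
    f = _as_number(days_to_last_follow_up)
    if d is not None and d < 0:
        raise ValueError(f"negative day_to_death: {day_to_death!r}")
    if f is not None and f < 0:
        raise ValueError(f"negative days_to_last_follow-up: {days_to_last_follow_up!r}")
    if d is None and f is None:
        return None, None
    time = max(v for v in (d, f) if v is not None)
    event = 1 if (d is not None and d != 0) else 0
    return time, event


def collapse_stage(raw_stage) -> str:
    """Collapse substaged stage strings to the 5-class set I/II/III/IV/X.

    Case-insensitive; strips a "Stage " prefix and a single trailing substage
    letter (A/B/C).  Indeterminate or unrecognized values become UNDEFINED.
    """
    if _is_missing(raw_stage):
        return UNDEFINED
    s = str(raw_stage).strip().lower()
    if s == _INDETERMINATE:
        return UNDEFINED
    if s.startswith("stage "):
        s = s[len("stage "):].strip()
    if len(s) > 1 and s[-1] in ("a", "b", "c"):
        s = s[:-1]
    return _STAGE_ROOTS.get(s, UNDEFINED)


def merge_lihc_risk(raw) -> str:
    """Liver-cancer risk-factor merge; rare aetiologies pooled as "others"."""
    if _is_missing(raw):
        return UNDEFINED
    s = str(raw).strip().lower()
    if s == _INDETERMINATE:
        return UNDEFINED
    if s in _LIHC_MERGE_TO_OTHERS:
        return "others"
    if s in _LIHC_KEEP:
        return _LIHC_KEEP[s]
    return UNDEFINED


def bin_alcohol(value) -> str:
    """Alcohol consumption per day: zero vs any."""
    v = _as_number(value)
    if v is None or v < 0:
        return UNDEFINED
    return "0" if v == 0 else ">0"


def bin_pregnancies(value) -> str:
    """Number of pregnancies into classes 1..5 and >5; 0 is outside the
    declared vocabulary and maps to UNDEFINED."""
    v = _as_number(value)
    if v is None or v < 1 or v != int(v):
        return UNDEFINED
    v = int(v)
    return str(v) if v <= 5 else ">5"


def passthrough(value) -> str:
    if _is_missing(value):
        return UNDEFINED
    s = str(value).strip()
    if s.lower() == _INDETERMINATE:
        return UNDEFINED
    return s


def numeric_binned(value, cutoffs, labels) -> str:
    """Generic half-open numeric binning: [−inf,c1), [c1,c2), ..., [ck,inf)."""
    if len(labels) != len(cutoffs) + 1:
        raise ValueError("need one more label than cutoffs")
    if list(cutoffs) != sorted(set(cutoffs)):
        raise ValueError("cutoffs must be strictly increasing")
    v = _as_number(value)
    if v is None:
        return UNDEFINED
    for c, lab in zip(cutoffs, labels):
        if v < c:
            return lab
    return labels[-1]


def merge_map(value, mapping, default=UNDEFINED) -> str:
    """Case-insensitive total mapping with a default for unlisted inputs."""
    if _is_missing(value):
        return UNDEFINED
    s = str(value).strip()
    if s.lower() == _INDETERMINATE:
        return UNDEFINED
    lowered = {k.lower(): v for k, v in mapping.items()}
    return lowered.get(s.lower(), default)


@dataclass
class VariableRule:
    """One harmonization rule: output variable name, kind, and parameters.

    Kinds: the generic ``passthrough`` / ``numeric-binned`` / ``merge-map`` /
    ``survival`` plus the dedicated ``pack-years`` / ``stage`` / ``lihc-risk``
    / ``alcohol`` / ``pregnancies`` transformations whose semantics are not
    expressible as plain bins or maps.
    """

    name: str
    kind: str
    source: str | list[str] | None = None
    parameters: dict = field(default_factory=dict)

    _KINDS = (
        "passthrough",
        "numeric-binned",
        "merge-map",
        "survival",
        "pack-years",
        "stage",
        "lihc-risk",
        "alcohol",
        "pregnancies",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "numeric-binned":
            cutoffs = self.parameters.get("cutoffs", [])
            if list(cutoffs) != sorted(set(cutoffs)):
                raise ValueError(f"rule {self.name}: cutoffs must be strictly increasing")

    def apply(self, record: dict):
        """Apply to one raw record (mapping field -> value)."""
        if self.kind == "survival":
            fields = self.source or ["day_to_death", "days_to_last_follow-up"]
            return derive_survival(record.get(fields[0]), record.get(fields[1]))
        value = record.get(self.source) if isinstance(self.source, str) else None
        if self.kind == "passthrough":
            return passthrough(value)
        if self.kind == "numeric-binned":
            return numeric_binned(
                value, self.parameters["cutoffs"], self.parameters["labels"]
            )
        if self.kind == "merge-map":
            return merge_map(
                value,
                self.parameters["mapping"],
                self.parameters.get("default", UNDEFINED),
            )
        if self.kind == "pack-years":
            return bin_pack_years(value)
        if self.kind == "stage":
            return collapse_stage(value)
        if self.kind == "lihc-risk":
            return merge_lihc_risk(value)
        if self.kind == "alcohol":
            return bin_alcohol(value)
        if self.kind == "pregnancies":
            return bin_pregnancies(value)
        raise AssertionError(self.kind)


def load_rules(path=None) -> list[VariableRule]:
    """Load rules from a JSON file; default to the packaged rule set."""
    if path is None:
        text = (
            resources.files("splicevis").joinpath("rules/default_rules.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    rules = [
        VariableRule(
            name=r["name"],
            kind=r["kind"],
            source=r.get("source"),
            parameters=r.get("parameters", {}),
        )
        for r in raw
    ]
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("rule names must be unique")
    return rules


@dataclass
class HarmonizedRecord:
    sample_id: str
    categories: dict[str, str]
    survival_time: float | None = None
    survival_event: int | None = None


def harmonize(
    records: list[dict] | pd.DataFrame,
    rules: list[VariableRule],
) -> tuple[list[HarmonizedRecord], dict]:
    """Apply every rule to every record; returns records plus a report.

    ``records`` is a list of dicts (must include "sample_id") or a DataFrame
    with a sample_id column.  A rule whose source field is absent from the
    table yields UNDEFINED everywhere, with a warning.  The report carries
    per-variable category counts and UNDEFINED tallies.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict(orient="records")
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("rule names must be unique")

    if records:
        present = set().union(*(set(r) for r in records))
        for rule in rules:
            srcs = (
                rule.source
                if isinstance(rule.source, list)
                else [rule.source]
                if rule.source
                else []
            )
            missing = [s for s in srcs if s not in present]
            if missing:
                warnings.warn(
                    f"rule {rule.name!r}: raw field(s) {missing} absent; "
                    f"all records will be UNDEFINED",
                    stacklevel=2,
                )

    out: list[HarmonizedRecord] = []
    counts: dict[str, dict[str, int]] = {r.name: {} for r in rules if r.kind != "survival"}
    survival_stats = {"n_with_time": 0, "n_events": 0}
    for rec in records:
        sid = str(rec.get("sample_id", ""))
        if not sid:
            raise ValueError("every record needs a non-empty sample_id")
        cats: dict[str, str] = {}
        time = event = None
        for rule in rules:
            if rule.kind == "survival":
                time, event = rule.apply(rec)
                if time is not None:
                    survival_stats["n_with_time"] += 1
                if event == 1:
                    survival_stats["n_events"] += 1
            else:
                label = rule.apply(rec)
                cats[rule.name] = label
                counts[rule.name][label] = counts[rule.name].get(label, 0) + 1
        out.append(
            HarmonizedRecord(
                sample_id=sid,
                categories=cats,
                survival_time=time,
                survival_event=event,
            )
        )

    report = {
        "n_records": len(out),
        "variables": {
            name: {
                "categories": dict(sorted(c.items())),
                "n_undefined": c.get(UNDEFINED, 0),
            }
            for name, c in counts.items()
        },
        "survival": survival_stats,
    }
    return out, report


def harmonized_to_frame(records: list[HarmonizedRecord]) -> pd.DataFrame:
    """Tabular view: one row per sample, category columns + survival pair."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, **r.categories}
        row["survival_time"] = r.survival_time
        row["survival_event"] = r.survival_event
        rows.append(row)
    return pd.DataFrame(rows)


def read_clinical_tsv(path) -> pd.DataFrame:
    """Raw clinical table: one row per sample, empty cell = missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    if "sample_id" not in df.columns:
        raise ValueError("clinical TSV must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    return df
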