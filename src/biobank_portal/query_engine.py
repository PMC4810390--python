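"""Boolean panel queries over the star-schema store.

A query is an ordered list of *panels*; the terms inside one panel are
combined by OR, and the panels themselves are combined by AND — the
standard i2b2 Query Tool semantics. Each panel may also carry a closed
date window and a minimum occurrence count. Occurrences are counted per
panel across all its expanded terms combined, so a patient with one fact
of term A and one of term B satisfies "at least 2 occurrences" of the
panel {A, B}.

Panel terms are either ontology display paths (expanded to their
concept-code sets) or raw namespaced concept codes. Date windows are
evaluated on true (unshifted) dates; de-identification applies only on
export.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from biobank_portal import deidentify
from biobank_portal.datastore import SAMPLE_TYPES, Store, expand_term, is_concept_code

logger = logging.getLogger(__name__)

REQUESTABLE_ITEMS = frozenset(SAMPLE_TYPES | {"genotype-data"})


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class Panel:
    """One OR-group of terms with an optional date window and count."""

    terms: tuple[str, ...]
    date_from: dt.date | None = None
    date_to: dt.date | None = None
    min_occurs: int = 1

    def __post_init__(self):
        if not self.terms:
            raise QueryError("panel must contain at least one term")
        if self.min_occurs < 1:
            raise QueryError("min_occurs must be >= 1")


@dataclass(frozen=True)
class QueryDefinition:
    """An AND of panels; serializes to/from a small JSON document."""

    panels: tuple[Panel, ...]

    def __post_init__(self):
        if not self.panels:
            raise QueryError("query must contain at least one panel")

    def to_json(self) -> str:
        return json.dumps(
            {
                "panels": [
                    {
                        "terms": list(p.terms),
                        "from": p.date_from.isoformat() if p.date_from else None,
                        "to": p.date_to.isoformat() if p.date_to else None,
                        "min_occurs": p.min_occurs,
                    }
                    for p in self.panels
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QueryDefinition":
        doc = json.loads(text)
        panels = []
        for p in doc["panels"]:
            panels.append(
                Panel(
                    terms=tuple(p["terms"]),
                    date_from=dt.date.fromisoformat(p["from"]) if p.get("from") else None,
                    date_to=dt.date.fromisoformat(p["to"]) if p.get("to") else None,
                    min_occurs=int(p.get("min_occurs", 1)),
                )
            )
        return cls(panels=tuple(panels))


@dataclass(frozen=True)
class PatientSet:
    """A set of patient ids plus the query that produced it."""

    patients: frozenset[str]
    provenance: QueryDefinition | None = None

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(sorted(self.patients))

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.patients


@dataclass(frozen=True)
class RequestManifest:
    """A sample / genotype-data request for a patient set."""

    patient_ids: tuple[str, ...]
    requested: frozenset[str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_ids": list(self.patient_ids),
                "requested": sorted(self.requested),
                "timestamp": self.timestamp,
            },
            indent=2,
        )


def resolve_term(store: Store, term: str) -> set[str]:
    """Resolve a panel term to its concept-code set.

    An ontology path expands through the hierarchy; a well-formed raw
    concept code stands for itself. Anything else is unresolvable.
    """
    if term in store.ontology:
        return expand_term(store.ontology, term)
    if is_concept_code(term):
        return {term}
    raise QueryError(f"unresolvable term {term!r}: not an ontology path or concept code")


def evaluate_panel(store: Store, panel: Panel) -> PatientSet:
    """Patients with >= min_occurs facts matching any term in the panel."""
    codes: set[str] = set()
    for term in panel.terms:
        codes |= resolve_term(store, term)
    facts = store.facts
    mask = facts["concept_code"].isin(codes)
    if panel.date_from is not None:
        mask &= facts["start_date"] >= pd.Timestamp(panel.date_from)
    if panel.date_to is not None:
        mask &= facts["start_date"] <= pd.Timestamp(panel.date_to)
    counts = facts.loc[mask, "patient_id"].value_counts()
    hits = set(counts[counts >= panel.min_occurs].index)
    return PatientSet(patients=frozenset(hits & store.patient_ids()))


def evaluate_query(store: Store, query: QueryDefinition) -> PatientSet:
    """Intersection over the query's panels (panels AND together)."""
    result: frozenset[str] | None = None
    for panel in query.panels:
        hits = evaluate_panel(store, panel).patients
        result = hits if result is None else (result & hits)
        if not result:
            break
    return PatientSet(patients=result or frozenset(), provenance=query)


def count_patients(store: Store, query: QueryDefinition) -> int:
    """Aggregate total for a query. Counts are exact (not obfuscated)."""
    return len(evaluate_query(store, query))


def export_dataset(
    store: Store,
    patient_set: PatientSet,
    variables: list[str],
    deid_key: str,
    max_shift_days: int = deidentify.DEFAULT_MAX_SHIFT_DAYS,
) -> pd.DataFrame:
    """Spreadsheet-style limited-dataset export for a patient set.

    One row per patient: the pseudonymous patient code, de-identified
    demographics (shifted birth date, truncated zip), then per requested
    variable the matching fact count and the most recent recorded value
    (empty when no fact carries a value). All emitted dates are shifted
    by the patient's keyed offset and zips truncated to three digits;
    raw identifiers never appear.
    """
    if not variables:
        raise QueryError("export requires at least one variable")
    if not deid_key:
        raise ValueError("export requires a de-identification key")
    var_codes = {v: resolve_term(store, v) for v in variables}
    patients = store.patients[store.patients["patient_id"].isin(patient_set.patients)]
    rows = []
    for p in patients.itertuples():
        offset = deidentify.date_shift_offset(p.patient_id, deid_key, max_shift_days)
        shifted_birth = deidentify.shift_date(p.birth_date.date(), offset)
        row: dict[str, object] = {
            "patient_code": deidentify.patient_code(p.patient_id, deid_key),
            "gender": p.gender,
            "race": p.race,
            "vital_status": p.vital_status,
            "birth_date": shifted_birth.isoformat(),
            "zip": deidentify.truncate_zip(p.zip),
        }
        facts = store.facts_for(p.patient_id)
        for var, codes in var_codes.items():
            matching = facts[facts["concept_code"].isin(codes)]
            row[var] = len(matching)
            valued = matching[matching["value"].astype(str).str.len() > 0]
            if len(valued):
                row[f"{var}__last_value"] = valued.sort_values("start_date")["value"].iloc[-1]
            else:
                row[f"{var}__last_value"] = ""
        rows.append(row)
    columns = ["patient_code", "gender", "race", "vital_status", "birth_date", "zip"]
    for v in variables:
        columns += [v, f"{v}__last_value"]
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values("patient_code", ignore_index=True)


def make_request(
    store: Store, patient_set: PatientSet, requested: set[str]
) -> RequestManifest:
    """Build a sample / genotype-data request manifest.

    Only patients actually possessing every requested item are kept
    (sample types from the patient dimension; ``genotype-data`` requires
    the genotyped flag). Dropped patients are logged, not errors — the
    portal's advice is to query for sample availability first.
    """
    if not requested:
        raise QueryError("request must name at least one sample type or genotype-data")
    bad = set(requested) - REQUESTABLE_ITEMS
    if bad:
        raise QueryError(f"unknown requested items {sorted(bad)}")
    patients = store.patients[store.patients["patient_id"].isin(patient_set.patients)]
    keep = []
    for p in patients.itertuples():
        have = set(str(p.sample_types).split(";")) - {""}
        if p.genotyped:
            have.add("genotype-data")
        if set(requested) <= have:
            keep.append(p.patient_id)
    dropped = len(patients) - len(keep)
    if dropped:
        logger.warning(
            "make_request: dropped %d of %d patients lacking %s",
            dropped,
            len(patients),
            sorted(requested),
        )
    return RequestManifest(
        patient_ids=tuple(sorted(keep)),
        requested=frozenset(requested),
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
    )
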