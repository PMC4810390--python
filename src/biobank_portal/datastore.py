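"""Star-schema storage of clinical facts, patients, notes and ontology.

The layout follows the i2b2 warehouse pattern: one tall *fact* table of
(patient, concept, date) observations, a patient dimension table, a note
table for clinical narratives, and a hierarchical ontology that maps
display paths to concept codes. All tables live in memory as pandas
DataFrames and round-trip losslessly through RFC-4180 CSV files.

Concept codes are namespaced strings (``"ICD9:714.0"``, ``"MED:antiTNF"``);
the namespace set is fixed, mirroring the data-type folders a portal
exposes (diagnoses, medications, labs, procedures, NLP-derived concepts,
surveys, consent attributes, sample types, genotyping status, and derived
phenotypes).

Updates are append-only: a refresh adds new patients and new facts, never
modifies or deletes existing rows, and re-applying the same delta is a
no-op.
"""

from __future__ import annotations

import datetime as dt
import os
import re
from dataclasses import dataclass, field, replace

import pandas as pd

NAMESPACES = frozenset(
    {"ICD9", "MED", "LAB", "PROC", "NLP", "SURVEY", "CONSENT", "SAMPLE", "GENO", "PHENO"}
)
SAMPLE_TYPES = frozenset({"DNA", "plasma", "serum"})
VITAL_STATUSES = frozenset({"alive", "deceased"})

FACT_COLUMNS = ["patient_id", "concept_code", "start_date", "value", "encounter_id"]
PATIENT_COLUMNS = [
    "patient_id",
    "birth_date",
    "gender",
    "race",
    "vital_status",
    "zip",
    "recontact_ok",
    "sample_types",
    "genotyped",
]
NOTE_COLUMNS = ["patient_id", "note_id", "note_date", "text"]
ONTOLOGY_COLUMNS = ["path", "concept_code", "is_folder"]

_CODE_RE = re.compile(r"^[A-Z0-9]+:[^:]+$")


class StoreFormatError(ValueError):
    """A table row violates the store's format contract."""


class UnknownPathError(KeyError):
    """An ontology path does not exist; carries the nearest existing ancestor."""

    def __init__(self, path: str, nearest_ancestor: str):
        super().__init__(path)
        self.path = path
        self.nearest_ancestor = nearest_ancestor

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return (
            f"unknown ontology path {self.path!r}; "
            f"nearest existing ancestor is {self.nearest_ancestor!r}"
        )


def is_concept_code(term: str) -> bool:
    """True if *term* is a well-formed namespaced concept code."""
    if not _CODE_RE.match(term):
        return False
    return term.split(":", 1)[0] in NAMESPACES


def _validate_code_series(codes: pd.Series, source: str) -> None:
    bad = ~codes.map(lambda c: isinstance(c, str) and is_concept_code(c))
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-base
        raise StoreFormatError(
            f"{source}, line {line}: malformed concept code {codes[bad.idxmax()]!r} "
            "(expected NAMESPACE:code with exactly one ':')"
        )


def _parse_date_series(raw: pd.Series, source: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.astype(str).str.len().gt(0)
    bad |= raw.astype(str).str.len().eq(0)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise StoreFormatError(
            f"{source}, line {line}: invalid {column} {raw[bad.idxmax()]!r} "
            "(expected ISO-8601 YYYY-MM-DD)"
        )
    return parsed


def _require_columns(df: pd.DataFrame, columns: list[str], source: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StoreFormatError(f"{source}: missing columns {missing}")


def _parse_bool_series(raw: pd.Series, source: str, column: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    lowered = raw.astype(str).str.lower()
    bad = ~lowered.isin(mapping)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise StoreFormatError(
            f"{source}, line {line}: invalid boolean {raw[bad.idxmax()]!r} in {column}"
        )
    return lowered.map(mapping)


def validate_facts(df: pd.DataFrame, source: str = "facts") -> pd.DataFrame:
    """Validate and normalize a raw fact table (string columns)."""
    _require_columns(df, FACT_COLUMNS, source)
    df = df[FACT_COLUMNS].reset_index(drop=True).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    empty = df["patient_id"].str.len().eq(0)
    if empty.any():
        raise StoreFormatError(f"{source}, line {int(empty.idxmax()) + 2}: empty patient_id")
    _validate_code_series(df["concept_code"], source)
    df["start_date"] = _parse_date_series(df["start_date"], source, "start_date")
    df["value"] = df["value"].fillna("").astype(str)
    df["encounter_id"] = df["encounter_id"].fillna("").astype(str)
    return df


def validate_patients(df: pd.DataFrame, source: str = "patients") -> pd.DataFrame:
    """Validate and normalize a raw patient dimension table."""
    _require_columns(df, PATIENT_COLUMNS, source)
    df = df[PATIENT_COLUMNS].reset_index(drop=True).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    empty = df["patient_id"].str.len().eq(0)
    if empty.any():
        raise StoreFormatError(f"{source}, line {int(empty.idxmax()) + 2}: empty patient_id")
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise StoreFormatError(
            f"{source}, line {int(dup.idxmax()) + 2}: duplicate patient_id "
            f"{df['patient_id'][dup.idxmax()]!r}"
        )
    df["birth_date"] = _parse_date_series(df["birth_date"], source, "birth_date")
    future = df["birth_date"] > pd.Timestamp(dt.date.today())
    if future.any():
        raise StoreFormatError(
            f"{source}, line {int(future.idxmax()) + 2}: birth_date in the future"
        )
    bad_vs = ~df["vital_status"].isin(VITAL_STATUSES)
    if bad_vs.any():
        raise StoreFormatError(
            f"{source}, line {int(bad_vs.idxmax()) + 2}: invalid vital_status "
            f"{df['vital_status'][bad_vs.idxmax()]!r}"
        )
    df["zip"] = df["zip"].fillna("").astype(str)
    df["recontact_ok"] = _parse_bool_series(df["recontact_ok"], source, "recontact_ok")
    df["genotyped"] = _parse_bool_series(df["genotyped"], source, "genotyped")

    def _check_samples(s: str) -> str:
        parts = [p for p in str(s).split(";") if p]
        bad = set(parts) - SAMPLE_TYPES
        if bad:
            raise StoreFormatError(f"{source}: invalid sample types {sorted(bad)}")
        return ";".join(sorted(set(parts)))

    df["sample_types"] = df["sample_types"].fillna("").map(_check_samples)
    return df


def validate_notes(df: pd.DataFrame, source: str = "notes") -> pd.DataFrame:
    _require_columns(df, NOTE_COLUMNS, source)
    df = df[NOTE_COLUMNS].reset_index(drop=True).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["note_id"] = df["note_id"].astype(str)
    dup = df["note_id"].duplicated()
    if dup.any():
        raise StoreFormatError(
            f"{source}, line {int(dup.idxmax()) + 2}: duplicate note_id "
            f"{df['note_id'][dup.idxmax()]!r}"
        )
    df["note_date"] = _parse_date_series(df["note_date"], source, "note_date")
    null_text = df["text"].isna()
    if null_text.any():
        raise StoreFormatError(f"{source}, line {int(null_text.idxmax()) + 2}: null note text")
    df["text"] = df["text"].astype(str)
    return df


@dataclass(frozen=True)
class OntologyNode:
    path: str
    concept_code: str | None
    is_folder: bool


class Ontology:
    """Hierarchy of concept terms: folders and code-bearing leaves.

    Paths are "/"-separated, case-sensitive display paths starting with
    "/". Folders carry no concept code; leaves carry exactly one.
    Expanding a folder yields the union of codes of all descendant leaves.
    """

    def __init__(self, nodes: list[OntologyNode]):
        self._nodes: dict[str, OntologyNode] = {}
        self._children: dict[str, list[str]] = {}
        for node in nodes:
            if not node.path.startswith("/") or node.path.rstrip("/") != node.path:
                raise StoreFormatError(f"ontology: bad path {node.path!r}")
            if node.path in self._nodes:
                raise StoreFormatError(f"ontology: duplicate path {node.path!r}")
            if node.is_folder and node.concept_code:
                raise StoreFormatError(f"ontology: folder {node.path!r} has a concept code")
            if not node.is_folder:
                if not node.concept_code or not is_concept_code(node.concept_code):
                    raise StoreFormatError(
                        f"ontology: leaf {node.path!r} needs exactly one valid concept code"
                    )
            self._nodes[node.path] = node
        for path in self._nodes:
            parent = path.rsplit("/", 1)[0]
            if parent and parent not in self._nodes:
                raise StoreFormatError(f"ontology: parent of {path!r} does not exist")
            self._children.setdefault(parent, []).append(path)

    @property
    def nodes(self) -> list[OntologyNode]:
        return [self._nodes[p] for p in sorted(self._nodes)]

    def __contains__(self, path: str) -> bool:
        return path in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def children(self, path: str) -> list[str]:
        return sorted(self._children.get(path, []))

    def nearest_ancestor(self, path: str) -> str:
        while path:
            path = path.rsplit("/", 1)[0]
            if path in self._nodes:
                return path
        return "/"

    def expand(self, path: str) -> set[str]:
        if path not in self._nodes:
            raise UnknownPathError(path, self.nearest_ancestor(path))
        node = self._nodes[path]
        if not node.is_folder:
            return {node.concept_code}
        codes: set[str] = set()
        stack = [path]
        while stack:
            for child in self._children.get(stack.pop(), []):
                child_node = self._nodes[child]
                if child_node.is_folder:
                    stack.append(child)
                else:
                    codes.add(child_node.concept_code)
        return codes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [n.path for n in self.nodes],
                "concept_code": [n.concept_code or "" for n in self.nodes],
                "is_folder": [n.is_folder for n in self.nodes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "ontology") -> "Ontology":
        _require_columns(df, ONTOLOGY_COLUMNS, source)
        df = df[ONTOLOGY_COLUMNS].reset_index(drop=True)
        is_folder = _parse_bool_series(df["is_folder"], source, "is_folder")
        nodes = [
            OntologyNode(
                path=str(row.path),
                concept_code=(str(row.concept_code) or None),
                is_folder=bool(flag),
            )
            for row, flag in zip(df.itertuples(), is_folder)
        ]
        return cls(nodes)


@dataclass
class Store:
    """In-memory star-schema store: facts, patients, notes, ontology."""

    facts: pd.DataFrame
    patients: pd.DataFrame
    notes: pd.DataFrame
    ontology: Ontology
    _facts_by_patient: dict | None = field(default=None, repr=False, compare=False)

    def patient_ids(self) -> set[str]:
        return set(self.patients["patient_id"])

    def has_patient(self, patient_id: str) -> bool:
        return patient_id in self.patient_ids()

    def patient(self, patient_id: str) -> pd.Series:
        rows = self.patients[self.patients["patient_id"] == patient_id]
        if rows.empty:
            raise KeyError(f"unknown patient {patient_id!r}")
        return rows.iloc[0]

    def facts_for(self, patient_id: str) -> pd.DataFrame:
        if self._facts_by_patient is None:
            object.__setattr__(
                self, "_facts_by_patient", dict(tuple(self.facts.groupby("patient_id")))
            )
        empty = self.facts.iloc[0:0]
        return self._facts_by_patient.get(patient_id, empty)

    def n_facts(self) -> int:
        return len(self.facts)

    def n_patients(self) -> int:
        return len(self.patients)


def expand_term(ontology: Ontology, path: str) -> set[str]:
    """Expand an ontology display path to its concept-code set.

    A leaf expands to the singleton of its own code; a folder expands to
    the union of the codes of every descendant leaf.
    """
    return ontology.expand(path)


def _read_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_store(facts_path, patients_path, notes_path, ontology_path) -> Store:
    """Load the four store tables from RFC-4180 CSV files.

    Malformed rows raise :class:`StoreFormatError` naming the file and
    1-based line number; a duplicate patient_id in the patient table is
    an error. Empty tables (header only) load cleanly.
    """
    facts = validate_facts(_read_csv(facts_path), source=str(facts_path))
    patients = validate_patients(_read_csv(patients_path), source=str(patients_path))
    notes = validate_notes(_read_csv(notes_path), source=str(notes_path))
    ontology = Ontology.from_frame(_read_csv(ontology_path), source=str(ontology_path))
    return Store(facts=facts, patients=patients, notes=notes, ontology=ontology)


def load_store_dir(store_dir: str | os.PathLike) -> Store:
    """Load a store from a directory holding the four standard CSV files."""
    d = os.fspath(store_dir)
    return load_store(
        os.path.join(d, "facts.csv"),
        os.path.join(d, "patients.csv"),
        os.path.join(d, "notes.csv"),
        os.path.join(d, "ontology.csv"),
    )


def _format_dates(df: pd.DataFrame, column: str) -> pd.DataFrame:
    df = df.copy()
    df[column] = pd.to_datetime(df[column]).dt.strftime("%Y-%m-%d")
    return df


def _format_bools(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    df = df.copy()
    for c in columns:
        df[c] = df[c].map({True: "true", False: "false"})
    return df


def write_store(store: Store, out_dir: str | os.PathLike) -> None:
    """Write the four tables to *out_dir* as facts/patients/notes/ontology.csv."""
    d = os.fspath(out_dir)
    os.makedirs(d, exist_ok=True)
    _format_dates(store.facts, "start_date").to_csv(
        os.path.join(d, "facts.csv"), index=False, lineterminator="\n"
    )
    patients = _format_bools(
        _format_dates(store.patients, "birth_date"), ["recontact_ok", "genotyped"]
    )
    patients.to_csv(os.path.join(d, "patients.csv"), index=False, lineterminator="\n")
    _format_dates(store.notes, "note_date").to_csv(
        os.path.join(d, "notes.csv"), index=False, lineterminator="\n"
    )
    onto = _format_bools(store.ontology.to_frame(), ["is_folder"])
    onto.to_csv(os.path.join(d, "ontology.csv"), index=False, lineterminator="\n")


def update_store(
    store: Store,
    new_facts: pd.DataFrame | None = None,
    new_patients: pd.DataFrame | None = None,
) -> Store:
    """Apply a weekly-refresh style delta: new subjects and new facts.

    Facts are append-only; exact duplicate fact rows are dropped, so
    re-applying the same delta is a no-op. A new patient row whose id
    already exists must match the stored record exactly (in particular
    its birth_date); a conflicting record is an error. Existing rows are
    never modified. Returns a new Store; the input is untouched.
    """
    facts = store.facts
    patients = store.patients
    if new_patients is not None and len(new_patients):
        if not pd.api.types.is_datetime64_any_dtype(new_patients["birth_date"]):
            new_patients = validate_patients(new_patients)
        overlap = new_patients[new_patients["patient_id"].isin(set(patients["patient_id"]))]
        if len(overlap):
            existing = patients.set_index("patient_id")
            for row in overlap.itertuples():
                old = existing.loc[row.patient_id]
                if old["birth_date"] != row.birth_date:
                    raise StoreFormatError(
                        f"update conflict for patient {row.patient_id!r}: "
                        f"birth_date {row.birth_date.date()} differs from stored "
                        f"{old['birth_date'].date()}"
                    )
        fresh = new_patients[~new_patients["patient_id"].isin(set(patients["patient_id"]))]
        patients = pd.concat([patients, fresh], ignore_index=True)
    if new_facts is not None and len(new_facts):
        if not pd.api.types.is_datetime64_any_dtype(new_facts["start_date"]):
            new_facts = validate_facts(new_facts)
        facts = pd.concat([facts, new_facts], ignore_index=True)
        facts = facts.drop_duplicates(subset=FACT_COLUMNS, ignore_index=True)
    return Store(facts=facts, patients=patients, notes=store.notes, ontology=store.ontology)
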