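"""Charlson age-comorbidity index and 10-year survival scoring.

The index flags relatively healthy control candidates in a biobank
population. ICD-9 diagnosis codes are grouped into 17 weighted
comorbidity categories; the sum of the weights of the categories present
is added to an age-band score to give the index

    X = (sum of comorbidity weights) + (age score)

which maps to a 10-year survival probability through

    Y = e^(0.9 * X),    Z = 0.983 ** Y.

Z is strictly decreasing in X: Z(0) = 98.30%, Z(2) = 90.15%,
Z(5) = 21.36%, and from X = 7 on survival is below 0.01%.

The ICD-9 -> category lists ship as an editable CSV resource
(``resources/comorbidity_map.csv``) using standard administrative-data
groupings with 3-digit / 4-digit prefixes. When both members of a graded
severity pair are present (diabetes with/without complications, mild vs
moderate-or-severe liver disease, malignancy vs metastatic solid tumor),
only the higher-weight category counts.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from importlib import resources as importlib_resources

import pandas as pd

from biobank_portal.datastore import Store
from biobank_portal.query_engine import PatientSet

#: (lower-weight, higher-weight) graded severity pairs; only the higher counts.
SEVERITY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Diabetes (mild to moderate)", "Diabetes with chronic complications"),
    ("Mild liver disease", "Moderate or severe liver disease"),
    ("Any malignancy, including lymphoma and leukemia", "Metastatic solid tumor"),
)

#: Age bands (inclusive lower bound, score); <50 scores 0, 90+ scores 5.
AGE_BANDS: tuple[tuple[int, int], ...] = ((50, 1), (60, 2), (70, 3), (80, 4), (90, 5))

EXPECTED_WEIGHTS = sorted([1] * 10 + [2] * 4 + [3, 6, 6])


@dataclass(frozen=True)
class ComorbidityMap:
    """17 weighted comorbidity categories and their ICD-9 code lists."""

    weights: dict[str, int]
    icd_codes: dict[str, frozenset[str]]

    def __post_init__(self):
        if sorted(self.weights.values()) != EXPECTED_WEIGHTS:
            raise ValueError(
                "comorbidity map must carry 17 categories with weights "
                "{1 x10, 2 x4, 3, 6, 6}"
            )
        seen: set[str] = set()
        for cat, codes in self.icd_codes.items():
            if codes & seen:
                raise ValueError(f"comorbidity map: overlapping codes in {cat!r}")
            seen |= codes

    @property
    def categories(self) -> list[str]:
        return sorted(self.weights)

    def match_category(self, icd_code_part: str) -> str | None:
        """Category matching a bare ICD-9 code (prefix at dot boundary)."""
        for cat, codes in self.icd_codes.items():
            for c in codes:
                if icd_code_part == c or icd_code_part.startswith(c + "."):
                    return cat
        return None


def load_comorbidity_map(path: str | None = None) -> ComorbidityMap:
    """Load the category/weight/ICD-code map (bundled resource by default)."""
    if path is None:
        ref = importlib_resources.files("biobank_portal.resources") / "comorbidity_map.csv"
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    weights: dict[str, int] = {}
    codes: dict[str, set[str]] = {}
    for row in df.itertuples():
        weights[row.category] = int(row.weight)
        codes.setdefault(row.category, set()).add(str(row.icd_code))
    return ComorbidityMap(
        weights=weights, icd_codes={c: frozenset(v) for c, v in codes.items()}
    )


@dataclass(frozen=True)
class CharlsonResult:
    """Per-patient Charlson scoring: categories, index X, survival Z."""

    patient_id: str
    categories_present: frozenset[str]
    comorbidity_sum: int
    age_score: int
    index: int  # X
    survival: float  # Z, as a fraction in (0, 1]

    @property
    def survival_percent(self) -> str:
        return format_survival_percent(self.survival)


def format_survival_percent(z: float) -> str:
    """Display form of a survival fraction: percent with two decimals."""
    return f"{z * 100:.2f}%"


def apply_severity_dominance(categories: set[str]) -> set[str]:
    """Drop the milder member of each graded pair when both are present."""
    out = set(categories)
    for mild, severe in SEVERITY_PAIRS:
        if mild in out and severe in out:
            out.discard(mild)
    return out


def map_comorbidities(
    store: Store,
    patient_id: str,
    comorbidity_map: ComorbidityMap | None = None,
    as_of_date: dt.date | None = None,
) -> set[str]:
    """Comorbidity categories for which a patient has >= 1 ICD-9 fact.

    Severity dominance is applied. With *as_of_date*, only facts dated
    on or before it count. Unknown patients are an error.
    """
    if not store.has_patient(patient_id):
        raise KeyError(f"unknown patient {patient_id!r}")
    if comorbidity_map is None:
        comorbidity_map = load_comorbidity_map()
    facts = store.facts_for(patient_id)
    facts = facts[facts["concept_code"].str.startswith("ICD9:")]
    if as_of_date is not None:
        facts = facts[facts["start_date"] <= pd.Timestamp(as_of_date)]
    present: set[str] = set()
    for code in facts["concept_code"].unique():
        cat = comorbidity_map.match_category(code.split(":", 1)[1])
        if cat:
            present.add(cat)
    return apply_severity_dominance(present)


def age_score(age_years: float) -> int:
    """Age-band score: <50 -> 0, then +1 per decade, capping at 5 for 90+."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    score = 0
    for lower, s in AGE_BANDS:
        if age_years >= lower:
            score = s
    return score


def charlson_survival(x: int) -> float:
    """10-year survival probability Z = 0.983 ** e^(0.9 X), as a fraction."""
    if x < 0:
        raise ValueError(f"Charlson index must be non-negative, got {x}")
    return 0.983 ** math.exp(0.9 * x)


def _age_at(birth_date: dt.date, as_of: dt.date) -> int:
    years = as_of.year - birth_date.year
    if (as_of.month, as_of.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def charlson_index(
    store: Store,
    patient_id: str,
    as_of_date: dt.date,
    comorbidity_map: ComorbidityMap | None = None,
) -> CharlsonResult:
    """Assemble the full Charlson result for one patient.

    Age is computed from the TRUE birth date (de-identification shifts
    only exported values, never the scoring inputs).
    """
    if comorbidity_map is None:
        comorbidity_map = load_comorbidity_map()
    patient = store.patient(patient_id)
    birth = patient["birth_date"].date()
    if as_of_date < birth:
        raise ValueError(f"as_of_date {as_of_date} precedes birth date {birth}")
    categories = map_comorbidities(store, patient_id, comorbidity_map, as_of_date)
    weight_sum = sum(comorbidity_map.weights[c] for c in categories)
    a_score = age_score(_age_at(birth, as_of_date))
    x = weight_sum + a_score
    return CharlsonResult(
        patient_id=patient_id,
        categories_present=frozenset(categories),
        comorbidity_sum=weight_sum,
        age_score=a_score,
        index=x,
        survival=charlson_survival(x),
    )


def default_as_of_date(store: Store) -> dt.date:
    """Latest fact date in the store (today when the store has no facts)."""
    if len(store.facts):
        return store.facts["start_date"].max().date()
    return dt.date.today()


def healthy_controls(
    store: Store,
    patient_set: PatientSet,
    min_survival: float,
    as_of_date: dt.date | None = None,
    comorbidity_map: ComorbidityMap | None = None,
) -> PatientSet:
    """Patients whose 10-year survival probability is >= *min_survival*."""
    if not (0 < min_survival <= 1):
        raise ValueError("min_survival must be in (0, 1]")
    if as_of_date is None:
        as_of_date = default_as_of_date(store)
    if comorbidity_map is None:
        comorbidity_map = load_comorbidity_map()
    keep = {
        pid
        for pid in patient_set.patients
        if charlson_index(store, pid, as_of_date, comorbidity_map).survival >= min_survival
    }
    return PatientSet(patients=frozenset(keep))


#: Survival bands exposed as queryable derived-phenotype codes.
HEALTHY_BANDS: tuple[tuple[str, float], ...] = (
    ("PHENO:healthy_survival_ge90", 0.90),
    ("PHENO:healthy_survival_ge75", 0.75),
    ("PHENO:healthy_survival_ge50", 0.50),
)


def tag_healthy_bands(
    store: Store,
    as_of_date: dt.date | None = None,
    comorbidity_map: ComorbidityMap | None = None,
    bands: tuple[tuple[str, float], ...] = HEALTHY_BANDS,
) -> Store:
    """Write banded healthy-population facts so queries can use them.

    Each patient whose survival clears a band's cutoff receives a
    PHENO-namespace fact dated *as_of_date*; the returned store can then
    answer panel queries like "survival >= 90% AND genotyped".
    """
    from biobank_portal.datastore import update_store

    if as_of_date is None:
        as_of_date = default_as_of_date(store)
    if comorbidity_map is None:
        comorbidity_map = load_comorbidity_map()
    rows = []
    for pid in sorted(store.patient_ids()):
        z = charlson_index(store, pid, as_of_date, comorbidity_map).survival
        for code, cutoff in bands:
            if z >= cutoff:
                rows.append(
                    {
                        "patient_id": pid,
                        "concept_code": code,
                        "start_date": pd.Timestamp(as_of_date),
                        "value": f"{z:.6f}",
                        "encounter_id": "",
                    }
                )
    if not rows:
        return store
    return update_store(store, new_facts=pd.DataFrame(rows))
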