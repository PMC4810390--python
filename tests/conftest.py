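import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from biobank_portal.datastore import Ontology, OntologyNode, Store, validate_facts, validate_patients
from biobank_portal.synthetic_data import CohortConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_tiny_store() -> Store:
    """Three patients, a handful of facts, and a two-level ontology."""
    facts = validate_facts(
        pd.DataFrame(
            [
                ("P1", "ICD9:714.0", "2010-03-01", "", ""),
                ("P1", "ICD9:714.0", "2011-06-15", "", ""),
                ("P1", "MED:antiTNF", "2011-07-01", "40mg", ""),
                ("P2", "LAB:crp", "2012-01-05", "12.5", ""),
                ("P3", "ICD9:714.0", "2009-11-20", "", ""),
                ("P3", "GENO:genotyped", "2014-01-01", "true", ""),
            ],
            columns=["patient_id", "concept_code", "start_date", "value", "encounter_id"],
        )
    )
    patients = validate_patients(
        pd.DataFrame(
            [
                ("P1", "1950-04-02", "F", "white", "alive", "02129", "true", "DNA;plasma", "true"),
                ("P2", "1980-12-30", "M", "black", "alive", "02114", "false", "DNA", "false"),
                ("P3", "1942-07-19", "F", "asian", "deceased", "94110", "true", "plasma;serum", "true"),
            ],
            columns=[
                "patient_id", "birth_date", "gender", "race", "vital_status",
                "zip", "recontact_ok", "sample_types", "genotyped",
            ],
        )
    )
    notes = pd.DataFrame(
        {
            "patient_id": pd.Series(["P1", "P2"], dtype=str),
            "note_id": pd.Series(["N1", "N2"], dtype=str),
            "note_date": pd.to_datetime(["2011-06-15", "2012-01-05"]),
            "text": ["erosions on hand xray today.", "no erosions seen on imaging."],
        }
    )
    ontology = Ontology(
        [
            OntologyNode("/Healthcare Data", None, True),
            OntologyNode("/Healthcare Data/Diagnoses", None, True),
            OntologyNode("/Healthcare Data/Diagnoses/ICD9:714.0", "ICD9:714.0", False),
            OntologyNode("/Healthcare Data/Medications", None, True),
            OntologyNode("/Healthcare Data/Medications/MED:antiTNF", "MED:antiTNF", False),
            OntologyNode("/Labs", None, True),
            OntologyNode("/Labs/LAB:crp", "LAB:crp", False),
            OntologyNode("/Genomics", None, True),
            OntologyNode("/Genomics/GENO:genotyped", "GENO:genotyped", False),
        ]
    )
    return Store(facts=facts, patients=patients, notes=notes, ontology=ontology)


@pytest.fixture
def tiny_store() -> Store:
    return make_tiny_store()


@pytest.fixture(scope="session")
def cohort200():
    """Small generated cohort shared across tests (n=200, seed=7)."""
    config = CohortConfig(n_patients=200, seed=7)
    store, truth = generate_cohort(config)
    return config, store, truth


@pytest.fixture(scope="session")
def cohort500():
    """Mid-size cohort for oracle-equivalence checks (n=500, seed=11)."""
    config = CohortConfig(n_patients=500, seed=11)
    store, truth = generate_cohort(config)
    return config, store, truth


def naive_evaluate_query(store: Store, query) -> set[str]:
    """Brute-force per-fact scan with the same panel predicate.

    Deliberately independent of the query engine: resolves terms by
    walking the ontology node list with a path-prefix filter, then scans
    every fact row in a plain Python loop.
    """
    from biobank_portal.datastore import is_concept_code

    def resolve(term: str) -> set[str]:
        nodes = {n.path: n for n in store.ontology.nodes}
        if term in nodes:
            node = nodes[term]
            if not node.is_folder:
                return {node.concept_code}
            return {
                n.concept_code
                for n in store.ontology.nodes
                if not n.is_folder and n.path.startswith(term + "/")
            }
        assert is_concept_code(term), term
        return {term}

    result: set[str] | None = None
    rows = list(store.facts.itertuples())
    for panel in query.panels:
        codes = set()
        for term in panel.terms:
            codes |= resolve(term)
        counts: dict[str, int] = {}
        for row in rows:
            if row.concept_code not in codes:
                continue
            d = row.start_date.date()
            if panel.date_from is not None and d < panel.date_from:
                continue
            if panel.date_to is not None and d > panel.date_to:
                continue
            counts[row.patient_id] = counts.get(row.patient_id, 0) + 1
        hits = {p for p, c in counts.items() if c >= panel.min_occurs}
        hits &= set(store.patients["patient_id"])
        result = hits if result is None else result & hits
    return result or set()


def random_query(rng, store: Store):
    """A random Boolean panel query over codes and folder paths in the store."""
    from biobank_portal.query_engine import Panel, QueryDefinition

    codes = sorted(store.facts["concept_code"].unique())
    folders = [n.path for n in store.ontology.nodes if n.is_folder]
    terms_pool = codes + folders
    panels = []
    for _ in range(int(rng.integers(1, 4))):
        k = int(rng.integers(1, 4))
        terms = tuple(terms_pool[int(i)] for i in rng.choice(len(terms_pool), size=k, replace=False))
        min_occurs = int(rng.integers(1, 4))
        if rng.random() < 0.4:
            start = dt.date(2006, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3000)))
            window = (start, start + dt.timedelta(days=int(rng.integers(30, 2000))))
        else:
            window = (None, None)
        panels.append(
            Panel(terms=terms, date_from=window[0], date_to=window[1], min_occurs=min_occurs)
        )
    return QueryDefinition(panels=tuple(panels))
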