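"""Seed-reproducible synthetic EHR cohorts.

The generator emulates the statistical structure a biobank portal
assumes, at desk scale:

* true phenotype labels ~ Bernoulli(prevalence);
* anchor diagnosis codes with *false-positive inflation*: true cases
  carry the anchor ICD-9 code with probability 1 - fn_rate, but
  non-cases also acquire it (billing artifacts, rule-out workups) with
  probability fp_rate — so the ICD-alone cohort strictly over-counts the
  truly affected;
* informative count features whose Poisson log-rate is shifted by an
  effect size for true cases (one coded anchor-count feature, one
  narrative concept), plus label-independent noise features;
* clinical notes synthesized from sentence templates with planted
  concept mentions, a fixed fraction of them negated by explicit cues,
  so the dictionary-matching NLP stage is honestly exercised;
* comorbidity burdens drawn per Charlson category from the same ICD-9
  resource the scorer uses;
* demographics, zips, consent/recontact flags, sample types, and
  genotyped status.

Everything is written in the datastore's CSV formats, and a
GroundTruth object records the labels, planted mention counts and
comorbidity assignments so tests can hold the pipeline to exact
bookkeeping.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from biobank_portal import charlson as charlson_mod
from biobank_portal.datastore import Ontology, OntologyNode, Store, validate_notes
from biobank_portal.phenotyping import PhenotypeDefinition

DEFAULT_COMORBIDITY_RATES: dict[str, float] = {
    "Myocardial infarction": 0.03,
    "Congestive heart failure": 0.04,
    "Peripheral vascular disease": 0.03,
    "Cerebrovascular disease": 0.04,
    "Dementia": 0.02,
    "Rheumatologic disease": 0.02,
    "Chronic pulmonary disease": 0.06,
    "Peptic ulcer disease": 0.02,
    "Mild liver disease": 0.02,
    "Diabetes (mild to moderate)": 0.08,
    "Diabetes with chronic complications": 0.02,
    "Hemiplegia or paraplegia": 0.01,
    "Renal disease": 0.03,
    "Any malignancy, including lymphoma and leukemia": 0.04,
    "Moderate or severe liver disease": 0.01,
    "Metastatic solid tumor": 0.01,
    "AIDS": 0.005,
}

DEFAULT_SAMPLE_TYPE_RATES: dict[str, float] = {"DNA": 0.95, "plasma": 0.85, "serum": 0.85}

NLP_CONCEPT = ("erosions", ("erosions", "erosive changes"))

_POSITIVE_TEMPLATES = (
    "{syn} noted on exam today.",
    "imaging of the hands shows {syn} at several joints.",
    "patient reports {syn} again at this visit.",
)
_NEGATED_TEMPLATES = (
    "no {syn} on imaging obtained today.",
    "patient denies {syn} at this time.",
    "negative for {syn} on careful review.",
    "imaging without {syn} at any joint.",
    "we ruled out {syn} during this admission.",
)
_FILLER_SENTENCES = (
    "routine follow up visit in clinic today.",
    "vitals stable and reviewed at length with the patient.",
    "medication list reviewed and updated during the visit.",
)


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 1000
    seed: int = 0
    phenotype_name: str = "rheumatoid_arthritis"
    anchor_code: str = "ICD9:714.0"
    phenotype_prevalence: float = 0.10
    icd_fp_rate: float = 0.04
    icd_fn_rate: float = 0.05
    beta_icd: float = 1.2
    beta_nlp: float = 1.0
    base_icd_rate: float = 2.0
    base_nlp_rate: float = 2.0
    n_noise_features: int = 8
    noise_rate: float = 0.5
    note_rate: float = 5.0
    negation_rate: float = 0.2
    comorbidity_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_RATES)
    )
    genotyped_fraction: float = 0.35
    recontact_rate: float = 0.90
    sample_type_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_TYPE_RATES)
    )
    date_start: dt.date = dt.date(2005, 1, 1)
    date_end: dt.date = dt.date(2015, 12, 31)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        probs = {
            "phenotype_prevalence": self.phenotype_prevalence,
            "icd_fp_rate": self.icd_fp_rate,
            "icd_fn_rate": self.icd_fn_rate,
            "negation_rate": self.negation_rate,
            "genotyped_fraction": self.genotyped_fraction,
            "recontact_rate": self.recontact_rate,
            **{f"comorbidity_rates[{k}]": v for k, v in self.comorbidity_rates.items()},
            **{f"sample_type_rates[{k}]": v for k, v in self.sample_type_rates.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name, v in (
            ("base_icd_rate", self.base_icd_rate),
            ("base_nlp_rate", self.base_nlp_rate),
            ("noise_rate", self.noise_rate),
            ("note_rate", self.note_rate),
        ):
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_noise_features < 0:
            raise ConfigError("n_noise_features must be >= 0")
        if self.date_end < self.date_start:
            raise ConfigError("date_end precedes date_start")

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        doc = yaml.safe_load(text) or {}
        for key in ("date_start", "date_end"):
            if key in doc and isinstance(doc[key], str):
                doc[key] = dt.date.fromisoformat(doc[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


@dataclass
class GroundTruth:
    """Generator bookkeeping, exactly consistent with the emitted files."""

    labels: dict[str, bool]
    anchored: set[str]
    mention_counts: dict[str, dict[str, tuple[int, int]]]  # pid -> concept -> (pos, neg)
    charlson_categories: dict[str, set[str]]

    def labeler(self, patient_id: str) -> bool:
        return self.labels[patient_id]

    @property
    def cases(self) -> set[str]:
        return {p for p, y in self.labels.items() if y}


def default_definition(config: CohortConfig) -> PhenotypeDefinition:
    """The phenotype definition matching the generator's informative features."""
    noise_codes = tuple(f"LAB:noise{i + 1}" for i in range(config.n_noise_features))
    return PhenotypeDefinition(
        name=config.phenotype_name,
        anchor_codes=frozenset({config.anchor_code}),
        coded_features=(config.anchor_code,) + noise_codes,
        nlp_concepts=(NLP_CONCEPT,),
    )


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _make_ontology(config: CohortConfig, icd_codes: set[str]) -> Ontology:
    nodes = [
        OntologyNode("/Healthcare Data", None, True),
        OntologyNode("/Healthcare Data/Diagnoses", None, True),
        OntologyNode("/Healthcare Data/Labs", None, True),
        OntologyNode("/Biobank", None, True),
        OntologyNode("/Biobank/Consent", None, True),
        OntologyNode("/Biobank/Consent/CONSENT:biobank", "CONSENT:biobank", False),
        OntologyNode("/Biobank/Consent/CONSENT:recontact_ok", "CONSENT:recontact_ok", False),
        OntologyNode("/Biobank/Samples", None, True),
        OntologyNode("/Biobank/Genomics", None, True),
        OntologyNode("/Biobank/Genomics/GENO:genotyped", "GENO:genotyped", False),
        OntologyNode("/Curated Disease Populations", None, True),
        OntologyNode(
            f"/Curated Disease Populations/PHENO:{config.phenotype_name}",
            f"PHENO:{config.phenotype_name}",
            False,
        ),
        OntologyNode("/Healthy Populations", None, True),
    ]
    for code, _cutoff in charlson_mod.HEALTHY_BANDS:
        nodes.append(OntologyNode(f"/Healthy Populations/{code}", code, False))
    for st in sorted(DEFAULT_SAMPLE_TYPE_RATES):
        nodes.append(OntologyNode(f"/Biobank/Samples/SAMPLE:{st}", f"SAMPLE:{st}", False))
    for code in sorted(icd_codes):
        nodes.append(OntologyNode(f"/Healthcare Data/Diagnoses/{code}", code, False))
    for i in range(config.n_noise_features):
        code = f"LAB:noise{i + 1}"
        nodes.append(OntologyNode(f"/Healthcare Data/Labs/{code}", code, False))
    return Ontology(nodes)


def _compose_note(
    rng: np.random.Generator, n_pos: int, n_neg: int, synonyms: tuple[str, ...]
) -> str:
    """One note: filler, then positive mention sentences, then negated ones.

    Positive sentences precede negated ones so that no negation cue can
    fall inside the token window before a planted positive mention —
    keeping the bookkeeping exactly consistent with what the dictionary
    matcher extracts.
    """
    sentences = [_FILLER_SENTENCES[int(rng.integers(0, len(_FILLER_SENTENCES)))]]
    for _ in range(n_pos):
        syn = synonyms[int(rng.integers(0, len(synonyms)))]
        tpl = _POSITIVE_TEMPLATES[int(rng.integers(0, len(_POSITIVE_TEMPLATES)))]
        sentences.append(tpl.format(syn=syn))
    for _ in range(n_neg):
        syn = synonyms[int(rng.integers(0, len(synonyms)))]
        tpl = _NEGATED_TEMPLATES[int(rng.integers(0, len(_NEGATED_TEMPLATES)))]
        sentences.append(tpl.format(syn=syn))
    return " ".join(sentences)


def generate_cohort(
    config: CohortConfig, out_dir: str | os.PathLike | None = None
) -> tuple[Store, GroundTruth]:
    """Generate a full synthetic cohort (optionally writing the CSV files).

    Returns the in-memory store and the exact ground-truth bookkeeping.
    The same config and seed always produce byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    comorbidity_map = charlson_mod.load_comorbidity_map()
    concept_id, synonyms = NLP_CONCEPT
    width = max(5, len(str(config.n_patients)))

    patient_rows, fact_rows, note_rows = [], [], []
    labels: dict[str, bool] = {}
    anchored: set[str] = set()
    mention_counts: dict[str, dict[str, tuple[int, int]]] = {}
    charlson_categories: dict[str, set[str]] = {}
    icd_codes_used: set[str] = {config.anchor_code}
    noise_codes = [f"LAB:noise{i + 1}" for i in range(config.n_noise_features)]
    note_counter = 0
    encounter_counter = 0

    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        y = bool(rng.random() < config.phenotype_prevalence)
        labels[pid] = y

        birth = _random_date(rng, dt.date(1930, 1, 1), dt.date(1995, 12, 31))
        gender = "F" if rng.random() < 0.55 else "M"
        race = ["white", "black", "asian", "hispanic", "other"][
            int(rng.choice(5, p=[0.6, 0.15, 0.1, 0.1, 0.05]))
        ]
        vital = "alive" if rng.random() < 0.95 else "deceased"
        zip_code = f"{int(rng.integers(0, 100000)):05d}"
        recontact = bool(rng.random() < config.recontact_rate)
        samples = sorted(
            st for st, rate in config.sample_type_rates.items() if rng.random() < rate
        )
        genotyped = bool(rng.random() < config.genotyped_fraction)
        patient_rows.append(
            {
                "patient_id": pid,
                "birth_date": pd.Timestamp(birth),
                "gender": gender,
                "race": race,
                "vital_status": vital,
                "zip": zip_code,
                "recontact_ok": recontact,
                "sample_types": ";".join(samples),
                "genotyped": genotyped,
            }
        )

        def emit(code: str, n: int = 1, value: str = ""):
            nonlocal encounter_counter
            for _ in range(n):
                encounter_counter += 1
                fact_rows.append(
                    {
                        "patient_id": pid,
                        "concept_code": code,
                        "start_date": pd.Timestamp(
                            _random_date(rng, config.date_start, config.date_end)
                        ),
                        "value": value,
                        # a distinct encounter per observation: two facts are
                        # never the same event, so update dedup stays exact
                        "encounter_id": f"E{encounter_counter:08d}",
                    }
                )

        # anchor diagnosis facts: cases minus false negatives, plus
        # billing false positives among non-cases
        is_anchored = bool(
            rng.random() < (1.0 - config.icd_fn_rate if y else config.icd_fp_rate)
        )
        if is_anchored:
            anchored.add(pid)
            rate = config.base_icd_rate * math.exp(config.beta_icd * y)
            emit(config.anchor_code, 1 + int(rng.poisson(rate)))

        # label-independent noise features
        for code in noise_codes:
            k = int(rng.poisson(config.noise_rate))
            if k:
                emit(code, k)

        # comorbidity burden, drawn from the Charlson resource lists
        cats: set[str] = set()
        anchor_code_part = config.anchor_code.split(":", 1)[1]
        for cat in sorted(config.comorbidity_rates):
            if rng.random() < config.comorbidity_rates[cat]:
                cats.add(cat)
                # never emit the anchor code itself here: anchor facts are
                # governed solely by the fp/fn mechanism above
                codes = sorted(comorbidity_map.icd_codes[cat] - {anchor_code_part})
                code = codes[int(rng.integers(0, len(codes)))]
                icd_codes_used.add(f"ICD9:{code}")
                emit(f"ICD9:{code}")
        if is_anchored:
            anchor_cat = comorbidity_map.match_category(
                config.anchor_code.split(":", 1)[1]
            )
            if anchor_cat:
                cats.add(anchor_cat)
        charlson_categories[pid] = cats

        # consent, sample and genotyping flags as queryable facts
        emit("CONSENT:biobank", value="true")
        if recontact:
            emit("CONSENT:recontact_ok", value="true")
        for st in samples:
            emit(f"SAMPLE:{st}")
        if genotyped:
            emit("GENO:genotyped", value="true")

        # narrative mentions of the informative concept
        n_mentions = int(rng.poisson(config.base_nlp_rate * math.exp(config.beta_nlp * y)))
        negated_flags = rng.random(n_mentions) < config.negation_rate
        n_pos = int(n_mentions - negated_flags.sum())
        n_neg = int(negated_flags.sum())
        mention_counts[pid] = {concept_id: (n_pos, n_neg)}

        n_notes = int(rng.poisson(config.note_rate))
        if n_notes == 0 and n_mentions > 0:
            n_notes = 1
        if n_notes:
            pos_alloc = rng.integers(0, n_notes, size=n_pos)
            neg_alloc = rng.integers(0, n_notes, size=n_neg)
            for j in range(n_notes):
                note_counter += 1
                text = _compose_note(
                    rng,
                    int(np.sum(pos_alloc == j)),
                    int(np.sum(neg_alloc == j)),
                    synonyms,
                )
                note_rows.append(
                    {
                        "patient_id": pid,
                        "note_id": f"N{note_counter:07d}",
                        "note_date": pd.Timestamp(
                            _random_date(rng, config.date_start, config.date_end)
                        ),
                        "text": text,
                    }
                )

    facts = pd.DataFrame(
        fact_rows,
        columns=["patient_id", "concept_code", "start_date", "value", "encounter_id"],
    )
    patients = pd.DataFrame(patient_rows)
    notes = validate_notes(
        pd.DataFrame(note_rows, columns=["patient_id", "note_id", "note_date", "text"])
    )
    ontology = _make_ontology(config, icd_codes_used)
    store = Store(facts=facts, patients=patients, notes=notes, ontology=ontology)
    truth = GroundTruth(
        labels=labels,
        anchored=anchored,
        mention_counts=mention_counts,
        charlson_categories=charlson_categories,
    )
    if out_dir is not None:
        from biobank_portal.datastore import write_store

        write_store(store, out_dir)
    return store, truth


def expected_inflation(config: CohortConfig) -> float:
    """Analytic expected ratio of anchored patients to anchored true cases.

    [p(1-fn) + (1-p)fp] / [p(1-fn)]; NaN (undefined) when no true case
    can ever be anchored.
    """
    p, fp, fn = config.phenotype_prevalence, config.icd_fp_rate, config.icd_fn_rate
    denom = p * (1.0 - fn)
    if denom == 0.0:
        return float("nan")
    return (denom + (1.0 - p) * fp) / denom
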