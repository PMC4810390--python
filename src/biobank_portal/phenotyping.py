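"""High-throughput probabilistic EHR phenotyping.

The pipeline turns a loose, billing-code-based disease definition into a
calibrated classifier in six steps:

1. define the phenotype by anchor diagnosis codes;
2. broaden it with candidate coded features (comorbidities, symptoms,
   medications) and narrative concepts;
3. extract narrative concept counts by dictionary matching with negation
   handling over the clinical notes;
4. draw a random gold-standard subset of the anchor cohort for chart
   review (labels come from a pluggable labeler);
5. fit an adaptive LASSO penalized logistic regression on the labeled
   subset, giving each patient a probability of truly having the
   phenotype;
6. choose a probability threshold (by target specificity) and score the
   whole anchor cohort, writing queryable derived-phenotype facts.

Diagnosis codes alone over-count: they are entered for billing and for
rule-out workups, so the anchor cohort is inflated with false positives.
The fitted model trades a little sensitivity for a far higher positive
predictive value, which is what downstream genetic studies need.

The adaptive LASSO is a two-stage penalized fit: an initial ridge
logistic regression gives coefficients ``b~``; the second stage solves an
L1-penalized logistic regression in which feature j is penalized
proportionally to ``1/|b~_j|**gamma`` (gamma = 1), so features the pilot
fit found irrelevant are pushed to exactly zero while strong features
are nearly unpenalized. The penalty level is chosen by stratified
5-fold cross-validated deviance. Counts are transformed log(1+count)
and standardized before fitting; reported coefficients are on the
original log-count scale.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from biobank_portal.datastore import Store, update_store
from biobank_portal.query_engine import Panel, PatientSet, evaluate_panel

NEGATION_CUES: tuple[tuple[str, ...], ...] = (
    ("no",),
    ("denies",),
    ("negative", "for"),
    ("without",),
    ("ruled", "out"),
)
NEGATION_WINDOW = 6  # tokens before the mention within which a cue negates

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class PhenotypingError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named phenotype: anchor codes, coded features, narrative concepts."""

    name: str
    anchor_codes: frozenset[str]
    coded_features: tuple[str, ...]
    nlp_concepts: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        if not self.anchor_codes:
            raise PhenotypingError("phenotype definition needs at least one anchor code")
        names = list(self.coded_features) + [c for c, _ in self.nlp_concepts]
        if len(names) != len(set(names)):
            raise PhenotypingError("feature names must be unique")
        for concept, synonyms in self.nlp_concepts:
            if not synonyms or any(not s.strip() for s in synonyms):
                raise PhenotypingError(f"concept {concept!r} has an empty synonym")

    @property
    def feature_names(self) -> list[str]:
        return list(self.coded_features) + [f"nlp:{c}" for c, _ in self.nlp_concepts]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "name": self.name,
                "anchor_codes": sorted(self.anchor_codes),
                "coded_features": list(self.coded_features),
                "nlp_concepts": [
                    {"id": c, "synonyms": list(syn)} for c, syn in self.nlp_concepts
                ],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PhenotypeDefinition":
        doc = yaml.safe_load(text)
        return cls(
            name=doc["name"],
            anchor_codes=frozenset(doc["anchor_codes"]),
            coded_features=tuple(doc.get("coded_features", [])),
            nlp_concepts=tuple(
                (c["id"], tuple(c["synonyms"])) for c in doc.get("nlp_concepts", [])
            ),
        )


@dataclass
class PhenotypeModel:
    """A fitted phenotype classifier (original log-count scale)."""

    features: list[str]
    coefficients: dict[str, float]
    intercept: float
    adaptive_weights: dict[str, float]
    penalty: float
    threshold: float | None = None
    metrics: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return [f for f in self.features if self.coefficients[f] != 0.0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "coefficients": self.coefficients,
                "intercept": self.intercept,
                "adaptive_weights": self.adaptive_weights,
                "penalty": self.penalty,
                "threshold": self.threshold,
                "metrics": self.metrics,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhenotypeModel":
        doc = json.loads(text)
        return cls(
            features=doc["features"],
            coefficients=doc["coefficients"],
            intercept=doc["intercept"],
            adaptive_weights=doc["adaptive_weights"],
            penalty=doc["penalty"],
            threshold=doc.get("threshold"),
            metrics=doc.get("metrics", {}),
        )


def anchor_cohort(store: Store, anchor_codes: set[str]) -> PatientSet:
    """Patients with at least one fact carrying an anchor diagnosis code."""
    if not anchor_codes:
        raise PhenotypingError("anchor code set must be non-empty")
    return evaluate_panel(store, Panel(terms=tuple(sorted(anchor_codes)), min_occurs=1))


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens (alphanumeric runs)."""
    return _TOKEN_RE.findall(text.lower())


def _count_mentions(tokens: list[str], synonym_tokens: list[list[str]]) -> int:
    """Non-negated whole-word mentions of any synonym in a token stream."""
    count = 0
    n = len(tokens)
    for syn in synonym_tokens:
        k = len(syn)
        for i in range(n - k + 1):
            if tokens[i : i + k] != syn:
                continue
            window_start = max(0, i - NEGATION_WINDOW)
            negated = False
            for cue in NEGATION_CUES:
                m = len(cue)
                # cue must END within the window before the mention
                for j in range(window_start, i - m + 1):
                    if tokens[j : j + m] == list(cue) and j + m <= i:
                        negated = True
                        break
                if negated:
                    break
            if not negated:
                count += 1
    return count


def extract_nlp_features(
    notes: pd.DataFrame,
    nlp_concepts: tuple[tuple[str, tuple[str, ...]], ...],
) -> pd.DataFrame:
    """Per-patient narrative concept counts by dictionary matching.

    Matching is case-insensitive and whole-word; a mention is negated —
    and excluded — when a negation cue ("no", "denies", "negative for",
    "without", "ruled out") ends within 6 tokens before it. Counts are
    summed over all of a patient's notes. Returns a patient x concept
    DataFrame covering every patient appearing in *notes*.
    """
    for concept, synonyms in nlp_concepts:
        if not synonyms or any(not s.strip() for s in synonyms):
            raise PhenotypingError(f"concept {concept!r} has an empty synonym")
    syn_tokens = {c: [tokenize(s) for s in syns] for c, syns in nlp_concepts}
    patients = sorted(notes["patient_id"].unique())
    counts = {c: dict.fromkeys(patients, 0) for c, _ in nlp_concepts}
    for row in notes.itertuples():
        tokens = tokenize(row.text)
        for concept, _ in nlp_concepts:
            hits = _count_mentions(tokens, syn_tokens[concept])
            if hits:
                counts[concept][row.patient_id] += hits
    return pd.DataFrame(
        {c: [counts[c][p] for p in patients] for c, _ in nlp_concepts},
        index=pd.Index(patients, name="patient_id"),
    )


def build_feature_matrix(
    store: Store, definition: PhenotypeDefinition, patients: PatientSet | None = None
) -> pd.DataFrame:
    """log(1+count) feature matrix over the anchor cohort (or given set).

    Coded features are fact counts per concept code; narrative features
    are non-negated mention counts from the notes. Column order is the
    definition's order (coded first, then ``nlp:<concept>``), so it is
    deterministic.
    """
    if patients is None:
        patients = anchor_cohort(store, set(definition.anchor_codes))
    index = pd.Index(sorted(patients.patients), name="patient_id")
    data = {}
    facts = store.facts[store.facts["patient_id"].isin(index)]
    for code in definition.coded_features:
        sub = facts[facts["concept_code"] == code]
        counts = sub["patient_id"].value_counts()
        data[code] = counts.reindex(index, fill_value=0).to_numpy(dtype=float)
    if definition.nlp_concepts:
        notes = store.notes[store.notes["patient_id"].isin(index)]
        nlp = extract_nlp_features(notes, definition.nlp_concepts)
        for concept, _ in definition.nlp_concepts:
            col = nlp[concept] if concept in nlp.columns else pd.Series(dtype=float)
            data[f"nlp:{concept}"] = (
                col.reindex(index, fill_value=0).to_numpy(dtype=float)
            )
    X = pd.DataFrame(data, index=index, columns=definition.feature_names)
    return np.log1p(X)


def sample_gold_standard(
    anchor: PatientSet, n: int, seed: int, labeler=None
) -> pd.DataFrame:
    """Simple random sample (without replacement) of the anchor cohort.

    Returns a DataFrame with ``patient_id`` and, when a *labeler*
    callable is supplied (chart review in real use, generator truth in
    tests), a binary ``label`` column. Reproducible under *seed*.
    """
    ids = sorted(anchor.patients)
    if not 1 <= n <= len(ids):
        raise PhenotypingError(
            f"gold-standard size {n} out of range 1..{len(ids)} (anchor cohort size)"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(ids), size=n, replace=False))
    sample = [ids[i] for i in chosen]
    out = pd.DataFrame({"patient_id": sample})
    if labeler is not None:
        out["label"] = [int(bool(labeler(pid))) for pid in sample]
    return out


LAMBDA_GRID = np.logspace(-4, 2, 50)
_ZERO_WEIGHT = 1e6  # adaptive weight assigned when the pilot coefficient is 0


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_adaptive_lasso(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    gamma: float = 1.0,
    n_folds: int = 5,
    lambda_grid: np.ndarray = LAMBDA_GRID,
) -> PhenotypeModel:
    """Two-stage adaptive LASSO penalized logistic regression.

    Stage 1 fits a ridge-penalized logistic regression on standardized
    features to get pilot coefficients ``b~`` (ridge rather than plain
    MLE so collinear feature blocks do not blow up). Stage 2 solves a
    weighted-L1 logistic fit with per-feature penalty ``1/|b~_j|**gamma``
    — implemented by rescaling column j by ``|b~_j|**gamma`` and applying
    a plain L1 penalty — with the penalty level chosen to minimize
    stratified K-fold cross-validated deviance (ties toward the sparser,
    larger penalty). Coefficients are returned on the original
    log-count scale.
    """
    features = list(X.columns)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != yv.shape[0]:
        raise PhenotypingError("X and y row counts differ")
    if Xv.shape[0] < 20:
        raise PhenotypingError(f"need >= 20 labeled rows, got {Xv.shape[0]}")
    if not np.all(np.isfinite(Xv)):
        raise PhenotypingError("feature matrix contains non-finite values")
    classes = np.unique(yv)
    if len(classes) < 2:
        raise PhenotypingError("labels contain a single class; need both cases and non-cases")

    # exact duplicate columns carry no extra information and would let the
    # ridge pilot split their weight arbitrarily; keep the first of each
    # identical group and give the clones zero coefficients
    keep: list[int] = []
    clone_of: dict[int, int] = {}
    for j in range(Xv.shape[1]):
        for k in keep:
            if np.array_equal(Xv[:, j], Xv[:, k]):
                clone_of[j] = k
                break
        else:
            keep.append(j)
    Xu = Xv[:, keep]

    mu = Xu.mean(axis=0)
    sd = Xu.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (Xu - mu) / sd_safe

    ridge = LogisticRegression(C=1.0, l1_ratio=0.0, solver="lbfgs", max_iter=5000, tol=1e-10)
    ridge.fit(Xs, yv)
    beta_pilot = ridge.coef_.ravel()
    w = np.where(
        (np.abs(beta_pilot) > 0) & (sd > 0),
        1.0 / np.maximum(np.abs(beta_pilot), 1.0 / _ZERO_WEIGHT) ** gamma,
        _ZERO_WEIGHT,
    )
    Xw = Xs / w  # L1 on the rescaled problem == weighted L1 on Xs

    n = len(yv)
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(folds.split(Xw, yv))
    cv_dev = np.zeros(len(lambda_grid))
    for train_idx, test_idx in splits:
        for k, lam in enumerate(lambda_grid):
            clf = LogisticRegression(
                C=1.0 / (lam * len(train_idx)), l1_ratio=1.0, solver="liblinear",
                max_iter=2000, tol=1e-8,
            )
            clf.fit(Xw[train_idx], yv[train_idx])
            p = clf.predict_proba(Xw[test_idx])[:, 1]
            cv_dev[k] += _deviance(yv[test_idx], p) / n_folds
    best = np.flatnonzero(cv_dev <= cv_dev.min() + 1e-12).max()  # sparser on ties
    lam = float(lambda_grid[best])

    final = LogisticRegression(
        C=1.0 / (lam * n), l1_ratio=1.0, solver="liblinear", max_iter=2000, tol=1e-8
    )
    final.fit(Xw, yv)
    u = final.coef_.ravel()
    beta_std = u / w
    beta_kept = beta_std / sd_safe
    intercept = float(final.intercept_[0] - np.sum(beta_kept * mu))
    beta_full = np.zeros(Xv.shape[1])
    w_full = np.full(Xv.shape[1], _ZERO_WEIGHT)
    for pos, j in enumerate(keep):
        beta_full[j] = beta_kept[pos]
        w_full[j] = w[pos]
    for j, k in clone_of.items():
        w_full[j] = w_full[k]
    return PhenotypeModel(
        features=features,
        coefficients={f: float(b) for f, b in zip(features, beta_full)},
        intercept=intercept,
        adaptive_weights={f: float(v) for f, v in zip(features, w_full)},
        penalty=lam,
    )


def predict_probability(model: PhenotypeModel, X: pd.DataFrame) -> pd.Series:
    """Logistic probabilities p = 1 / (1 + exp(-(b0 + X b))) per patient."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise PhenotypingError(f"feature matrix missing model columns {missing}")
    Xv = np.asarray(X[model.features], dtype=float)
    beta = np.array([model.coefficients[f] for f in model.features])
    z = model.intercept + Xv @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    return pd.Series(p, index=X.index, name="probability")


def choose_threshold(
    probs: np.ndarray, labels: np.ndarray, min_specificity: float
) -> float:
    """Smallest observed-probability threshold meeting a specificity floor.

    Classifying at threshold t means p >= t is a case. Among the
    observed probability values (so at least one patient is classified
    positive), returns the smallest t whose specificity is >=
    *min_specificity* — which, because sensitivity is non-increasing in
    t, also maximizes sensitivity subject to the constraint. If no
    threshold attains the floor, raises with the maximum achievable
    specificity.
    """
    if not 0 < min_specificity < 1:
        raise PhenotypingError("min_specificity must be in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    neg = probs[labels == 0]
    if len(neg) == 0:
        return float(np.min(probs))
    best_spec = 0.0
    for t in np.unique(probs):
        spec = float(np.mean(neg < t))
        best_spec = max(best_spec, spec)
        if spec >= min_specificity:
            return float(t)
    raise PhenotypingError(
        f"specificity floor {min_specificity} unattainable; "
        f"maximum achievable specificity is {best_spec:.4f}"
    )


def evaluate_phenotype(predictions: np.ndarray, truth: np.ndarray) -> dict:
    """Confusion-matrix metrics; undefined ratios are None, never 0."""
    pred = np.asarray(predictions).astype(bool)
    true = np.asarray(truth).astype(bool)
    if pred.shape != true.shape:
        raise PhenotypingError("prediction and truth vectors must align")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
    }


def apply_phenotype(
    store: Store,
    model: PhenotypeModel,
    definition: PhenotypeDefinition,
    threshold: float | None = None,
) -> tuple[PatientSet, Store]:
    """Score the anchor cohort and write derived-phenotype facts.

    Every anchor-cohort patient is scored; those with p >= threshold
    receive a ``PHENO:<name>`` fact (dated at the store's latest fact
    date) so the phenotype becomes queryable like any other concept.
    Returns the classified patient set and the augmented store.
    """
    t = threshold if threshold is not None else model.threshold
    if t is None:
        raise PhenotypingError("no classification threshold set")
    anchor = anchor_cohort(store, set(definition.anchor_codes))
    X = build_feature_matrix(store, definition, anchor)
    probs = predict_probability(model, X)
    positives = sorted(probs.index[probs >= t])
    as_of = store.facts["start_date"].max() if len(store.facts) else pd.Timestamp.today()
    facts = pd.DataFrame(
        {
            "patient_id": positives,
            "concept_code": f"PHENO:{definition.name}",
            "start_date": as_of,
            "value": [f"{probs[p]:.6f}" for p in positives],
            "encounter_id": "",
        }
    )
    new_store = update_store(store, new_facts=facts) if len(facts) else store
    return PatientSet(patients=frozenset(positives)), new_store


def train_phenotype(
    store: Store,
    definition: PhenotypeDefinition,
    gold: pd.DataFrame,
    min_specificity: float = 0.95,
    seed: int = 0,
) -> PhenotypeModel:
    """Fit the model on a labeled gold standard and set its threshold.

    *gold* carries ``patient_id`` and binary ``label`` columns (the
    chart-review outcome). The threshold is the smallest one reaching
    *min_specificity* on the gold set; training-set sensitivity, PPV and
    specificity at that threshold are stored in ``model.metrics``.
    """
    gold = gold.reset_index(drop=True)
    anchor = anchor_cohort(store, set(definition.anchor_codes))
    X_all = build_feature_matrix(store, definition, anchor)
    missing = [p for p in gold["patient_id"] if p not in X_all.index]
    if missing:
        raise PhenotypingError(f"gold-standard patients outside the anchor cohort: {missing[:5]}")
    X = X_all.loc[gold["patient_id"]]
    y = gold["label"].to_numpy(dtype=int)
    model = fit_adaptive_lasso(X, y, seed=seed)
    probs = predict_probability(model, X).to_numpy()
    model.threshold = choose_threshold(probs, y, min_specificity)
    pred = probs >= model.threshold
    model.metrics = {
        k: v for k, v in evaluate_phenotype(pred, y).items() if k in ("sensitivity", "ppv", "specificity")
    }
    model.metrics["min_specificity"] = min_specificity
    return model
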