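import numpy as np
import pandas as pd
import pytest

from biobank_portal.phenotyping import (
    PhenotypeDefinition,
    PhenotypeModel,
    PhenotypingError,
    anchor_cohort,
    apply_phenotype,
    build_feature_matrix,
    choose_threshold,
    evaluate_phenotype,
    extract_nlp_features,
    fit_adaptive_lasso,
    predict_probability,
    sample_gold_standard,
    train_phenotype,
)
from biobank_portal.query_engine import Panel, evaluate_panel
from biobank_portal.synthetic_data import default_definition


def _notes(texts):
    return pd.DataFrame(
        {
            "patient_id": [p for p, _ in texts],
            "note_id": [f"N{i}" for i in range(len(texts))],
            "note_date": pd.to_datetime(["2012-01-01"] * len(texts)),
            "text": [t for _, t in texts],
        }
    )


EROSIONS = (("erosions", ("erosions",)),)


class TestAnchorCohort:
    def test_patients_with_at_least_one_anchor_fact(self, tiny_store):
        assert anchor_cohort(tiny_store, {"ICD9:714.0"}).patients == {"P1", "P3"}

    def test_equals_single_occurrence_panel(self, cohort200):
        _, store, _ = cohort200
        a = anchor_cohort(store, {"ICD9:714.0"})
        b = evaluate_panel(store, Panel(terms=("ICD9:714.0",), min_occurs=1))
        assert a.patients == b.patients

    def test_empty_code_set_rejected(self, tiny_store):
        with pytest.raises(PhenotypingError):
            anchor_cohort(tiny_store, set())

    def test_anchor_count_exceeds_true_cases_among_anchored(self, cohort500):
        """Billing false positives inflate the ICD-alone cohort."""
        _, store, truth = cohort500
        anchor = anchor_cohort(store, {"ICD9:714.0"})
        true_anchored = {p for p in anchor.patients if truth.labels[p]}
        assert len(anchor) > len(true_anchored)


class TestExtractNlpFeatures:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("erosions on hand xray", 1),
            ("no erosions seen", 0),
            ("patient denies erosions", 0),
            ("negative for erosions", 0),
            ("imaging without erosions", 0),
            ("we ruled out erosions today", 0),
            ("EROSIONS at the MCP joints", 1),  # case-insensitive
            ("bone erosions and more erosions", 2),
            ("microerosions present", 0),  # whole-word only
        ],
    )
    def test_mention_counting_with_negation(self, text, expected):
        counts = extract_nlp_features(_notes([("P1", text)]), EROSIONS)
        assert counts.loc["P1", "erosions"] == expected

    def test_cue_outside_six_token_window_does_not_negate(self):
        text = "no acute distress was evident on detailed exam today erosions present"
        counts = extract_nlp_features(_notes([("P1", text)]), EROSIONS)
        assert counts.loc["P1", "erosions"] == 1

    def test_counts_sum_across_notes(self):
        notes = _notes([("P1", "erosions seen"), ("P1", "erosions again"), ("P2", "all clear")])
        counts = extract_nlp_features(notes, EROSIONS)
        assert counts.loc["P1", "erosions"] == 2
        assert counts.loc["P2", "erosions"] == 0

    def test_multiword_synonyms_match_token_sequences(self):
        concepts = (("erosions", ("erosive changes",)),)
        counts = extract_nlp_features(
            _notes([("P1", "subtle erosive changes at the wrist")]), concepts
        )
        assert counts.loc["P1", "erosions"] == 1

    def test_empty_synonym_rejected(self):
        with pytest.raises(PhenotypingError):
            extract_nlp_features(_notes([("P1", "x")]), (("c", ("",)),))

    def test_matches_generator_bookkeeping(self, cohort200):
        """Extracted counts == planted positives (negated mentions excluded)."""
        config, store, truth = cohort200
        defn = default_definition(config)
        counts = extract_nlp_features(store.notes, defn.nlp_concepts)
        for pid in store.patient_ids():
            got = int(counts.loc[pid, "erosions"]) if pid in counts.index else 0
            planted_pos, _planted_neg = truth.mention_counts[pid]["erosions"]
            assert got == planted_pos


class TestSampleGoldStandard:
    def _anchor(self, cohort):
        _, store, _ = cohort
        return anchor_cohort(store, {"ICD9:714.0"})

    def test_full_sample_is_whole_cohort(self, cohort200):
        anchor = self._anchor(cohort200)
        sample = sample_gold_standard(anchor, len(anchor), seed=1)
        assert set(sample["patient_id"]) == anchor.patients

    def test_reproducible_under_seed(self, cohort200):
        anchor = self._anchor(cohort200)
        a = sample_gold_standard(anchor, 10, seed=42)
        b = sample_gold_standard(anchor, 10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_sample_rejected(self, cohort200):
        anchor = self._anchor(cohort200)
        with pytest.raises(PhenotypingError):
            sample_gold_standard(anchor, len(anchor) + 1, seed=1)

    def test_inclusion_frequency_is_uniform(self, cohort500):
        """n=50 of ~500: per-patient inclusion rate near n/N over repeats."""
        from biobank_portal.query_engine import PatientSet

        anchor = PatientSet(frozenset(f"P{i:03d}" for i in range(500)))
        n_draws, n = 2_000, 50
        hits = {p: 0 for p in anchor.patients}
        for s in range(n_draws):
            for p in sample_gold_standard(anchor, n, seed=s)["patient_id"]:
                hits[p] += 1
        rate = n / 500
        se = np.sqrt(rate * (1 - rate) / n_draws)
        freqs = np.array(list(hits.values())) / n_draws
        assert abs(freqs.mean() - rate) < 3 * se
        assert (np.abs(freqs - rate) < 5 * se).mean() > 0.99

    def test_labeler_attaches_labels(self, cohort200):
        _, store, truth = cohort200
        anchor = anchor_cohort(store, {"ICD9:714.0"})
        sample = sample_gold_standard(anchor, 20, seed=3, labeler=truth.labeler)
        assert set(sample.columns) == {"patient_id", "label"}
        for row in sample.itertuples():
            assert row.label == int(truth.labels[row.patient_id])


def _simulate_xy(rng, n=400, p=10, beta=(1.5, -1.0)):
    X = rng.poisson(1.0, size=(n, p)).astype(float)
    Xl = np.log1p(X)
    eta = -0.5 + beta[0] * Xl[:, 0] + beta[1] * Xl[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(Xl, columns=[f"f{i}" for i in range(p)]), y


class TestFitAdaptiveLasso:
    def test_recovers_true_features_with_correct_signs(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = _simulate_xy(rng)
            if len(np.unique(y)) < 2:
                continue
            model = fit_adaptive_lasso(X, y, seed=seed)
            ok = model.coefficients["f0"] > 0 and model.coefficients["f1"] < 0
            hits += ok
        assert hits >= 9

    def test_null_selection_is_sparse(self):
        n_selected = []
        for seed in range(10):
            rng = np.random.default_rng(1_000 + seed)
            X = pd.DataFrame(
                np.log1p(rng.poisson(1.0, size=(400, 10)).astype(float)),
                columns=[f"f{i}" for i in range(10)],
            )
            y = rng.integers(0, 2, size=400)
            model = fit_adaptive_lasso(X, y, seed=seed)
            n_selected.append(len(model.selected_features))
        assert np.median(n_selected) <= 1

    def test_duplicate_column_leaves_probabilities_unchanged(self):
        rng = np.random.default_rng(5)
        X, y = _simulate_xy(rng)
        model = fit_adaptive_lasso(X, y, seed=5)
        p1 = predict_probability(model, X)
        X2 = X.copy()
        X2["f0_dup"] = X2["f0"]
        model2 = fit_adaptive_lasso(X2, y, seed=5)
        p2 = predict_probability(model2, X2)
        assert np.max(np.abs(p1.to_numpy() - p2.to_numpy())) < 1e-6

    def test_column_permutation_leaves_probabilities_unchanged(self):
        rng = np.random.default_rng(6)
        X, y = _simulate_xy(rng)
        model = fit_adaptive_lasso(X, y, seed=6)
        perm = list(reversed(X.columns))
        model_p = fit_adaptive_lasso(X[perm], y, seed=6)
        p1 = predict_probability(model, X)
        p2 = predict_probability(model_p, X[perm])
        assert np.max(np.abs(p1.to_numpy() - p2.to_numpy())) < 1e-6

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((30, 3)), columns=list("abc"))
        with pytest.raises(PhenotypingError, match="single class"):
            fit_adaptive_lasso(X, np.zeros(30), seed=0)

    def test_nonfinite_features_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((30, 3)), columns=list("abc"))
        X.iloc[0, 0] = np.inf
        y = np.array([0, 1] * 15)
        with pytest.raises(PhenotypingError, match="non-finite"):
            fit_adaptive_lasso(X, y, seed=0)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((10, 3)), columns=list("abc"))
        with pytest.raises(PhenotypingError, match="20"):
            fit_adaptive_lasso(X, np.array([0, 1] * 5), seed=0)


class TestPredictProbability:
    def _model(self, coefficients, intercept):
        return PhenotypeModel(
            features=list(coefficients),
            coefficients=coefficients,
            intercept=intercept,
            adaptive_weights={f: 1.0 for f in coefficients},
            penalty=0.1,
        )

    def test_all_zero_features_give_intercept_only(self):
        model = self._model({"a": 2.0}, intercept=-1.0)
        X = pd.DataFrame({"a": [0.0, 0.0]})
        p = predict_probability(model, X)
        assert np.allclose(p, 1 / (1 + np.exp(1.0)))

    def test_zero_everything_gives_half(self):
        model = self._model({"a": 0.0}, intercept=0.0)
        assert predict_probability(model, pd.DataFrame({"a": [3.0]}))[0] == 0.5

    def test_matches_hand_rolled_logistic(self):
        rng = np.random.default_rng(2)
        coeffs = {f"f{i}": float(c) for i, c in enumerate(rng.normal(size=4))}
        model = self._model(coeffs, intercept=0.3)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list(coeffs))
        p = predict_probability(model, X)
        for i in range(20):
            z = 0.3 + sum(coeffs[f] * X.iloc[i][f] for f in coeffs)
            assert p.iloc[i] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)

    def test_column_mismatch_rejected(self):
        model = self._model({"a": 1.0}, 0.0)
        with pytest.raises(PhenotypingError, match="missing"):
            predict_probability(model, pd.DataFrame({"b": [1.0]}))


class TestChooseThreshold:
    def test_separable_case_reaches_full_sensitivity(self):
        probs = np.array([0.9] * 5 + [0.1] * 20)
        labels = np.array([1] * 5 + [0] * 20)
        t = choose_threshold(probs, labels, 0.95)
        assert 0.1 < t <= 0.9
        assert (probs[labels == 1] >= t).all()

    def test_lower_floor_never_decreases_sensitivity(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 400)
        probs = np.clip(rng.normal(0.3 + 0.3 * labels, 0.2), 0.001, 0.999)
        last_sens = -1.0
        for floor in (0.95, 0.9, 0.8, 0.7, 0.6):
            t = choose_threshold(probs, labels, floor)
            sens = float(np.mean(probs[labels == 1] >= t))
            assert sens >= last_sens
            last_sens = sens

    def test_unattainable_floor_reports_maximum(self):
        probs = np.array([0.95, 0.6, 0.4, 0.2])
        labels = np.array([0, 1, 1, 0])  # top probability is a non-case
        with pytest.raises(PhenotypingError, match="unattainable"):
            choose_threshold(probs, labels, 0.999)


class TestEvaluatePhenotype:
    def test_perfect_predictions(self):
        truth = np.array([1, 0, 1, 1, 0])
        m = evaluate_phenotype(truth, truth)
        assert m["sensitivity"] == 1.0 and m["ppv"] == 1.0

    def test_direct_arithmetic(self):
        pred = np.array([1] * 10 + [0] * 3 + [0] * 5)
        true = np.array([1] * 9 + [0] + [1] * 3 + [0] * 5)
        m = evaluate_phenotype(pred, true)
        assert m["tp"] == 9 and m["fp"] == 1 and m["fn"] == 3
        assert m["sensitivity"] == 0.75
        assert m["ppv"] == 0.9

    def test_undefined_metrics_are_none(self):
        m = evaluate_phenotype(np.zeros(4), np.zeros(4))
        assert m["sensitivity"] is None and m["ppv"] is None
        assert m["specificity"] == 1.0

    def test_agrees_with_confusion_matrix_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pred = rng.integers(0, 2, 30).astype(bool)
            true = rng.integers(0, 2, 30).astype(bool)
            m = evaluate_phenotype(pred, true)
            tp = sum(1 for a, b in zip(pred, true) if a and b)
            fp = sum(1 for a, b in zip(pred, true) if a and not b)
            fn = sum(1 for a, b in zip(pred, true) if not a and b)
            assert m["tp"] == tp and m["fp"] == fp and m["fn"] == fn
            if tp + fp:
                assert m["ppv"] == tp / (tp + fp)


class TestPipeline:
    def test_apply_round_trips_into_query_engine(self, cohort200):
        config, store, truth = cohort200
        defn = default_definition(config)
        anchor = anchor_cohort(store, set(defn.anchor_codes))
        gold = sample_gold_standard(
            anchor, min(150, len(anchor)), seed=5, labeler=truth.labeler
        )
        model = train_phenotype(store, defn, gold, min_specificity=0.90, seed=5)
        classified, tagged = apply_phenotype(store, model, defn)
        hits = evaluate_panel(tagged, Panel(terms=(f"PHENO:{defn.name}",)))
        assert hits.patients == classified.patients

    def test_extreme_threshold_keeps_only_top_probabilities(self, cohort200):
        config, store, truth = cohort200
        defn = default_definition(config)
        anchor = anchor_cohort(store, set(defn.anchor_codes))
        gold = sample_gold_standard(
            anchor, min(150, len(anchor)), seed=5, labeler=truth.labeler
        )
        model = train_phenotype(store, defn, gold, min_specificity=0.90, seed=5)
        X = build_feature_matrix(store, defn, anchor)
        probs = predict_probability(model, X)
        top = probs.max()
        classified, _ = apply_phenotype(store, model, defn, threshold=top - 1e-9)
        assert classified.patients == set(probs.index[probs >= top - 1e-9])

    def test_model_round_trips_through_json(self, cohort200):
        config, store, truth = cohort200
        defn = default_definition(config)
        anchor = anchor_cohort(store, set(defn.anchor_codes))
        gold = sample_gold_standard(
            anchor, min(150, len(anchor)), seed=5, labeler=truth.labeler
        )
        model = train_phenotype(store, defn, gold, min_specificity=0.90, seed=5)
        restored = PhenotypeModel.from_json(model.to_json())
        assert restored.coefficients == model.coefficients
        assert restored.threshold == model.threshold

    def test_definition_round_trips_through_yaml(self):
        defn = PhenotypeDefinition(
            name="ra",
            anchor_codes=frozenset({"ICD9:714.0"}),
            coded_features=("ICD9:714.0", "MED:antiTNF"),
            nlp_concepts=(("erosions", ("erosions", "erosive changes")),),
        )
        assert PhenotypeDefinition.from_yaml(defn.to_yaml()) == defn
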