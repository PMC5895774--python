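import math

import numpy as np
import pytest

from steroidratio.cohort import ANALYTES, CohortTable, SteroidPanel, SubjectRecord, ValidationError
from steroidratio.classify import (
    ClassificationResult,
    PosteriorState,
    ProfileMatchClassifier,
    ReferenceDatabase,
    band_classify,
    classify,
    loo_classify,
    sequential_correction,
    similarity,
    update_correction,
)


def bayes_oracle(query, features, labels, k=3, priors=None, correction=None):
    """Explicit enumeration of neighbor similarities and Bayes weights."""
    classes = sorted(set(labels))
    priors = priors or {c: 1.0 / len(classes) for c in classes}
    correction = correction or {c: 1.0 for c in classes}
    sims = []
    for v in features:
        dot = sum(q * x for q, x in zip(query, v))
        nq = math.sqrt(sum(q * q for q in query))
        nv = math.sqrt(sum(x * x for x in v))
        sims.append((1.0 + dot / (nq * nv)) / 2.0)
    weights = {}
    for c in classes:
        s = sorted((sims[j] for j in range(len(labels)) if labels[j] == c), reverse=True)
        weights[c] = (sum(s[:k]) / min(k, len(s))) * priors[c] * correction[c]
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


class TestSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_map_to_half(self):
        # 2-D log-ratio vectors with zero dot product under (1+cos)/2
        assert similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_antiparallel_vectors_map_to_zero(self):
        assert similarity([1.0, 2.0], [-1.0, -2.0]) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert similarity(a, b) == pytest.approx(similarity(b, a))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            similarity([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            similarity([1.0, np.nan], [1.0, 2.0])


class TestClassify:
    def test_single_class_db_predicts_it_with_posterior_one(self):
        db = ReferenceDatabase(np.eye(3), np.array(["PCa"] * 3), np.array(["a", "b", "c"]))
        res = classify(np.array([1.0, 1.0, 1.0]), db)
        assert res.predicted == "PCa"
        assert res.posterior["PCa"] == pytest.approx(1.0)
        assert res.coefficient == pytest.approx(100.0)

    def test_symmetric_neighbors_tie_is_half_half(self):
        # query equidistant from one vector of each class
        feats = np.array([[1.0, 0.2], [0.2, 1.0]])
        db = ReferenceDatabase(feats, np.array(["X", "Y"]), np.array(["a", "b"]))
        res = classify(np.array([0.6, 0.6]), db, k=1)
        assert res.posterior["X"] == pytest.approx(0.5)
        assert res.posterior["Y"] == pytest.approx(0.5)
        # documented tie rule: class of the single most similar neighbor,
        # here exactly tied too, so lexicographic
        assert res.predicted == "X"

    def test_toy_db_matches_hand_bayes_calculation(self):
        feats = np.array([[1.0, 0.9], [0.9, 1.0], [-1.0, -1.0]])
        labels = np.array(["X", "X", "Y"])
        db = ReferenceDatabase(feats, labels, np.array(["a", "b", "c"]))
        query = np.array([1.0, 1.0])
        res = classify(query, db, k=3)
        expected = bayes_oracle(query, feats, labels, k=3)
        assert res.predicted == "X"
        for c in ("X", "Y"):
            assert res.posterior[c] == pytest.approx(expected[c], rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_bruteforce_oracle_on_small_dbs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        d = rng.integers(2, 6)
        feats = rng.normal(size=(n, d))
        labels = rng.choice(["PCa", "BPH", "HC"], size=n)
        db = ReferenceDatabase(feats, labels, np.array([f"s{i}" for i in range(n)]))
        query = rng.normal(size=d)
        res = classify(query, db, k=3)
        expected = bayes_oracle(query, feats, labels.tolist(), k=3)
        for c, p in expected.items():
            assert res.posterior[c] == pytest.approx(p, rel=1e-10)

    def test_posterior_sums_to_one(self):
        rng = np.random.default_rng(9)
        feats = rng.normal(size=(12, 6))
        labels = rng.choice(["PCa", "BPH", "HC"], size=12)
        db = ReferenceDatabase(feats, labels, np.array([f"s{i}" for i in range(12)]))
        for _ in range(5):
            res = classify(rng.normal(size=6), db)
            assert sum(res.posterior.values()) == pytest.approx(1.0)
            assert max(res.posterior, key=res.posterior.get) == res.predicted

    def test_identity_match_forbidden(self):
        db = ReferenceDatabase(np.eye(2), np.array(["X", "Y"]), np.array(["a", "b"]))
        with pytest.raises(ValidationError, match="identity"):
            classify(np.array([1.0, 0.0]), db, query_id="a")

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ReferenceDatabase(np.empty((0, 2)), np.array([]), np.array([]))


class TestCorrection:
    def make_state(self, corr):
        return PosteriorState({}, {}, 0.0, {}, dict(corr))

    def test_all_correct_stream_converges_to_one(self):
        state = self.make_state({"PCa": 1.8, "BPH": 0.6})
        for step in range(2000):
            state = update_correction(state, True, step)
        assert state.correction["PCa"] == pytest.approx(1.0, abs=1e-6)
        assert state.correction["BPH"] == pytest.approx(1.0, abs=1e-6)

    def test_corrections_stay_in_clip_range_over_10000_steps(self):
        rng = np.random.default_rng(42)
        state = self.make_state({"PCa": 1.0, "BPH": 1.0, "HC": 1.0})
        classes = ["PCa", "BPH", "HC"]
        for step in range(10_000):
            correct = bool(rng.random() < 0.5)
            t, p = rng.choice(classes, 2, replace=False)
            state = update_correction(
                state, correct, step,
                true_class=None if correct else t,
                predicted_class=None if correct else p,
            )
            assert all(0.5 <= v <= 2.0 for v in state.correction.values())

    def test_deterministic(self):
        s0 = self.make_state({"PCa": 1.2, "BPH": 0.9})
        a = update_correction(s0, False, 3, true_class="BPH", predicted_class="PCa")
        b = update_correction(s0, False, 3, true_class="BPH", predicted_class="PCa")
        assert a.correction == b.correction

    def test_wrong_outcome_boosts_underpredicted_class(self):
        s0 = self.make_state({"PCa": 1.0, "BPH": 1.0})
        s1 = update_correction(s0, False, 0, true_class="BPH", predicted_class="PCa")
        assert s1.correction["BPH"] > 1.0 > s1.correction["PCa"]

    def test_sequential_correction_runs_and_clips(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(9, 4))
        labels = np.array(["PCa", "BPH", "HC"] * 3)
        db = ReferenceDatabase(feats, labels, np.array([f"s{i}" for i in range(9)]))
        corr = sequential_correction(db, feats, labels, steps=200)
        assert set(corr) == {"PCa", "BPH", "HC"}
        assert all(0.5 <= v <= 2.0 for v in corr.values())


def cohort_from_rows(rows_by_class, analytes=ANALYTES):
    subjects = []
    for cls, rows in rows_by_class.items():
        for j, row in enumerate(rows):
            subjects.append(
                SubjectRecord(
                    id=f"{cls}{j}",
                    class_label=cls,
                    panel=SteroidPanel(dict(zip(analytes, row)), analytes=tuple(analytes)),
                )
            )
    return CohortTable(subjects)


class TestLeaveOneOut:
    def test_identical_vectors_per_class_are_perfectly_recovered(self):
        rng = np.random.default_rng(5)
        prototypes = {c: rng.uniform(0.5, 5.0, 10) for c in ("PCa", "BPH", "HC")}
        cohort = cohort_from_rows({c: [p] * 4 for c, p in prototypes.items()})
        results = loo_classify(cohort, mode="ratio")
        assert all(r.predicted == r.true_label for r in results)

    def test_coefficients_stay_on_1_100_scale(self, synthetic71):
        results = loo_classify(synthetic71, mode="ratio")
        assert all(1.0 <= r.coefficient <= 100.0 for r in results)

    def test_deterministic_under_repetition(self, synthetic71):
        a = loo_classify(synthetic71, mode="ratio")
        b = loo_classify(synthetic71, mode="ratio")
        assert [r.predicted for r in a] == [r.predicted for r in b]
        assert np.allclose([r.coefficient for r in a], [r.coefficient for r in b])

    def test_single_class_cohort_rejected(self):
        cohort = cohort_from_rows({"PCa": [np.ones(10) * (j + 1) for j in range(3)]})
        with pytest.raises(ValidationError, match="two classes"):
            loo_classify(cohort)

    def test_missing_panels_listed_in_error(self, table1):
        with pytest.raises(ValidationError, match="A0001"):
            loo_classify(table1)

    def test_ratio_mode_invariant_to_scaling_one_subject(self, synthetic71):
        base = loo_classify(synthetic71, mode="ratio")
        subjects = [
            SubjectRecord(id=s.id, class_label=s.class_label, psa=s.psa, panel=s.panel)
            for s in synthetic71
        ]
        target = subjects[0]
        scaled_panel = target.panel.replace_values(
            {a: target.panel[a] * 7.5 for a in ANALYTES}
        )
        subjects[0] = SubjectRecord(
            id=target.id, class_label=target.class_label, psa=target.psa, panel=scaled_panel
        )
        scaled = loo_classify(CohortTable(subjects), mode="ratio")
        assert [r.predicted for r in base] == [r.predicted for r in scaled]
        assert np.allclose(
            [r.coefficient for r in base], [r.coefficient for r in scaled]
        )

    def test_absolute_mode_sensitive_to_scaling_one_analyte(self):
        rng = np.random.default_rng(8)
        rows = {c: [rng.uniform(0.5, 5.0, 10) for _ in range(4)] for c in ("PCa", "HC")}
        cohort = cohort_from_rows(rows)
        base = loo_classify(cohort, mode="absolute")
        # quadruple one analyte of one subject: percent composition changes
        s0 = cohort.subjects[0]
        new_panel = s0.panel.replace_values({"testosterone": s0.panel["testosterone"] * 4})
        cohort.subjects[0] = SubjectRecord(
            id=s0.id, class_label=s0.class_label, panel=new_panel
        )
        perturbed = loo_classify(cohort, mode="absolute")
        assert not np.allclose(
            list(base[0].posterior.values()), list(perturbed[0].posterior.values())
        )


class TestBandClassify:
    @pytest.mark.parametrize(
        "coef, label", [(44.5, "PCa"), (22.6, "BPH"), (5.3, "HC"), (30.0, "PCa"), (10.0, "HC")]
    )
    def test_band_examples(self, coef, label):
        assert band_classify(coef) == label

    def test_reproduces_reported_ratio_column_for_all_71_subjects(self, table1):
        for s in table1:
            assert band_classify(s.reported_coefficient) == s.reported_classifications["ratio_rule"]

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            band_classify(50.0, bands=(30, 10))


class TestEstimatorInterface:
    def test_fit_predict_proba_shapes(self, synthetic71):
        labels, ids, rows = synthetic71.panel_matrix()
        X, y = np.asarray(rows), np.asarray(labels)
        clf = ProfileMatchClassifier().fit(X[10:], y[10:])
        proba = clf.predict_proba(X[:10])
        assert proba.shape == (10, 3)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(clf.predict(X[:10])) <= set(clf.classes_)
        coefs = clf.decision_coefficient(X[:10])
        assert np.all((coefs >= 1) & (coefs <= 100))

    def test_get_set_params_round_trip(self):
        clf = ProfileMatchClassifier(mode="absolute", k=5)
        params = clf.get_params()
        clone = ProfileMatchClassifier().set_params(**params)
        assert clone.get_params() == params

    def test_frequency_priors(self, synthetic71):
        labels, ids, rows = synthetic71.panel_matrix()
        X, y = np.asarray(rows), np.asarray(labels)
        clf = ProfileMatchClassifier(priors="frequency").fit(X, y)
        assert clf.db_.priors["HC"] == pytest.approx(31 / 71)
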