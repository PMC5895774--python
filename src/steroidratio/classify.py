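"""Profile-match classification of steroid panels.

The engine classifies a subject's panel by matching its feature vector
(log pairwise ratios, or percent concentrations for the absolute-match
model) against a labeled reference database. The per-class likelihood is
the mean cosine similarity of the query to its top-K nearest reference
vectors within the class; a Bayes posterior combines it with class
priors and a per-class multiplicative correction factor that is refined
over sequential classification rounds:

    P(A | B)  proportional to  P(B | A) * P(A) * C_A

where A ranges over the disease classes and B is the observed vector.
Cosine similarity is mapped onto [0, 1] by (1 + cos theta) / 2; in
ratio mode the cosine is taken on the elementwise natural log of the
ratio entries so that a ratio and its reciprocal contribute
symmetrically, and so that the score is invariant under global
rescaling of a panel.

Evaluation follows a leave-one-out protocol: every subject is scored
against a database built from all the other subjects, with the identity
match excluded. Each result carries a discriminating coefficient on a
normalized 1-100 scale (an affine map of the winning posterior margin);
a separate banding rule maps reported 1-100 coefficients to classes
(low band -> HC, high band -> PCa, middle -> BPH).

:class:`ProfileMatchClassifier` packages the engine as a scikit-learn
estimator (``fit``/``predict``/``predict_proba``) so it composes with
pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted
from sklearn.utils.multiclass import unique_labels

from .cohort import ANALYTES, CohortTable, ValidationError
from .vectorize import PercentVectorizer, RatioVectorizer

__all__ = [
    "similarity",
    "classify",
    "update_correction",
    "sequential_correction",
    "loo_classify",
    "band_classify",
    "ReferenceDatabase",
    "PosteriorState",
    "ClassificationResult",
    "ProfileMatchClassifier",
    "DEFAULT_BANDS",
]

#: Coefficient bands: <= low -> HC, >= high -> PCa, otherwise BPH.
#: Chosen inside the empty gaps of the reported coefficients
#: (8.0 -> 18.7 and 26.8 -> 38.7).
DEFAULT_BANDS: tuple[float, float] = (10.0, 30.0)


def similarity(a, b) -> float:
    """Angular similarity of two same-mode feature vectors, in [0, 1].

    ``(1 + cos theta) / 2`` of the two vectors; ratio-mode callers pass
    log-ratio vectors. Returns 1 iff the vectors are positively
    proportional.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in feature vectors")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm feature vector")
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return (1.0 + cos) / 2.0


@dataclass
class ReferenceDatabase:
    """Labeled feature vectors used for matching.

    ``features`` is an (n, d) matrix already in feature space (log
    ratios for ratio mode, percent concentrations for absolute mode);
    ``mode`` records which. Priors default to uniform over represented
    classes; ``correction`` is the per-class multiplicative factor.
    """

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    mode: str = "ratio"
    priors: dict[str, float] = field(default_factory=dict)
    correction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        if self.mode not in ("ratio", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.features) == 0:
            raise ValueError("empty reference database")
        self.classes = tuple(sorted(set(self.labels.tolist())))
        if not self.priors:
            self.priors = {c: 1.0 / len(self.classes) for c in self.classes}
        if not self.correction:
            self.correction = {c: 1.0 for c in self.classes}


@dataclass
class PosteriorState:
    """Bayes bookkeeping for one classification."""

    priors: dict[str, float]
    likelihoods: dict[str, float]
    evidence: float
    posterior: dict[str, float]
    correction: dict[str, float]


@dataclass
class ClassificationResult:
    subject_id: str
    predicted: str
    posterior: dict[str, float]
    coefficient: float
    neighbor_ids: tuple[str, ...] = ()
    true_label: str | None = None


def _class_likelihoods(sims: np.ndarray, labels: np.ndarray, classes, k: int):
    """Mean of the top-k similarities within each class."""
    out = {}
    top_ids = {}
    for c in classes:
        mask = labels == c
        s = np.sort(sims[mask])[::-1]
        kk = min(k, len(s))
        out[c] = float(s[:kk].mean())
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(sims[mask])[::-1][:kk]]
        top_ids[c] = order
    return out, top_ids


def classify(query, db: ReferenceDatabase, *, k: int = 3, query_id: str | None = None,
             bands: tuple[float, float] = DEFAULT_BANDS) -> ClassificationResult:
    """Classify one feature vector against a reference database.

    The posterior over classes is ``likelihood * prior * correction``
    normalized to sum to one; the discriminating coefficient is
    ``1 + 99 * (winning posterior - runner-up posterior)``. Ties are
    broken by the class of the single most similar neighbor, then
    lexicographically.
    """
    query = np.asarray(query, dtype=float)
    if query_id is not None and query_id in set(db.ids.tolist()):
        raise ValidationError(
            f"identity match forbidden: query id {query_id!r} present in database"
        )
    sims = np.array([similarity(query, v) for v in db.features])
    like, top_ids = _class_likelihoods(sims, db.labels, db.classes, k)
    weights = {
        c: like[c] * db.priors.get(c, 0.0) * db.correction.get(c, 1.0)
        for c in db.classes
    }
    total = sum(weights.values())
    if total <= 0:
        posterior = {c: 1.0 / len(db.classes) for c in db.classes}
    else:
        posterior = {c: w / total for c, w in weights.items()}

    best = max(posterior.values())
    tied = sorted(c for c, p in posterior.items() if p == best)
    if len(tied) > 1:
        nearest = db.labels[int(np.argmax(sims))]
        predicted = nearest if nearest in tied else tied[0]
    else:
        predicted = tied[0]

    ranked = sorted(posterior.values(), reverse=True)
    margin = ranked[0] - (ranked[1] if len(ranked) > 1 else 0.0)
    coefficient = 1.0 + 99.0 * margin
    neighbors = tuple(db.ids[top_ids[predicted]].tolist())
    return ClassificationResult(
        subject_id=query_id or "",
        predicted=str(predicted),
        posterior={str(c): p for c, p in posterior.items()},
        coefficient=float(coefficient),
        neighbor_ids=neighbors,
    )


def update_correction(state: PosteriorState, correct: bool, step: int, *,
                      true_class: str | None = None, predicted_class: str | None = None,
                      rate: float = 0.01, clip: tuple[float, float] = (0.5, 2.0)) -> PosteriorState:
    """One sequential refinement step of the per-class correction factor.

    On a wrong classification the under-predicted true class is boosted
    by ``(1 + rate)`` and the over-predicted class shrunk by the same
    factor; on a correct one every factor decays toward 1 (exponent
    ``1 - rate``). Factors stay inside ``clip``. Deterministic in its
    inputs; ``step`` is accepted for protocol bookkeeping.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    lo, hi = clip
    corr = dict(state.correction)
    if correct:
        corr = {c: v ** (1.0 - rate) for c, v in corr.items()}
    else:
        if true_class is None or predicted_class is None:
            raise ValueError("true_class and predicted_class required on a wrong outcome")
        corr[true_class] = corr.get(true_class, 1.0) * (1.0 + rate)
        corr[predicted_class] = corr.get(predicted_class, 1.0) / (1.0 + rate)
    corr = {c: float(np.clip(v, lo, hi)) for c, v in corr.items()}
    return replace(state, correction=corr)


def sequential_correction(db: ReferenceDatabase, queries, labels, *, k: int = 3,
                          steps: int = 10_000, rate: float = 0.01,
                          clip: tuple[float, float] = (0.5, 2.0)) -> dict[str, float]:
    """Run sequential classification rounds, refining the correction state.

    Cycles deterministically through ``queries`` (feature vectors) with
    known ``labels`` for ``steps`` rounds, updating the database's
    correction factors after each classification. Returns the final
    factors (also written back onto ``db``).
    """
    queries = np.asarray(queries, dtype=float)
    labels = np.asarray(labels)
    state = PosteriorState(db.priors, {}, 0.0, {}, dict(db.correction))
    for step in range(steps):
        j = step % len(queries)
        res = classify(queries[j], db, k=k)
        correct = res.predicted == labels[j]
        state = update_correction(
            state, correct, step,
            true_class=None if correct else str(labels[j]),
            predicted_class=None if correct else res.predicted,
            rate=rate, clip=clip,
        )
        db.correction = dict(state.correction)
    return dict(state.correction)


def band_classify(coefficient: float, bands: tuple[float, float] = DEFAULT_BANDS) -> str:
    """Map a 1-100 discriminating coefficient to a class by banding."""
    low, high = bands
    if not low < high:
        raise ValueError("bands must satisfy low < high")
    if coefficient >= high:
        return "PCa"
    if coefficient <= low:
        return "HC"
    return "BPH"


class ProfileMatchClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-profile Bayes classifier over steroid panels.

    Parameters
    ----------
    mode : {"ratio", "absolute"}, default "ratio"
        Feature encoding: log pairwise concentration ratios, or percent
        concentrations (the singular absolute-concentration match).
    k : int, default 3
        Neighbors per class whose similarities are averaged into the
        class likelihood.
    priors : "uniform", "frequency" or dict, default "uniform"
        Class priors. Uniform keeps the 31/20/20 class imbalance from
        dominating the posterior.
    correction_rate, correction_clip
        Parameters of the sequential correction update; corrections
        start at 1 and are only refined by :meth:`refine`.
    weight_normalize : bool, default True
        Divide cortisol by 10 and DHEAS by 100 before encoding.
    include_total : bool, default False
        In absolute mode, include the virtual total-concentration
        channel in the similarity (excluded by default: it encodes
        overall abundance, which would break the compositional intent).
    bands : (low, high), default (10, 30)
        Coefficient bands used by :func:`band_classify`.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in ``fit``.
    db_ : ReferenceDatabase of encoded training vectors.
    """

    def __init__(self, mode="ratio", k=3, priors="uniform", correction_rate=0.01,
                 correction_clip=(0.5, 2.0), weight_normalize=True,
                 include_total=False, analytes=ANALYTES, bands=DEFAULT_BANDS):
        self.mode = mode
        self.k = k
        self.priors = priors
        self.correction_rate = correction_rate
        self.correction_clip = correction_clip
        self.weight_normalize = weight_normalize
        self.include_total = include_total
        self.analytes = analytes
        self.bands = bands

    def _vectorizer(self):
        if self.mode == "ratio":
            return RatioVectorizer(
                analytes=self.analytes, weight_normalize=self.weight_normalize, log=True
            )
        if self.mode == "absolute":
            return PercentVectorizer(
                analytes=self.analytes,
                weight_normalize=self.weight_normalize,
                include_total=self.include_total,
            )
        raise ValueError(f"unknown mode {self.mode!r}")

    def _priors_dict(self, labels):
        classes = sorted(set(labels.tolist()))
        if self.priors == "uniform":
            return {c: 1.0 / len(classes) for c in classes}
        if self.priors == "frequency":
            n = len(labels)
            return {c: float((labels == c).sum()) / n for c in classes}
        return dict(self.priors)

    def fit(self, X, y, ids=None):
        X = check_array(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        self.classes_ = unique_labels(y)
        self.vectorizer_ = self._vectorizer().fit(X)
        features = self.vectorizer_.transform(X)
        if ids is None:
            ids = np.array([f"train{i}" for i in range(len(X))])
        self.db_ = ReferenceDatabase(
            features, y, np.asarray(ids), mode=self.mode, priors=self._priors_dict(y)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _results(self, X, ids=None):
        check_is_fitted(self, "db_")
        X = check_array(X)
        features = self.vectorizer_.transform(X)
        out = []
        for j, f in enumerate(features):
            qid = None if ids is None else ids[j]
            out.append(classify(f, self.db_, k=self.k, query_id=qid, bands=self.bands))
        return out

    def predict(self, X):
        return np.array([r.predicted for r in self._results(X)])

    def predict_proba(self, X):
        results = self._results(X)
        return np.array(
            [[r.posterior.get(str(c), 0.0) for c in self.classes_] for r in results]
        )

    def decision_coefficient(self, X):
        """Per-subject discriminating coefficient on the 1-100 scale."""
        return np.array([r.coefficient for r in self._results(X)])

    def refine(self, X, y, steps: int = 10_000):
        """Sequential correction-factor refinement on labeled panels."""
        check_is_fitted(self, "db_")
        X = check_array(X)
        features = self.vectorizer_.transform(X)
        sequential_correction(
            self.db_, features, np.asarray(y), k=self.k, steps=steps,
            rate=self.correction_rate, clip=self.correction_clip,
        )
        return self


def loo_classify(cohort: CohortTable, mode: str = "ratio", *, k: int = 3,
                 priors="uniform", weight_normalize: bool = True,
                 bands: tuple[float, float] = DEFAULT_BANDS) -> list[ClassificationResult]:
    """Leave-one-out classification of every subject in a cohort.

    For each subject a reference database is built from all the other
    subjects' panels and the held-out subject is classified against it.
    Requires a complete panel and class label for every subject, and at
    least two classes.
    """
    labels, ids, rows = cohort.panel_matrix()
    if any(lbl is None for lbl in labels):
        missing = [i for i, lbl in zip(ids, labels) if lbl is None]
        raise ValidationError(f"subjects without class labels: {missing}")
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    ids = np.asarray(ids)
    if len(set(y.tolist())) < 2:
        raise ValidationError("leave-one-out requires at least two classes")
    results = []
    for j in range(len(X)):
        keep = np.ones(len(X), dtype=bool)
        keep[j] = False
        clf = ProfileMatchClassifier(
            mode=mode, k=k, priors=priors, weight_normalize=weight_normalize, bands=bands
        ).fit(X[keep], y[keep], ids=ids[keep])
        res = clf._results(X[j : j + 1], ids=[ids[j]])[0]
        res.subject_id = str(ids[j])
        res.true_label = str(y[j])
        results.append(res)
    return results


def results_frame(results):
    """Results as a tidy table (one row per subject) for export."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "id": r.subject_id,
            "true_label": r.true_label,
            "predicted": r.predicted,
            "coefficient": r.coefficient,
        }
        for c, p in r.posterior.items():
            row[f"posterior_{c}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
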