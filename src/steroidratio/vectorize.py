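"""Feature encodings for steroid panels.

Two encodings are supported, mirroring the two matching models:

* the *percent concentration vector*: each analyte's share of the total
  panel concentration, ``Cn_i = (C_i / Cv) * 100`` with ``Cv = sum C_i``,
  keyed by the analyte's MRM parent m/z, plus a virtual m/z-1000 channel
  that carries the raw total ``Cv`` as a normalizing bookmark;
* the *combinatorial ratio vector*: every pairwise concentration ratio
  ``R(k, i) = C(k) / C(i)`` over the canonical analyte order (k < i),
  ``n(n-1)/2`` entries for ``n`` analytes.

Because cortisol and DHEAS circulate one to two orders of magnitude
above the other eight steroids, a weight normalization divides cortisol
by 10 and DHEAS by 100 before vector building, so that the similarity
function is not dominated by those two channels.

Thin scikit-learn transformers (:class:`RatioVectorizer`,
:class:`PercentVectorizer`) expose the same encodings on ``(n_subjects,
n_analytes)`` arrays for use in pipelines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import ANALYTES, SteroidPanel, TransitionTable, builtin_transitions

__all__ = [
    "DegenerateInputError",
    "ConcentrationVector",
    "RatioVector",
    "weight_normalize",
    "percent_vector",
    "ratio_vector",
    "ratio_count",
    "RatioVectorizer",
    "PercentVectorizer",
    "WEIGHT_DIVISORS",
]

#: Default weight-normalization divisors for the dominant analytes.
WEIGHT_DIVISORS: dict[str, float] = {"cortisol": 10.0, "DHEAS": 100.0}

#: m/z key of the virtual total-concentration channel.
VIRTUAL_MZ = 1000.0


class DegenerateInputError(ValueError):
    """Input panel cannot be encoded (all-zero, zero or missing entries)."""


def weight_normalize(panel: SteroidPanel, divisors=None) -> SteroidPanel:
    """Divide cortisol by 10 and DHEAS by 100; other analytes unchanged.

    Returns a new panel flagged ``normalized=True``; the input is not
    mutated. The operation compounds if applied twice, so callers should
    check the flag rather than re-applying.
    """
    divisors = divisors or WEIGHT_DIVISORS
    missing = [a for a in divisors if a not in panel.analytes]
    if missing:
        raise ValueError(f"panel lacks analytes required for normalization: {missing}")
    updates = {a: panel[a] / d for a, d in divisors.items()}
    return panel.replace_values(updates, normalized=True)


@dataclass(frozen=True)
class ConcentrationVector:
    """Percent-normalized concentration vector keyed by parent m/z.

    ``keys`` are ``(parent_mz, analyte)`` pairs in panel order — the
    analyte name disambiguates shared parent ions (DHEA and DHEAS both
    fragment from m/z 271.2). The virtual ``(1000.0, "__total__")``
    entry carries ``cv``, the raw summed concentration in ng/mL; the
    percent entries over the real analytes sum to 100.
    """

    keys: tuple[tuple[float, str], ...]
    cn: np.ndarray
    cv: float

    def __len__(self) -> int:
        return len(self.keys)

    def percent(self, analyte: str) -> float:
        for (mz, name), value in zip(self.keys, self.cn):
            if name == analyte:
                return float(value)
        raise KeyError(analyte)

    def values_without_total(self) -> np.ndarray:
        return np.array(
            [v for (mz, name), v in zip(self.keys, self.cn) if name != "__total__"]
        )


def percent_vector(
    panel: SteroidPanel, transitions: TransitionTable | None = None
) -> ConcentrationVector:
    """Encode a panel as percent-of-total entries plus the virtual channel."""
    values = np.asarray(panel.values(), dtype=float)
    if np.any(np.isnan(values)):
        raise DegenerateInputError("panel contains missing concentrations")
    cv = float(values.sum())
    if cv <= 0:
        raise DegenerateInputError("all-zero panel cannot be percent-normalized")
    if transitions is None and set(panel.analytes) <= set(ANALYTES):
        transitions = builtin_transitions()
    keys = []
    for a in panel.analytes:
        mz = transitions.parent_mz(a) if transitions is not None else float("nan")
        keys.append((mz, a))
    keys.append((VIRTUAL_MZ, "__total__"))
    cn = np.append(values / cv * 100.0, cv)
    return ConcentrationVector(tuple(keys), cn, cv)


@dataclass(frozen=True)
class RatioVector:
    """All pairwise concentration ratios of a panel.

    ``pairs[j] = (analyte_k, analyte_i)`` with k < i in canonical order
    and ``values[j] = C(k) / C(i)``; ``n`` analytes give ``n(n-1)/2``
    entries. Invariant under global rescaling of the panel.
    """

    pairs: tuple[tuple[str, str], ...]
    values: np.ndarray
    n: int

    def __len__(self) -> int:
        return len(self.pairs)

    def ratio(self, numerator: str, denominator: str) -> float:
        for (k, i), v in zip(self.pairs, self.values):
            if (k, i) == (numerator, denominator):
                return float(v)
            if (k, i) == (denominator, numerator):
                return 1.0 / float(v)
        raise KeyError((numerator, denominator))


def ratio_vector(panel: SteroidPanel, apply_weight_normalization: bool = True) -> RatioVector:
    """Encode a panel as its combinatorial pairwise ratio vector.

    With ``apply_weight_normalization`` (default) the cortisol/10 and
    DHEAS/100 reweighting is applied first unless the panel is already
    flagged normalized.
    """
    if apply_weight_normalization and not panel.normalized:
        if all(a in panel.analytes for a in WEIGHT_DIVISORS):
            panel = weight_normalize(panel)
    names = panel.analytes
    values = np.asarray(panel.values(), dtype=float)
    bad = [names[j] for j in range(len(names)) if not values[j] > 0]
    if bad:
        raise DegenerateInputError(f"zero or missing concentration for analytes: {bad}")
    pairs = []
    ratios = []
    for k, i in itertools.combinations(range(len(names)), 2):
        pairs.append((names[k], names[i]))
        ratios.append(values[k] / values[i])
    return RatioVector(tuple(pairs), np.asarray(ratios), n=len(names))


def ratio_count(n: int) -> int:
    """Number of pairwise ratios for ``n`` analytes: sum_{k=1}^{n-1}(n-k)."""
    if n < 1:
        raise ValueError(f"analyte count must be >= 1, got {n}")
    return sum(n - k for k in range(1, n))


def export_vector(vector, path, sep: str = ",") -> None:
    """Write a feature vector as delimited text, one (key, value) row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"key{sep}value\n")
        if isinstance(vector, RatioVector):
            for (k, i), v in zip(vector.pairs, vector.values):
                fh.write(f"{k}/{i}{sep}{float(v)!r}\n")
        elif isinstance(vector, ConcentrationVector):
            for (mz, name), v in zip(vector.keys, vector.cn):
                fh.write(f"{mz}:{name}{sep}{float(v)!r}\n")
        else:
            raise TypeError(f"cannot export {type(vector).__name__}")


def _weight_divisor_row(analytes) -> np.ndarray:
    return np.array([WEIGHT_DIVISORS.get(a, 1.0) for a in analytes], dtype=float)


class RatioVectorizer(TransformerMixin, BaseEstimator):
    """Transform (n_subjects, n_analytes) concentrations to log pairwise ratios.

    Parameters
    ----------
    analytes : sequence of str, default canonical ten-steroid panel
        Column names of the input matrix, in order.
    weight_normalize : bool, default True
        Apply the cortisol/10, DHEAS/100 reweighting before forming
        ratios (no-op for analytes absent from the panel).
    log : bool, default True
        Return natural-log ratios, making a ratio and its reciprocal
        symmetric contributors to downstream cosine similarity.
    """

    def __init__(self, analytes=ANALYTES, weight_normalize=True, log=True):
        self.analytes = analytes
        self.weight_normalize = weight_normalize
        self.log = log

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != len(self.analytes):
            raise ValueError(
                f"expected {len(self.analytes)} analyte columns, got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        self.pairs_ = tuple(itertools.combinations(range(len(self.analytes)), 2))
        return self

    def transform(self, X):
        check_is_fitted(self, "pairs_")
        X = check_array(X)
        if self.weight_normalize:
            X = X / _weight_divisor_row(self.analytes)
        if np.any(X <= 0):
            raise DegenerateInputError("ratio encoding requires strictly positive concentrations")
        k = [p[0] for p in self.pairs_]
        i = [p[1] for p in self.pairs_]
        R = X[:, k] / X[:, i]
        return np.log(R) if self.log else R

    def get_feature_names_out(self, input_features=None):
        names = list(self.analytes)
        return np.array([f"{names[k]}/{names[i]}" for k, i in self.pairs_])


class PercentVectorizer(TransformerMixin, BaseEstimator):
    """Transform (n_subjects, n_analytes) concentrations to percent-of-total.

    Optionally appends the virtual total-concentration channel as a last
    column (``include_total=True``); by default only the compositional
    percentages are returned, which is what the absolute-match
    similarity uses.
    """

    def __init__(self, analytes=ANALYTES, weight_normalize=True, include_total=False):
        self.analytes = analytes
        self.weight_normalize = weight_normalize
        self.include_total = include_total

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != len(self.analytes):
            raise ValueError(
                f"expected {len(self.analytes)} analyte columns, got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if self.weight_normalize:
            X = X / _weight_divisor_row(self.analytes)
        cv = X.sum(axis=1, keepdims=True)
        if np.any(cv <= 0):
            raise DegenerateInputError("all-zero panel cannot be percent-normalized")
        P = X / cv * 100.0
        if self.include_total:
            P = np.hstack([P, cv])
        return P

    def get_feature_names_out(self, input_features=None):
        names = [f"pct:{a}" for a in self.analytes]
        if self.include_total:
            names.append("total")
        return np.array(names)
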