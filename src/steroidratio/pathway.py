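"""Steroidogenesis pathway graph and enzyme attribution.

Steroids are synthesized from cholesterol along a branched enzymatic
pathway (P450scc, 3beta-HSD, P450C17/CYP17A1, 21-hydroxylase,
11beta-hydroxylase, aldosterone synthase, 17beta-HSD, sulfotransferase,
5alpha-reductase). A class-discriminating concentration ratio between
two steroids therefore points at the enzymes on the pathway segment
connecting them — e.g. the progesterone / 17-OH-progesterone ratio
implicates P450C17.

The graph ships as an editable tab-separated edge list (substrate,
product, enzyme) and is held as a :class:`networkx.DiGraph` with the
enzyme name on each edge.

Ratio pairs are ranked by a centroid-Chebyshev separation score: for
each analyte pair, the maximum absolute difference between class
centroids of the log ratio, affinely rescaled per cohort onto the 1-100
relational-coefficient scale. This is a heuristic attribution aid, not
a statistical inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .cohort import ANALYTES, CohortTable, ValidationError
from .vectorize import RatioVectorizer

__all__ = [
    "load_pathway",
    "default_pathway",
    "enzymes_for_pair",
    "rank_ratio_separation",
    "select_discriminative",
    "DiscriminativeRatio",
]


def load_pathway(path_or_lines) -> nx.DiGraph:
    """Load a pathway edge list: substrate <TAB> product <TAB> enzyme."""
    if isinstance(path_or_lines, (list, tuple)):
        lines = path_or_lines
    else:
        with open(path_or_lines, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    g = nx.DiGraph()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"malformed pathway edge line: {line!r}")
        substrate, product, enzyme = (p.strip() for p in parts)
        if not enzyme:
            raise ValidationError(f"edge {substrate}->{product} lacks an enzyme label")
        g.add_edge(substrate, product, enzyme=enzyme)
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("pathway graph must be acyclic")
    return g


def default_pathway() -> nx.DiGraph:
    """The packaged steroidogenesis graph (covers all ten panel analytes)."""
    text = resources.files("steroidratio.data").joinpath("steroidogenesis.tsv").read_text(
        encoding="utf-8"
    )
    return load_pathway(text.splitlines())


def enzymes_for_pair(pair, graph: nx.DiGraph) -> list[str]:
    """Enzymes on the shortest directed path between two steroids.

    Tries both orientations; returns the edge enzyme labels along the
    shorter existing path, or an empty list when the steroids are on
    unconnected branches.
    """
    a, b = pair
    for node in (a, b):
        if node not in graph:
            raise KeyError(node)
    paths = []
    for u, v in ((a, b), (b, a)):
        try:
            paths.append(nx.shortest_path(graph, u, v))
        except nx.NetworkXNoPath:
            pass
    if not paths:
        return []
    path = min(paths, key=len)
    return [graph.edges[x, y]["enzyme"] for x, y in zip(path, path[1:])]


@dataclass(frozen=True)
class DiscriminativeRatio:
    """A class-separating analyte ratio with its enzyme attribution."""

    pair: tuple[str, str]
    coefficient: float
    classes_separated: tuple[str, str]
    enzymes: tuple[str, ...]


def _log_ratio_matrix(cohort: CohortTable):
    labels, ids, rows = cohort.panel_matrix()
    if any(lbl is None for lbl in labels):
        raise ValidationError("all subjects need class labels for separation ranking")
    X = np.asarray(rows, dtype=float)
    analytes = cohort.subjects[0].panel.analytes
    vec = RatioVectorizer(analytes=analytes, weight_normalize=False, log=True).fit(X)
    return vec, vec.transform(X), np.asarray(labels), analytes


def rank_ratio_separation(cohort: CohortTable) -> dict[tuple[str, str], float]:
    """Score every analyte pair's between-class separation on [1, 100].

    The raw score of a pair is the Chebyshev distance between class
    centroids restricted to that pair's log ratio (the largest absolute
    centroid difference over all class pairings); raw scores are then
    affinely rescaled per cohort so the least separating pair maps to 1
    and the most separating to 100. Scale-invariant in each subject's
    panel and fully deterministic.
    """
    vec, L, labels, analytes = _log_ratio_matrix(cohort)
    classes = sorted(set(labels.tolist()))
    centroids = {c: L[labels == c].mean(axis=0) for c in classes}
    raw = np.zeros(L.shape[1])
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            raw = np.maximum(raw, np.abs(centroids[ci] - centroids[cj]))
    span = raw.max() - raw.min()
    if span == 0:
        scaled = np.ones_like(raw)
    else:
        scaled = 1.0 + 99.0 * (raw - raw.min()) / span
    pairs = [(analytes[k], analytes[i]) for k, i in vec.pairs_]
    return dict(zip(pairs, scaled.tolist()))


def _best_separated_classes(cohort: CohortTable, pair) -> tuple[str, str]:
    vec, L, labels, analytes = _log_ratio_matrix(cohort)
    pairs = [(analytes[k], analytes[i]) for k, i in vec.pairs_]
    j = pairs.index(tuple(pair))
    classes = sorted(set(labels.tolist()))
    best, best_d = (classes[0], classes[0]), -1.0
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            d = abs(L[labels == ci, j].mean() - L[labels == cj, j].mean())
            if d > best_d:
                best, best_d = (ci, cj), d
    return best


def select_discriminative(cohort: CohortTable, threshold: float = 40.0,
                          graph: nx.DiGraph | None = None) -> list[DiscriminativeRatio]:
    """Pairs whose relational coefficient exceeds ``threshold``, ranked.

    Each selected pair carries the enzymes on the pathway segment
    between its two steroids (empty when the branches are unconnected).
    """
    if graph is None:
        graph = default_pathway()
    scores = rank_ratio_separation(cohort)
    selected = [(pair, s) for pair, s in scores.items() if s > threshold]
    selected.sort(key=lambda t: -t[1])
    out = []
    for pair, s in selected:
        enzymes = tuple(enzymes_for_pair(pair, graph)) if all(p in graph for p in pair) else ()
        out.append(
            DiscriminativeRatio(
                pair=pair,
                coefficient=float(s),
                classes_separated=_best_separated_classes(cohort, pair),
                enzymes=enzymes,
            )
        )
    return out
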