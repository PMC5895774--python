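"""Synthetic cohort generator.

Generates full ten-steroid serum panels plus PSA for the three study
classes (PCa, BPH, HC) with the statistical structure the analysis
assumes: log-normal concentration marginals, class-specific median
shifts, optional enzyme-level perturbations propagated along the
steroidogenesis graph, and log-normal PSA per class. Default class
sizes are 20 / 20 / 31.

The defaults encode the qualitative anchors of the study cohort, chosen
once and documented in the methods note:

* DHEAS and cortisol circulate one to two orders of magnitude above the
  other eight steroids (both can exceed 1,000 ng/mL);
* most steroids — androgens in particular — are lower in PCa subjects
  than in BPH or controls;
* PSA medians bracket the clinical table's ranges (controls ~1 ng/mL,
  BPH ~6, PCa ~10 with a heavy tail);
* BPH carries a distinct mild mineralocorticoid-branch shift so the
  three classes are not collinear.

All randomness flows from a single mandatory seed; per-class substreams
are spawned deterministically, so equal seeds give byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .cohort import ANALYTES, CohortTable, SteroidPanel, SubjectRecord
from .pathway import default_pathway

__all__ = ["GeneratorConfig", "default_config", "simulate_cohort", "perturb_enzyme"]

#: Baseline (HC) median concentrations, ng/mL.
BASELINE_MEDIANS: dict[str, float] = {
    "aldosterone": 0.10,
    "corticosterone": 4.0,
    "cortisol": 120.0,
    "11-deoxycortisol": 0.30,
    "androstenedione": 1.0,
    "testosterone": 4.5,
    "DHEA": 3.0,
    "DHEAS": 1200.0,
    "17-OH-progesterone": 1.2,
    "progesterone": 0.15,
}

#: Between-subject log-sd per analyte (dominant channels are noisier).
BASELINE_LOG_SD: dict[str, float] = {
    **{a: 0.35 for a in ANALYTES},
    "cortisol": 0.5,
    "DHEAS": 0.5,
    "aldosterone": 0.4,
}

#: Class-specific median multipliers (HC is the baseline).
CLASS_MULTIPLIERS: dict[str, dict[str, float]] = {
    "HC": {},
    "PCa": {
        "testosterone": 0.6,
        "androstenedione": 0.7,
        "DHEA": 0.7,
        "DHEAS": 0.6,
        "17-OH-progesterone": 0.9,
        "progesterone": 1.2,
        "aldosterone": 0.9,
        "corticosterone": 0.9,
        "11-deoxycortisol": 0.9,
    },
    "BPH": {
        "testosterone": 0.6,
        "DHEA": 0.75,
        "DHEAS": 0.8,
        "androstenedione": 0.75,
        "corticosterone": 1.8,
        "aldosterone": 1.8,
        "11-deoxycortisol": 1.6,
    },
}

#: Class-specific enzyme perturbations applied on the pathway graph
#: (PCa carries a partial P450C17 deficit, depressing the androgen arm).
CLASS_ENZYME_PERTURBATIONS: dict[str, dict[str, float]] = {
    "HC": {},
    "PCa": {"P450C17": 0.75},
    "BPH": {},
}

#: PSA log-normal parameters per class: (median ng/mL, log-sd).
PSA_PARAMS: dict[str, tuple[float, float]] = {
    "HC": (1.0, 0.7),
    "BPH": (6.3, 0.5),
    "PCa": (10.0, 1.0),
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator.

    ``correlation`` optionally supplies a common between-analyte
    correlation matrix for the log concentrations (must be positive
    semi-definite); by default analytes vary independently on the log
    scale. ``seed`` is mandatory.
    """

    seed: int
    class_sizes: dict[str, int] = field(
        default_factory=lambda: {"PCa": 20, "BPH": 20, "HC": 31}
    )
    analytes: tuple[str, ...] = ANALYTES
    baseline_medians: dict[str, float] = field(default_factory=lambda: dict(BASELINE_MEDIANS))
    log_sd: dict[str, float] = field(default_factory=lambda: dict(BASELINE_LOG_SD))
    class_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in CLASS_MULTIPLIERS.items()}
    )
    enzyme_perturbations: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in CLASS_ENZYME_PERTURBATIONS.items()}
    )
    psa_params: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(PSA_PARAMS))
    correlation: np.ndarray | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for c, n in self.class_sizes.items():
            if n < 0:
                raise ValueError(f"negative class size for {c}")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(self.analytes), len(self.analytes)):
                raise ValueError("correlation matrix has wrong shape")
            try:
                np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
            except np.linalg.LinAlgError as exc:
                raise ValueError("correlation matrix is not positive semi-definite") from exc
            self.correlation = C


def default_config(seed: int) -> GeneratorConfig:
    """The study-condition defaults with the given seed."""
    return GeneratorConfig(seed=seed)


def perturb_enzyme(panel: SteroidPanel, graph: nx.DiGraph, enzyme: str,
                   factor: float) -> SteroidPanel:
    """Apply a mass-action caricature of an enzyme activity change.

    All steroids downstream of the enzyme's edges are multiplied by
    ``factor``; the enzyme's substrates — and their descendants along
    branches that bypass the enzyme — are divided by it (substrate
    accumulates when the enzyme is deficient and drains the alternative
    branches when overactive). Analytes absent from the graph are
    unchanged. ``factor=1`` is the identity.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    edges = [(u, v) for u, v, d in graph.edges(data=True) if d.get("enzyme") == enzyme]
    if not edges:
        raise KeyError(enzyme)
    products = {v for _, v in edges}
    substrates = {u for u, _ in edges}
    down: set[str] = set(products)
    for p in products:
        down |= nx.descendants(graph, p)
    up: set[str] = set(substrates) - down
    for s in substrates:
        up |= nx.descendants(graph, s) - down - products
    up -= down
    updates = {}
    for a in panel.analytes:
        if a in down:
            updates[a] = panel[a] * factor
        elif a in up:
            updates[a] = panel[a] / factor
    return panel.replace_values(updates)


def _class_stream_order(config: GeneratorConfig):
    # Deterministic class order: canonical labels first, then extras sorted.
    canonical = [c for c in ("PCa", "BPH", "HC") if c in config.class_sizes]
    extras = sorted(set(config.class_sizes) - set(canonical))
    return canonical + extras


def simulate_cohort(config: GeneratorConfig, graph: nx.DiGraph | None = None) -> CohortTable:
    """Draw a synthetic cohort under the configured study conditions."""
    if graph is None:
        graph = default_pathway()
    classes = _class_stream_order(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(classes))
    analytes = config.analytes
    n_a = len(analytes)
    sd = np.array([config.log_sd[a] for a in analytes])
    chol = None
    if config.correlation is not None:
        chol = np.linalg.cholesky(config.correlation + 1e-12 * np.eye(n_a))

    subjects = []
    for cls, ss in zip(classes, streams):
        rng = np.random.default_rng(ss)
        mult = config.class_multipliers.get(cls, {})
        mu = np.array(
            [np.log(config.baseline_medians[a] * mult.get(a, 1.0)) for a in analytes]
        )
        psa_median, psa_sd = config.psa_params[cls]
        for j in range(config.class_sizes[cls]):
            z = rng.standard_normal(n_a)
            if chol is not None:
                z = chol @ z
            conc = np.exp(mu + sd * z)
            panel = SteroidPanel(dict(zip(analytes, conc)), analytes=analytes)
            for enzyme, factor in config.enzyme_perturbations.get(cls, {}).items():
                panel = perturb_enzyme(panel, graph, enzyme, factor)
            psa = float(np.exp(np.log(psa_median) + psa_sd * rng.standard_normal()))
            subjects.append(
                SubjectRecord(
                    id=f"{cls}{j + 1:04d}",
                    class_label=cls,
                    age=None,
                    psa=psa,
                    panel=panel,
                )
            )
    return CohortTable(subjects, provenance=f"synthetic cohort (seed={config.seed})")
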