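"""Synthetic cohorts with planted structure for pipeline validation.

Every downstream stage of the prognostic-index pipeline is exercised
against data whose truth is known by construction:

* a tumour/normal expression cohort with planted up/down differential
  genes on a log2-normal abundance scale (FPKM-like),
* a weighted interaction network in which a planted module is densely
  wired to designated seed genes,
* proportional-hazards survival times driven by a planted gene subset
  (inverse-transform exponential simulation with independent censoring),
* a patient clinical table with a planted marker-covariate odds ratio.

All randomness flows from one explicit integer seed per spec object; no
global random state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "NetworkSpec",
    "SurvivalSpec",
    "CohortData",
    "generate_cohort",
    "generate_network",
    "generate_survival",
    "generate_clinical_table",
    "planted_prognostic_bundle",
]


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect sizes of a tumour/normal expression cohort.

    A ``de_fraction`` of genes is shifted by ``+lfc_effect`` (first half)
    or ``-lfc_effect`` (second half) in tumour samples, on the log2 scale.
    """

    n_genes: int = 200
    n_tumour: int = 50
    n_normal: int = 50
    de_fraction: float = 0.1
    lfc_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumour, self.n_normal) < 1:
            raise ValueError("gene and sample counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Random weighted network with a planted seed-adjacent module."""

    n_nodes: int
    module_genes: tuple[str, ...]
    seed_genes: tuple[str, ...]
    within_module_edge_prob: float = 0.4
    background_edge_prob: float = 0.02
    weight_range: tuple[float, float] = (0.4, 1.0)
    seed: int = 0
    node_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for p in (self.within_module_edge_prob, self.background_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability outside [0, 1]: {p}")
        if self.within_module_edge_prob <= self.background_edge_prob:
            raise ValueError("within-module density must exceed background")
        lo, hi = self.weight_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("weight_range must lie in (0, 1]")


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards generator: T = -log(U) / (rate * exp(x'beta))."""

    beta_true: dict[str, float]
    baseline_rate: float = 0.2
    censor_rate: float = 0.1
    max_follow_up: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")


@dataclass(frozen=True)
class CohortData:
    expression: pd.DataFrame = field(repr=False)  # genes x samples, FPKM-like
    annotation: pd.DataFrame = field(repr=False)  # sample, group
    de_truth: pd.DataFrame = field(repr=False)  # gene, planted, true_lfc


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Log2-normal expression with planted differential genes.

    Gene baselines are drawn once per gene; tumour samples of planted
    genes get a ±lfc_effect shift on the log2 scale, giving a closed-form
    true log2 fold change.  Output abundances are 2**log2-value, hence
    strictly positive and heavy-tailed like FPKM.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    samples = [f"T{i:03d}" for i in range(spec.n_tumour)] + [
        f"N{i:03d}" for i in range(spec.n_normal)
    ]
    group = ["tumour"] * spec.n_tumour + ["normal"] * spec.n_normal

    n_de = int(round(spec.de_fraction * spec.n_genes))
    n_up = n_de // 2 + n_de % 2
    true_lfc = np.zeros(spec.n_genes)
    true_lfc[:n_up] = spec.lfc_effect
    true_lfc[n_up:n_de] = -spec.lfc_effect

    baseline = rng.uniform(3.0, 8.0, size=spec.n_genes)
    log2expr = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, len(samples))
    )
    log2expr[:, : spec.n_tumour] += true_lfc[:, None]

    expr = pd.DataFrame(2.0**log2expr, index=genes, columns=samples)
    annotation = pd.DataFrame({"sample": samples, "group": group}).set_index("sample")
    # labels record the *designated* genes, even at lfc_effect=0
    planted = np.array(["null"] * spec.n_genes, dtype=object)
    planted[:n_up] = "up"
    planted[n_up:n_de] = "down"
    de_truth = pd.DataFrame({"gene": genes, "planted": planted, "true_lfc": true_lfc})
    return CohortData(expression=expr, annotation=annotation, de_truth=de_truth)


def generate_network(spec: NetworkSpec) -> nx.Graph:
    """Erdos-Renyi background with a dense planted module around the seeds.

    Node pairs inside module ∪ seeds connect with the within-module
    probability, all others with the background probability; weights are
    uniform in ``weight_range``.  No self-loops.
    """
    if spec.node_names is not None:
        nodes = list(spec.node_names)
        if len(nodes) != spec.n_nodes:
            raise ValueError("node_names length must equal n_nodes")
    else:
        named = list(dict.fromkeys([*spec.seed_genes, *spec.module_genes]))
        if len(named) > spec.n_nodes:
            raise ValueError("more named genes than n_nodes")
        nodes = named + [f"N{i:04d}" for i in range(spec.n_nodes - len(named))]
    missing = (set(spec.seed_genes) | set(spec.module_genes)) - set(nodes)
    if missing:
        raise ValueError(f"module/seed genes absent from node set: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    dense = set(spec.module_genes) | set(spec.seed_genes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    lo, hi = spec.weight_range
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = (
                spec.within_module_edge_prob
                if u in dense and v in dense
                else spec.background_edge_prob
            )
            if rng.random() < p:
                g.add_edge(u, v, weight=float(rng.uniform(lo, hi)))
    return g


def hazard_covariates(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scored log2(x+1) — the scale the survival generator
    feeds into the linear hazard predictor."""
    x = np.log2(expr.to_numpy(dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)


def generate_survival(expr: pd.DataFrame, spec: SurvivalSpec) -> pd.DataFrame:
    """Inverse-transform proportional-hazards times for each sample of ``expr``.

    The linear predictor uses z-scored log2(x+1) covariates so that
    ``beta_true`` is in interpretable per-SD log-hazard units.  Censoring
    is an independent exponential clock plus administrative truncation at
    ``max_follow_up``.
    """
    missing = [g for g in spec.beta_true if g not in expr.index]
    if missing:
        raise ValueError(f"beta_true genes absent from expression: {missing}")
    rng = np.random.default_rng(spec.seed)
    n = expr.shape[1]
    eta = np.zeros(n)
    if spec.beta_true:
        X = hazard_covariates(expr)
        for gene, b in spec.beta_true.items():
            eta += b * X.loc[gene].to_numpy()
    u = rng.uniform(size=n)
    t_event = -np.log(u) / (spec.baseline_rate * np.exp(eta))
    if spec.censor_rate > 0:
        t_censor = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum.reduce([t_event, t_censor, np.full(n, spec.max_follow_up)])
    event = (t_event <= t_censor) & (t_event <= spec.max_follow_up)
    if not event.any():
        warnings.warn("all samples censored: no events generated", RuntimeWarning)
    return pd.DataFrame(
        {"time": time, "event": event.astype(int)}, index=expr.columns
    )


def generate_clinical_table(
    n_pos: int, n_neg: int, assoc_strength: float, seed: int = 0
) -> pd.DataFrame:
    """Patient table with a planted marker-exposure odds ratio.

    ``assoc_strength`` is the odds ratio linking marker-positive status to
    the 'exposure' covariate (baseline exposure probability 0.3 among
    marker-negative patients; ``inf`` gives perfect separation).  Two
    additional covariates (age group, grade) are independent of the
    marker, i.e. planted nulls.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("patient counts must be positive")
    if assoc_strength < 0:
        raise ValueError("odds ratio must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    marker = np.array(["positive"] * n_pos + ["negative"] * n_neg)

    p_neg = 0.3
    if np.isinf(assoc_strength):
        p_pos = 1.0
        p_neg_eff = 0.0
    else:
        odds = assoc_strength * p_neg / (1 - p_neg)
        p_pos = odds / (1 + odds)
        p_neg_eff = p_neg
    p_exposed = np.where(marker == "positive", p_pos, p_neg_eff)
    exposure = np.where(rng.uniform(size=n) < p_exposed, "yes", "no")

    age_group = np.where(rng.uniform(size=n) < 0.5, "<55", ">=55")
    grade = rng.choice(["G1", "G2", "G3"], size=n, p=[0.2, 0.3, 0.5])
    return pd.DataFrame(
        {
            "patient": [f"P{i:03d}" for i in range(n)],
            "marker": marker,
            "exposure": exposure,
            "age_group": age_group,
            "grade": grade,
        }
    ).set_index("patient")


@dataclass(frozen=True)
class PlantedBundle:
    """Full synthetic study: cohort, network, survival and ground truth."""

    cohort: CohortData
    network: nx.Graph
    survival: pd.DataFrame  # tumour samples only
    gene_sets: dict[str, list[str]]
    seed_genes: tuple[str, ...]
    prognostic_genes: tuple[str, ...]
    beta_true: dict[str, float]


def planted_prognostic_bundle(
    seed: int = 0,
    *,
    n_genes: int = 200,
    n_tumour: int = 400,
    n_normal: int = 60,
    de_fraction: float = 0.2,
    lfc_effect: float = 2.0,
    noise_sd: float = 0.5,
    n_prognostic: int = 8,
    beta_magnitude: float = 0.8,
) -> PlantedBundle:
    """The standard end-to-end recovery experiment.

    200 metabolic genes, 40 planted differential (20 up / 20 down), 8 of
    them prognostic with alternating ±``beta_magnitude`` log-hazard
    effects, and a network in which the differential genes form a dense
    module around five seed genes.  The pipeline should carry the
    prognostic genes through DE filtering, network prioritization, Cox
    screening and the lasso into the final risk model.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    cohort = generate_cohort(
        CohortSpec(
            n_genes=n_genes,
            n_tumour=n_tumour,
            n_normal=n_normal,
            de_fraction=de_fraction,
            lfc_effect=lfc_effect,
            noise_sd=noise_sd,
            seed=int(sub[0]),
        )
    )
    de_genes = cohort.de_truth.loc[
        cohort.de_truth["planted"] != "null", "gene"
    ].tolist()
    n_up = sum(cohort.de_truth["planted"] == "up")
    # prognostic genes: half from the up-regulated block, half from the down
    k = n_prognostic // 2
    prognostic = tuple(de_genes[:k] + de_genes[n_up : n_up + (n_prognostic - k)])
    beta_true = {
        g: beta_magnitude if i % 2 == 0 else -beta_magnitude
        for i, g in enumerate(prognostic)
    }

    seeds = ("ACOT7", "CERK", "EHMT2", "MTAP", "PDE8A")
    all_nodes = tuple(cohort.expression.index) + seeds
    network = generate_network(
        NetworkSpec(
            n_nodes=len(all_nodes),
            module_genes=tuple(de_genes),
            seed_genes=seeds,
            within_module_edge_prob=0.4,
            background_edge_prob=0.02,
            weight_range=(0.4, 1.0),
            seed=int(sub[1]),
            node_names=all_nodes,
        )
    )

    tumour_cols = cohort.annotation.index[cohort.annotation["group"] == "tumour"]
    survival = generate_survival(
        cohort.expression[tumour_cols],
        SurvivalSpec(beta_true=beta_true, seed=int(sub[2])),
    )
    gene_sets = {"METABOLISM": list(cohort.expression.index)}
    return PlantedBundle(
        cohort=cohort,
        network=network,
        survival=survival,
        gene_sets=gene_sets,
        seed_genes=seeds,
        prognostic_genes=prognostic,
        beta_true=beta_true,
    )
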