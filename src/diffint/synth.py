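"""Synthetic study generator with planted differential-interactome structure.

Emulates the statistical shape of a two-phenotype expression study on a
known interaction network so every pipeline stage can be exercised without
external downloads:

* background expression is i.i.d. log-normal per gene (a plausible shape
  for intensity/FPKM scales);
* each *planted* edge is pushed, per sample and with a phenotype-specific
  probability, into the jointly over-expressed state: both endpoint values
  are resampled from the far upper tail of their gene distributions, so the
  discretization stage is genuinely exercised rather than bypassed. An
  edge planted "activated" uses a high tumor rate and a low normal rate; a
  "repressed" edge swaps the two;
* decoy (null) edges connect genes that carry no planted signal at either
  endpoint, so the manifest's null edges are null by construction;
* survival times are exponential with hazard h0 * exp(sum beta_g * x~_g)
  on standardized expression, with independent uniform censoring at a
  configurable rate;
* the drug-gene table holds decoy drugs with random gene sets plus one
  planted drug whose set contains the given target genes.

All generators are deterministic under a fixed seed: each draws from its
own `numpy` Generator spawned from (seed, stream-id).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .differential import ACTIVATED, REPRESSED
from .io import (
    ClinicalTable,
    DrugGeneTable,
    ExpressionDataset,
    InteractionNetwork,
    NORMAL,
    TUMOR,
    canonical_edge,
    write_clinical,
    write_drug_gene_table,
    write_expression,
    write_network,
)

_STREAM_NETWORK = 0
_STREAM_EXPRESSION = 1
_STREAM_SURVIVAL = 2
_STREAM_DRUGS = 3


@dataclass(frozen=True)
class PlantedEdge:
    """An edge seeded to occupy the jointly-high state phenotype-specifically.

    ``tumor_rate`` / ``normal_rate`` are the per-sample probabilities that a
    tumor / normal sample is pushed into the [+1 +1] joint state.
    """

    gene_a: str
    gene_b: str
    direction: str          # "activated" or "repressed"
    tumor_rate: float
    normal_rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_rate <= 1 and 0 <= self.normal_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.direction not in (ACTIVATED, REPRESSED):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def edge(self) -> tuple[str, str]:
        return canonical_edge(self.gene_a, self.gene_b)

    @classmethod
    def activated(cls, a, b, tumor_rate=0.8, normal_rate=0.02):
        return cls(a, b, ACTIVATED, tumor_rate, normal_rate)

    @classmethod
    def repressed(cls, a, b, tumor_rate=0.02, normal_rate=0.8):
        return cls(a, b, REPRESSED, tumor_rate, normal_rate)


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults give a desk-scale study: 500 genes, 50 normal + 50 tumor
    samples, a 300-edge network. Expression backgrounds are log-normal with
    per-gene log-means drawn uniformly from ``meanlog_range`` and a common
    log-sd; planted values sit ``push_z`` log-sds above the gene's log-mean.
    """

    n_genes: int = 500
    n_normal: int = 50
    n_tumor: int = 50
    n_edges: int = 300
    planted_edges: tuple[PlantedEdge, ...] = ()
    meanlog_range: tuple[float, float] = (1.0, 3.0)
    sdlog: float = 0.5
    push_z: float = 3.0
    survival_betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2
    n_decoy_drugs: int = 50
    decoy_set_size: int = 5
    planted_drug: str = "DRUG_PLANTED"
    seed: int = 0

    def __post_init__(self) -> None:
        genes = set(self.gene_ids())
        for pe in self.planted_edges:
            if pe.gene_a not in genes or pe.gene_b not in genes:
                raise ValueError(
                    f"planted edge ({pe.gene_a}, {pe.gene_b}) endpoints "
                    "not in gene list"
                )
        for g in self.survival_betas:
            if g not in genes:
                raise ValueError(f"survival beta on unknown gene {g!r}")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        return [f"N{i:03d}" for i in range(self.n_normal)] + [
            f"T{i:03d}" for i in range(self.n_tumor)
        ]

    def phenotypes(self) -> list[str]:
        return [NORMAL] * self.n_normal + [TUMOR] * self.n_tumor

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def simulate_network(cfg: SimulationConfig) -> InteractionNetwork:
    """The study network: all planted edges plus decoy edges on signal-free genes.

    Decoy edges connect only genes that appear in no planted edge, so a
    decoy edge cannot inherit differential expression from a planted
    endpoint — the manifest's null edges are guaranteed null.
    """
    rng = cfg._rng(_STREAM_NETWORK)
    planted = {pe.edge for pe in cfg.planted_edges}
    if len(planted) != len(cfg.planted_edges):
        raise ValueError("duplicate planted edges")
    planted_genes = {g for e in planted for g in e}
    pool = [g for g in cfg.gene_ids() if g not in planted_genes]
    n_decoys = cfg.n_edges - len(planted)
    if n_decoys < 0:
        raise ValueError("n_edges smaller than the number of planted edges")
    if len(pool) < 2 and n_decoys > 0:
        raise ValueError("not enough signal-free genes for decoy edges")
    edges = set(planted)
    decoys = set()
    while len(decoys) < n_decoys:
        a, b = rng.choice(len(pool), size=2, replace=False)
        decoys.add(canonical_edge(pool[a], pool[b]))
    return InteractionNetwork(frozenset(edges | decoys))


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionDataset, dict]:
    """Generate the expression matrix and its ground-truth manifest."""
    rng = cfg._rng(_STREAM_EXPRESSION)
    genes = cfg.gene_ids()
    samples = cfg.sample_ids()
    phenos = cfg.phenotypes()
    n_samples = len(samples)
    gidx = {g: i for i, g in enumerate(genes)}

    meanlog = rng.uniform(*cfg.meanlog_range, size=cfg.n_genes)
    values = np.exp(
        meanlog[:, None] + cfg.sdlog * rng.standard_normal((cfg.n_genes, n_samples))
    )
    tumor = np.array([p == TUMOR for p in phenos])
    for pe in cfg.planted_edges:
        rate = np.where(tumor, pe.tumor_rate, pe.normal_rate)
        push = rng.random(n_samples) < rate
        for g in (pe.gene_a, pe.gene_b):
            i = gidx[g]
            offset = cfg.push_z + rng.uniform(0.0, 0.5, size=int(push.sum()))
            values[i, push] = np.exp(meanlog[i] + cfg.sdlog * offset)

    ds = ExpressionDataset(genes, samples, values, phenos)
    manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_normal": cfg.n_normal,
        "n_tumor": cfg.n_tumor,
        "planted_edges": [
            {
                "gene_a": pe.edge[0],
                "gene_b": pe.edge[1],
                "direction": pe.direction,
                "tumor_rate": pe.tumor_rate,
                "normal_rate": pe.normal_rate,
            }
            for pe in cfg.planted_edges
        ],
        "survival_betas": dict(cfg.survival_betas),
        "planted_drug": cfg.planted_drug,
    }
    return ds, manifest


def simulate_survival(cfg: SimulationConfig, expr: ExpressionDataset) -> ClinicalTable:
    """Exponential survival with hazard h0*exp(sum beta_g x~_g); uniform censoring.

    x~ is the per-gene z-scored expression. Each subject is independently
    censored with probability ``censoring_rate``; a censored subject's
    recorded time is uniform on (0, T), its latent event time.
    """
    rng = cfg._rng(_STREAM_SURVIVAL)
    gidx = expr.gene_index()
    lin = np.zeros(len(expr.sample_ids))
    for g, beta in cfg.survival_betas.items():
        x = expr.values[gidx[g]]
        sd = x.std(ddof=1)
        if sd > 0:
            lin += beta * (x - x.mean()) / sd
    hazard = cfg.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(t_event)) < cfg.censoring_rate
    time = np.where(censored, rng.uniform(0.0, 1.0, len(t_event)) * t_event, t_event)
    event = (~censored).astype(int)
    return ClinicalTable(list(expr.sample_ids), time, event)


def simulate_drug_table(cfg: SimulationConfig, targets: set[str]) -> DrugGeneTable:
    """Decoy drugs with random gene sets plus one planted drug covering targets."""
    if not targets:
        raise ValueError("planted drug needs a non-empty target set")
    rng = cfg._rng(_STREAM_DRUGS)
    genes = cfg.gene_ids()
    records = set()
    for j in range(cfg.n_decoy_drugs):
        picks = rng.choice(len(genes), size=cfg.decoy_set_size, replace=False)
        for i in picks:
            records.add((f"DRUG_{j:04d}", genes[i]))
    for g in sorted(targets):
        records.add((cfg.planted_drug, g))
    return DrugGeneTable(frozenset(records))


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produced, plus its ground truth."""

    config: SimulationConfig
    expression: ExpressionDataset
    network: InteractionNetwork
    clinical: ClinicalTable
    drug_table: DrugGeneTable
    manifest: dict


def simulate_study(
    cfg: SimulationConfig, drug_targets: set[str] | None = None
) -> SimulatedStudy:
    """Run every generator for one config.

    ``drug_targets`` defaults to the planted hubs (genes on two or more
    planted edges), or to the first planted edge's gene pair when no gene
    repeats.
    """
    expr, manifest = simulate_expression(cfg)
    net = simulate_network(cfg)
    clinical = simulate_survival(cfg, expr)
    if drug_targets is None:
        drug_targets = _default_targets(cfg)
    table = simulate_drug_table(cfg, drug_targets)
    manifest["drug_targets"] = sorted(drug_targets)
    return SimulatedStudy(cfg, expr, net, clinical, table, manifest)


def _default_targets(cfg: SimulationConfig) -> set[str]:
    degree: dict[str, int] = {}
    for pe in cfg.planted_edges:
        for g in pe.edge:
            degree[g] = degree.get(g, 0) + 1
    if not degree:
        raise ValueError("no planted edges: supply drug_targets explicitly")
    hubs = {g for g, d in degree.items() if d >= 2}
    if hubs:
        return hubs
    return set(cfg.planted_edges[0].edge)


def write_study(study: SimulatedStudy, out_dir) -> dict[str, str]:
    """Write every input format plus the ground-truth manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "network": out / "network.tsv",
        "clinical": out / "clinical.tsv",
        "drug_table": out / "drug_gene.tsv",
        "manifest": out / "manifest.json",
    }
    write_expression(study.expression, paths["matrix"], paths["labels"])
    write_network(study.network, paths["network"])
    write_clinical(study.clinical, paths["clinical"])
    write_drug_gene_table(study.drug_table, paths["drug_table"])
    with open(paths["manifest"], "w") as fh:
        json.dump(study.manifest, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Ready-made study designs
# ---------------------------------------------------------------------------

def planted_recovery_config(
    seed: int,
    n_genes: int = 500,
    n_normal: int = 50,
    n_tumor: int = 50,
    n_edges: int = 300,
    n_activated: int = 20,
    n_repressed: int = 20,
    tumor_rate: float = 0.8,
    normal_rate: float = 0.02,
    **kwargs,
) -> SimulationConfig:
    """Scattered planted edges on disjoint gene pairs (signal-recovery design).

    The first 2*(n_activated+n_repressed) genes host the planted edges, one
    fresh gene pair per edge; activated edges occupy the [+1 +1] state in
    tumor samples at ``tumor_rate``, repressed edges in normal samples.
    """
    gene = lambda i: f"G{i:04d}"
    planted = []
    g = 0
    for _ in range(n_activated):
        planted.append(
            PlantedEdge.activated(gene(g), gene(g + 1), tumor_rate, normal_rate)
        )
        g += 2
    for _ in range(n_repressed):
        planted.append(
            PlantedEdge.repressed(gene(g), gene(g + 1), normal_rate, tumor_rate)
        )
        g += 2
    return SimulationConfig(
        n_genes=n_genes,
        n_normal=n_normal,
        n_tumor=n_tumor,
        n_edges=n_edges,
        planted_edges=tuple(planted),
        seed=seed,
        **kwargs,
    )


def closure_config(
    seed: int,
    n_genes: int = 400,
    n_normal: int = 50,
    n_tumor: int = 50,
    n_edges: int = 120,
    hub_sizes: tuple[int, ...] = (8, 6),
    tumor_rate: float = 0.8,
    normal_rate: float = 0.02,
    beta: float = 0.8,
    n_prognostic_genes: int = 3,
    **kwargs,
) -> SimulationConfig:
    """Hub-star design for end-to-end closure.

    Each hub gets a star of activated planted edges, so the pipeline should
    rediscover one module per hub. Survival betas are placed on the first
    hub and its first ``n_prognostic_genes - 1`` partners, making the first
    module the planted prognostic signature; the planted drug's gene set is
    the hub genes.
    """
    gene = lambda i: f"G{i:04d}"
    planted = []
    g = 0
    hubs = []
    betas: dict[str, float] = {}
    for h_i, size in enumerate(hub_sizes):
        hub = gene(g)
        hubs.append(hub)
        g += 1
        partners = []
        for _ in range(size):
            partners.append(gene(g))
            g += 1
        for p in partners:
            planted.append(PlantedEdge.activated(hub, p, tumor_rate, normal_rate))
        if h_i == 0:
            for pg in [hub] + partners[: n_prognostic_genes - 1]:
                betas[pg] = beta
    return SimulationConfig(
        n_genes=n_genes,
        n_normal=n_normal,
        n_tumor=n_tumor,
        n_edges=n_edges,
        planted_edges=tuple(planted),
        survival_betas=betas,
        seed=seed,
        **kwargs,
    )
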