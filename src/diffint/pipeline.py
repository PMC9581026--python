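"""End-to-end orchestration: expression + network in, report out.

``run_pipeline`` chains the stages in method order — discretize, count
joint states, call differential PPIs, build hub modules — and, when the
corresponding inputs are supplied, runs pathway over-representation, drug
repositioning against the module hubs, and per-module prognostic scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import differential, enrichment, modules, prognosis
from .differential import DifferentialPPI, StateCountRecord
from .discretize import DEFAULT_BAND_SD, discretize as discretize_dataset
from .io import ClinicalTable, DrugGeneTable, ExpressionDataset, InteractionNetwork, \
    filter_network_to_expression
from .modules import ModuleCatalog

logger = logging.getLogger(__name__)


@dataclass
class ModulePrognosis:
    module: str
    hazard_ratio: float | None
    logrank_p: float | None
    o_high: float | None = None
    e_high: float | None = None
    o_low: float | None = None
    e_low: float | None = None
    error: str | None = None

    @property
    def significant(self) -> bool:
        return self.logrank_p is not None and self.logrank_p < prognosis.SIGNIFICANCE_LEVEL


@dataclass
class PipelineResult:
    records: list[StateCountRecord]
    dppis: list[DifferentialPPI]
    call_summary: dict[str, int]
    catalog: ModuleCatalog
    drug_results: list[enrichment.EnrichmentResult] = field(default_factory=list)
    ora: pd.DataFrame | None = None
    module_prognosis: list[ModulePrognosis] = field(default_factory=list)

    def report(self) -> dict:
        """A JSON-serializable run summary."""
        rep: dict = dict(self.call_summary)
        rep["n_modules"] = len(self.catalog)
        rep["modules"] = {
            name: len(m.edges) for name, m in sorted(self.catalog.modules.items())
        }
        rep["drugs"] = [
            {"drug": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p": r.p, "z": r.z}
            for r in self.drug_results
        ]
        rep["module_prognosis"] = [
            {"module": mp.module, "hazard_ratio": mp.hazard_ratio,
             "logrank_p": mp.logrank_p, "significant": mp.significant,
             "error": mp.error}
            for mp in self.module_prognosis
        ]
        return rep


def run_pipeline(
    expr: ExpressionDataset,
    net: InteractionNetwork,
    *,
    band_width_sd: float = DEFAULT_BAND_SD,
    reference: str = "all",
    f_min: float = differential.DEFAULT_F_MIN,
    q_low: float = differential.DEFAULT_Q_LOW,
    q_high: float = differential.DEFAULT_Q_HIGH,
    min_edges: int = modules.DEFAULT_MIN_EDGES,
    drug_table: DrugGeneTable | None = None,
    drug_targets: set[str] | None = None,
    drug_p_cut: float = enrichment.DEFAULT_DRUG_P_CUT,
    clinical: ClinicalTable | None = None,
    gmt: dict[str, set[str]] | None = None,
    ora_universe: set[str] | None = None,
    ora_p_cut: float = enrichment.DEFAULT_ORA_P_CUT,
) -> PipelineResult:
    """Run the full differential-interactome analysis on one dataset.

    Optional stages activate when their inputs are given: ``gmt`` enables
    module over-representation (universe defaults to all dataset genes),
    ``drug_table`` enables repositioning (query defaults to the module
    hubs), and ``clinical`` enables per-module prognostic scoring.
    """
    net = filter_network_to_expression(net, expr)
    dm = discretize_dataset(expr, band_width_sd=band_width_sd, reference=reference)
    records = differential.count_joint_states(dm, net)
    dppis = differential.call_differential_ppis(
        records, f_min=f_min, q_low=q_low, q_high=q_high
    )
    catalog = modules.build_modules(dppis, min_edges=min_edges)

    result = PipelineResult(
        records=records,
        dppis=dppis,
        call_summary=differential.summarize_calls(dppis),
        catalog=catalog,
    )

    if gmt is not None:
        universe = ora_universe if ora_universe is not None else set(expr.gene_ids)
        result.ora = enrichment.ora_modules(catalog, gmt, universe, p_cut=ora_p_cut)

    if drug_table is not None:
        targets = drug_targets if drug_targets is not None else catalog.hubs()
        if targets:
            result.drug_results = enrichment.reposition_drugs(
                targets, drug_table, p_cut=drug_p_cut
            )
        else:
            logger.warning("no module hubs: drug repositioning skipped")

    if clinical is not None:
        for name, module in sorted(catalog.modules.items()):
            genes = sorted(module.members | {module.hub})
            try:
                model = prognosis.fit_module_cox(expr, clinical, genes)
                pi = prognosis.prognostic_index(model, expr)
                strat = prognosis.stratify_and_test(pi, clinical)
            except ValueError as exc:
                result.module_prognosis.append(
                    ModulePrognosis(name, None, None, error=str(exc))
                )
                continue
            result.module_prognosis.append(
                ModulePrognosis(
                    name,
                    strat.hazard_ratio,
                    strat.logrank_p,
                    strat.o_high,
                    strat.e_high,
                    strat.o_low,
                    strat.e_low,
                )
            )
    return result
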