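"""Hypergeometric over-representation analysis and drug repositioning.

Overlap between a query gene set (e.g. module members or drug targets) and a
reference set within a universe of N genes is scored with the upper-tail
hypergeometric probability p = P[X >= k], X ~ Hypergeometric(N, K, n), where
K is the reference-set size and n the query size after restriction to the
universe. p-values are also expressed as z-scores via the inverse normal
cumulative distribution, z = Phi^-1(1 - p).

Drug repositioning applies the same test per drug, with the drug's targets
as the reference set and all genes occurring in the drug-gene table as the
universe; drugs with p below a cutoff (default 1e-3) are returned ranked by
ascending p. Raw p-value cutoffs are used by default (no multiple-testing
correction); Benjamini-Hochberg is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import DrugGeneTable
from .modules import ModuleCatalog

logger = logging.getLogger(__name__)

DEFAULT_ORA_P_CUT = 0.05
DEFAULT_DRUG_P_CUT = 1e-3


@dataclass(frozen=True)
class EnrichmentResult:
    """One query-vs-reference overlap with its hypergeometric p and z-score."""

    set_name: str
    k: int   # overlap size
    K: int   # reference-set size in universe
    n: int   # query size in universe
    N: int   # universe size
    p: float
    z: float


def p_to_z(p: float) -> float:
    """Convert a p-value to a z-score via the inverse normal CDF.

    z = Phi^-1(1 - p); requires p strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(stats.norm.isf(p))


def hypergeom_overrep(
    query: set[str],
    reference: set[str],
    universe: set[str],
    set_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test of query vs reference.

    Members of query or reference outside the universe are dropped with a
    warning. p = P[X >= k] is inclusive, so k = 0 gives p = 1 exactly
    (z is then -inf, the quantile at probability 0).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray_q = query - universe
    stray_r = reference - universe
    if stray_q or stray_r:
        logger.warning(
            "dropped %d query and %d reference gene(s) outside the universe",
            len(stray_q), len(stray_r),
        )
    query = query & universe
    reference = reference & universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    N = len(universe)
    K = len(reference)
    n = len(query)
    k = len(query & reference)
    # sf(k-1) = P[X >= k]
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    z = float(stats.norm.isf(p))
    return EnrichmentResult(set_name=set_name, k=k, K=K, n=n, N=N, p=p, z=z)


def reposition_drugs(
    targets: set[str],
    table: DrugGeneTable,
    p_cut: float = DEFAULT_DRUG_P_CUT,
) -> list[EnrichmentResult]:
    """Rank drugs by hypergeometric association of their gene sets with targets.

    The universe is every gene occurring in the drug-gene table. Returns the
    drugs with p < p_cut, sorted ascending by p (ties broken by larger
    overlap, then drug id). Targets overlapping no drug yield an empty list.
    """
    if not table.records:
        raise ValueError("drug-gene table is empty")
    universe = table.universe()
    query = targets & universe
    if not query:
        logger.warning("no target gene occurs in the drug-gene table")
        return []
    results = []
    for drug, genes in table.gene_sets().items():
        res = hypergeom_overrep(query, genes, universe, set_name=drug)
        if res.p < p_cut:
            results.append(res)
    results.sort(key=lambda r: (r.p, -r.k, r.set_name))
    return results


def ora_modules(
    catalog: ModuleCatalog,
    gmt_collection: dict[str, set[str]],
    universe: set[str],
    p_cut: float = DEFAULT_ORA_P_CUT,
    fdr: bool = False,
) -> pd.DataFrame:
    """Over-representation of each module's members against a GMT collection.

    The query for each module is its member set plus the hub. Rows with zero
    overlap are excluded. With ``fdr=True`` a Benjamini-Hochberg adjusted
    q-value column is added (the raw-p cutoff still selects rows by default).
    """
    rows = []
    for name, module in sorted(catalog.modules.items()):
        query = (set(module.members) | {module.hub}) & universe
        if not query:
            continue
        for set_name, genes in gmt_collection.items():
            res = hypergeom_overrep(query, genes, universe, set_name=set_name)
            if res.k == 0:
                continue
            rows.append(
                {"module": name, "set_name": set_name, "k": res.k, "K": res.K,
                 "n": res.n, "N": res.N, "p": res.p, "z": res.z}
            )
    df = pd.DataFrame(
        rows, columns=["module", "set_name", "k", "K", "n", "N", "p", "z"]
    )
    if fdr and len(df):
        df["q_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    if len(df):
        df = df[df["p"] < p_cut].sort_values(["module", "p"]).reset_index(drop=True)
    return df


def _benjamini_hochberg(p):
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
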