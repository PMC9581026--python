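"""Prognostic scoring of module gene signatures.

A multivariate Cox proportional-hazards model is fitted on a module's genes;
its linear predictor, the prognostic index PI = sum_p beta_p * x_p, scores
each patient. Patients are split into low- and high-risk groups at the
median PI (configurable quantile; ties go to the low group), and the group
separation is quantified by the log-rank test and the observed/expected
hazard ratio

    HR = (O1/E1) / (O2/E2)

where O and E are the observed and expected death counts of the log-rank
computation, group 1 being the high-risk group. Separation is flagged
significant at log-rank p < 0.05.

The Cox fit is delegated to lifelines (Efron handling of tied event times);
the log-rank O/E decomposition, variance and p-value are computed here so
that the HR components are exactly those of the reported test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .io import ClinicalTable, ExpressionDataset

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"
DEFAULT_SPLIT_QUANTILE = 0.5
SIGNIFICANCE_LEVEL = 0.05
MIN_CLINICAL_SAMPLES = 10


@dataclass
class PrognosticModel:
    """Per-gene Cox coefficients defining a prognostic index."""

    genes: list[str]
    betas: np.ndarray
    n_samples: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.genes) != len(self.betas):
            raise ValueError("one coefficient required per gene")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite Cox coefficient")


@dataclass
class RiskStratification:
    """Median-split risk groups with log-rank test and O/E hazard ratio."""

    sample_ids: list[str]
    pi: np.ndarray
    group: list[str]            # per sample, "low" or "high"
    o_high: float
    e_high: float
    o_low: float
    e_low: float
    hazard_ratio: float
    logrank_stat: float
    logrank_p: float

    @property
    def significant(self) -> bool:
        return self.logrank_p < SIGNIFICANCE_LEVEL


def _design_matrix(
    expr: ExpressionDataset, clinical: ClinicalTable, genes: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    seen: dict[str, None] = {}
    for g in genes:
        if g in seen:
            logger.warning("duplicate gene %r in model gene list; deduplicated", g)
        seen[g] = None
    genes = list(seen)
    gidx = expr.gene_index()
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise ValueError(f"gene(s) not in expression dataset: {', '.join(missing)}")
    cid = {s: i for i, s in enumerate(expr.sample_ids)}
    shared = [s for s in clinical.sample_ids if s in cid]
    clin = clinical.subset(shared)
    X = expr.values[np.ix_([gidx[g] for g in genes], [cid[s] for s in shared])].T
    df = pd.DataFrame(X, columns=genes)
    df["time"] = clin.time
    df["event"] = clin.event
    df.index = pd.Index(shared)
    return df, genes


def fit_module_cox(
    expr: ExpressionDataset, clinical: ClinicalTable, genes: list[str]
) -> PrognosticModel:
    """Fit multivariate Cox proportional-hazards coefficients for a gene list.

    Samples are matched between the expression and clinical tables by id;
    at least 10 matched samples are required. Duplicate genes in the list
    are deduplicated with a warning. Raises on non-convergence with advice
    to reduce the gene list.
    """
    df, genes = _design_matrix(expr, clinical, genes)
    if len(df) < MIN_CLINICAL_SAMPLES:
        raise ValueError(
            f"need >= {MIN_CLINICAL_SAMPLES} samples with clinical data, got {len(df)}"
        )
    cph = CoxPHFitter()
    try:
        with np.errstate(all="ignore"):
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, Exception) as exc:  # lifelines raises mixed types
        if isinstance(exc, (ValueError, ConvergenceError)):
            raise ValueError(
                "Cox fit did not converge; consider reducing the gene list "
                f"({exc})"
            ) from exc
        raise
    betas = cph.params_.reindex(genes).to_numpy()
    if not np.all(np.isfinite(betas)):
        raise ValueError(
            "Cox fit produced non-finite coefficients; consider reducing the gene list"
        )
    return PrognosticModel(
        genes=genes,
        betas=betas,
        n_samples=len(df),
        n_events=int(df["event"].sum()),
    )


def prognostic_index(model: PrognosticModel, expr: ExpressionDataset) -> pd.Series:
    """PI = sum_p beta_p x_p per sample, indexed by sample id."""
    gidx = expr.gene_index()
    missing = [g for g in model.genes if g not in gidx]
    if missing:
        raise ValueError(f"model gene(s) not in expression: {', '.join(missing)}")
    X = expr.values[[gidx[g] for g in model.genes]]
    return pd.Series(model.betas @ X, index=expr.sample_ids, name="PI")


def logrank_oe(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float, float, float, float, float]:
    """Two-group log-rank decomposition.

    Returns (O1, E1, O2, E2, V, chi2, p): observed and expected deaths per
    group, the hypergeometric variance of O1, and the chi-square statistic
    (O1 - E1)^2 / V with its 1-df p-value. At each distinct event time t
    with d deaths among n at risk, group 1's expected share is d * n1 / n.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_group1 = np.asarray(in_group1, bool)
    o1 = float(event[in_group1].sum())
    o2 = float(event[~in_group1].sum())
    e1 = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = int(((time == t) & (event == 1)).sum())
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    e2 = (o1 + o2) - e1
    if v > 0:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return o1, e1, o2, e2, v, chi2, p


def stratify_and_test(
    pi: pd.Series,
    clinical: ClinicalTable,
    split_quantile: float = DEFAULT_SPLIT_QUANTILE,
) -> RiskStratification:
    """Median-split risk groups and their log-rank separation.

    Samples with PI <= the split quantile of PI form the low-risk group
    (ties to low); both groups must keep >= 2 samples. Requires at least
    one observed event overall.
    """
    cid = set(clinical.sample_ids)
    pi = pi[[s in cid for s in pi.index]]
    clin = clinical.subset(list(pi.index))
    pi = pi.reindex(clin.sample_ids)
    if clin.event.sum() == 0:
        raise ValueError("no events: cannot test survival separation")
    cut = float(np.quantile(pi.to_numpy(), split_quantile))
    high = pi.to_numpy() > cut
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError(
            "degenerate split: need >= 2 samples per risk group "
            "(is the prognostic index constant?)"
        )
    o1, e1, o2, e2, v, chi2, p = logrank_oe(clin.time, clin.event, high)
    if e1 > 0 and e2 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
    else:
        hr = np.nan
        logger.warning("hazard ratio undefined: a group has no expected/observed deaths")
    return RiskStratification(
        sample_ids=list(pi.index),
        pi=pi.to_numpy(),
        group=[HIGH if h else LOW for h in high],
        o_high=o1,
        e_high=e1,
        o_low=o2,
        e_low=e2,
        hazard_ratio=hr,
        logrank_stat=chi2,
        logrank_p=p,
    )


def km_curves(strat: RiskStratification, clinical: ClinicalTable) -> pd.DataFrame:
    """Kaplan-Meier survival curve coordinates per risk group.

    Returns a long table (group, time, survival) suitable for plotting
    elsewhere; estimation uses lifelines' KaplanMeierFitter.
    """
    from lifelines import KaplanMeierFitter

    clin = clinical.subset(strat.sample_ids)
    group = np.array(strat.group)
    frames = []
    for g in (LOW, HIGH):
        mask = group == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(clin.time[mask], clin.event[mask], label=g)
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": g, "time": sf.index.to_numpy(),
                 "survival": sf[g].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)
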