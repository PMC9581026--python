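"""The differential-interactome core: joint-state counting, the q statistic,
and differential PPI (dPPI) calling.

For each interaction (A, B) and each sample, the pair of discretized levels
(l_A, l_B) forms one of nine joint co-expression states. Per state we count
occurrences in the normal group (N0, out of NN samples) and the tumor group
(N1, out of NT samples), normalize to frequencies f0 = N0/NN and f1 = N1/NT,
and estimate the probability that the state belongs to the tumor phenotype:

    q = f1 / (f0 + f1)

q is 0.5 when a state is equally frequent in both phenotypes, near 1 when it
is essentially tumor-specific, and near 0 when it is normal-specific. A state
supports a differential call when it is common enough in at least one
phenotype (max(f0, f1) > f_min, default 20%) and q is extreme: q > q_high
(default 0.90) marks the interaction state as activated in tumor, q < q_low
(default 0.10) as repressed in tumor. All three comparisons are strict.

q is a per-(edge, state) quantity; an edge's direction is the union of its
qualifying states, and an edge qualifying in both directions through
different states is reported once per direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .discretize import DiscretizedMatrix
from .io import InteractionNetwork

logger = logging.getLogger(__name__)

ACTIVATED = "activated"
REPRESSED = "repressed"

#: All nine joint states in a fixed display order: levels of the first
#: (lexicographically smaller) gene vary slowest.
JOINT_STATES: tuple[tuple[int, int], ...] = tuple(product((-1, 0, 1), repeat=2))

DEFAULT_F_MIN = 0.20
DEFAULT_Q_LOW = 0.10
DEFAULT_Q_HIGH = 0.90


@dataclass(frozen=True)
class StateCountRecord:
    """Counts and frequencies of one joint state on one interaction.

    ``q`` is None when the state occurs in neither phenotype (f0 + f1 = 0),
    in which case the state carries no evidence and is excluded from calling.
    """

    edge: tuple[str, str]
    state: tuple[int, int]
    n0: int
    n1: int
    nn: int
    nt: int

    @property
    def f0(self) -> float:
        return self.n0 / self.nn

    @property
    def f1(self) -> float:
        return self.n1 / self.nt

    @property
    def q(self) -> float | None:
        return compute_q(self)


@dataclass(frozen=True)
class SupportingState:
    state: tuple[int, int]
    q: float
    f0: float
    f1: float


@dataclass(frozen=True)
class DifferentialPPI:
    """An interaction called activated or repressed in the tumor phenotype."""

    edge: tuple[str, str]
    direction: str
    supporting_states: tuple[SupportingState, ...]

    @property
    def best_state(self) -> SupportingState:
        """The supporting state with the most extreme q (ties: largest max(f0,f1))."""
        key = (
            (lambda s: (s.q, max(s.f0, s.f1)))
            if self.direction == ACTIVATED
            else (lambda s: (-s.q, max(s.f0, s.f1)))
        )
        return max(self.supporting_states, key=key)


def count_joint_states(
    dm: DiscretizedMatrix, net: InteractionNetwork
) -> list[StateCountRecord]:
    """Count all nine joint states per edge, per phenotype.

    Every edge yields exactly 9 records (zero counts included), so that the
    per-edge counts partition each phenotype's samples. Edges with an
    endpoint absent from the matrix are skipped with a logged count.
    """
    gidx = dm.gene_index()
    tumor = dm.phenotype_mask
    nn = int((~tumor).sum())
    nt = int(tumor.sum())
    # state index encoding: 3*(l_a+1) + (l_b+1) in 0..8
    state_of_index = {3 * (a + 1) + (b + 1): (a, b) for a, b in JOINT_STATES}

    records: list[StateCountRecord] = []
    n_skipped = 0
    for edge in sorted(net.edges):
        a, b = edge
        if a not in gidx or b not in gidx:
            n_skipped += 1
            continue
        code = 3 * (dm.levels[gidx[a]].astype(np.int32) + 1) + (
            dm.levels[gidx[b]].astype(np.int32) + 1
        )
        c0 = np.bincount(code[~tumor], minlength=9)
        c1 = np.bincount(code[tumor], minlength=9)
        for k in range(9):
            records.append(
                StateCountRecord(edge, state_of_index[k], int(c0[k]), int(c1[k]), nn, nt)
            )
    if n_skipped:
        logger.warning(
            "%d edge(s) skipped: endpoint missing from expression matrix", n_skipped
        )
    return records


def compute_q(rec: StateCountRecord) -> float | None:
    """The tumor-occurrence probability estimate of one state.

    q = (N1/NT) / (N0/NN + N1/NT); None when both frequencies are zero.
    """
    if rec.nn <= 0 or rec.nt <= 0:
        raise ValueError("both phenotype groups must be non-empty")
    denom = rec.f0 + rec.f1
    if denom == 0:
        return None
    return rec.f1 / denom


def call_differential_ppis(
    records: list[StateCountRecord],
    f_min: float = DEFAULT_F_MIN,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
) -> list[DifferentialPPI]:
    """Call differential PPIs from state-count records.

    A state supports ``activated`` when max(f0, f1) > f_min and q > q_high,
    and ``repressed`` when max(f0, f1) > f_min and q < q_low (all strict).
    An edge yields one call per direction with at least one supporting
    state; an edge may be reported in both directions.
    """
    support: dict[tuple[tuple[str, str], str], list[SupportingState]] = {}
    for rec in records:
        f0, f1 = rec.f0, rec.f1
        denom = f0 + f1
        if denom == 0:
            continue
        if max(f0, f1) <= f_min:
            continue
        q = f1 / denom
        # The repressed rule q < q_low is evaluated through the complementary
        # ratio f0/(f0+f1) > 1-q_low: bit-identical to the swapped-phenotype
        # q, so exchanging labels flips calls exactly even when q lands on a
        # representable threshold.
        if q > q_high:
            direction = ACTIVATED
        elif f0 / denom > 1.0 - q_low:
            direction = REPRESSED
        else:
            continue
        support.setdefault((rec.edge, direction), []).append(
            SupportingState(rec.state, q, rec.f0, rec.f1)
        )
    calls = [
        DifferentialPPI(edge, direction, tuple(states))
        for (edge, direction), states in support.items()
    ]
    calls.sort(key=lambda c: (c.edge, c.direction))
    return calls


def records_to_frame(records: list[StateCountRecord]) -> pd.DataFrame:
    """Tabulate state counts (one row per edge x state) for TSV export."""
    return pd.DataFrame(
        {
            "gene_a": [r.edge[0] for r in records],
            "gene_b": [r.edge[1] for r in records],
            "state_a": [r.state[0] for r in records],
            "state_b": [r.state[1] for r in records],
            "N0": [r.n0 for r in records],
            "N1": [r.n1 for r in records],
            "f0": [r.f0 for r in records],
            "f1": [r.f1 for r in records],
            "q": [r.q if r.q is not None else np.nan for r in records],
        }
    )


def dppis_to_frame(calls: list[DifferentialPPI]) -> pd.DataFrame:
    """Tabulate dPPI calls (edge, direction, best state, q, f0, f1)."""
    rows = []
    for c in calls:
        best = c.best_state
        rows.append(
            {
                "gene_a": c.edge[0],
                "gene_b": c.edge[1],
                "direction": c.direction,
                "state_a": best.state[0],
                "state_b": best.state[1],
                "q": best.q,
                "f0": best.f0,
                "f1": best.f1,
                "n_supporting_states": len(c.supporting_states),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "direction", "state_a", "state_b",
            "q", "f0", "f1", "n_supporting_states",
        ],
    )


def summarize_calls(calls: list[DifferentialPPI]) -> dict[str, int]:
    """Per-direction and distinct-edge tallies of a call set.

    Reported separately because an edge can be called in both directions,
    so the per-direction counts need not sum to the distinct-edge count.
    """
    return {
        "n_activated": sum(c.direction == ACTIVATED for c in calls),
        "n_repressed": sum(c.direction == REPRESSED for c in calls),
        "n_distinct_edges": len({c.edge for c in calls}),
    }
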