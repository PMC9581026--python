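"""Independent oracles used across the test suite.

These deliberately avoid the package's vectorized code paths: counts are
re-derived by explicit per-sample loops, hypergeometric tails by exhaustive
subset enumeration, and q by the plain formula on Python floats.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from diffint.io import ExpressionDataset, InteractionNetwork, NORMAL, TUMOR


def naive_state_counts(dm, net):
    """Per-(edge, state) counts by a plain loop over samples."""
    gidx = {g: i for i, g in enumerate(dm.gene_ids)}
    counts = {}
    for edge in net.edges:
        a, b = edge
        if a not in gidx or b not in gidx:
            continue
        for la in (-1, 0, 1):
            for lb in (-1, 0, 1):
                counts[(edge, (la, lb))] = [0, 0]
        for j, pheno in enumerate(dm.phenotype):
            state = (int(dm.levels[gidx[a], j]), int(dm.levels[gidx[b], j]))
            counts[(edge, state)][0 if pheno == NORMAL else 1] += 1
    return {k: tuple(v) for k, v in counts.items()}


def naive_q(n0, n1, nn, nt):
    f0, f1 = n0 / nn, n1 / nt
    if f0 + f1 == 0:
        return None
    return f1 / (f0 + f1)


def naive_calls(counts, nn, nt, f_min=0.20, q_low=0.10, q_high=0.90):
    """Set of (edge, direction) calls recomputed from naive counts."""
    calls = set()
    for (edge, _state), (n0, n1) in counts.items():
        f0, f1 = n0 / nn, n1 / nt
        if f0 + f1 == 0:
            continue
        if max(f0, f1) <= f_min:
            continue
        # repressed is phrased through the complementary ratio so the rule
        # is exactly antisymmetric under phenotype exchange (see methods)
        if f1 / (f0 + f1) > q_high:
            calls.add((edge, "activated"))
        elif f0 / (f0 + f1) > 1.0 - q_low:
            calls.add((edge, "repressed"))
    return calls


def enum_hypergeom_tail(N, K, n, k):
    """P[X >= k] by enumerating all C(N, n) draws of a size-n subset."""
    universe = range(N)
    reference = set(range(K))
    hits = sum(
        1 for draw in combinations(universe, n) if len(reference & set(draw)) >= k
    )
    return hits / comb(N, n)


def random_dataset(rng, n_genes=6, nn=4, nt=4):
    """A small random two-phenotype dataset with lognormal values."""
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(nn + nt)]
    values = np.exp(rng.normal(2.0, 0.7, size=(n_genes, nn + nt)))
    phenos = [NORMAL] * nn + [TUMOR] * nt
    return ExpressionDataset(genes, samples, values, phenos)


def random_network(rng, genes, n_edges):
    edges = set()
    genes = list(genes)
    while len(edges) < min(n_edges, comb(len(genes), 2)):
        a, b = rng.choice(len(genes), size=2, replace=False)
        edges.add(tuple(sorted((genes[a], genes[b]))))
    return InteractionNetwork(frozenset(edges))


def swap_labels(ds: ExpressionDataset) -> ExpressionDataset:
    flipped = [TUMOR if p == NORMAL else NORMAL for p in ds.phenotype]
    return ExpressionDataset(ds.gene_ids, ds.sample_ids, ds.values.copy(), flipped)
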