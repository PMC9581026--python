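import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffint.differential import (
    ACTIVATED,
    REPRESSED,
    StateCountRecord,
    call_differential_ppis,
    compute_q,
    count_joint_states,
    dppis_to_frame,
    summarize_calls,
)
from diffint.discretize import DiscretizedMatrix, discretize
from diffint.io import InteractionNetwork

from helpers import (
    naive_calls,
    naive_state_counts,
    random_dataset,
    random_network,
    swap_labels,
)


def _dm(levels_by_gene, phenotype):
    genes = sorted(levels_by_gene)
    n = len(phenotype)
    levels = np.array([levels_by_gene[g] for g in genes])
    return DiscretizedMatrix(genes, [f"s{i}" for i in range(n)], levels, phenotype)


class TestCountJointStates:
    def test_single_state_occupies_all_samples(self):
        dm = _dm({"A": [1] * 8, "B": [1] * 8}, ["normal"] * 3 + ["tumor"] * 5)
        recs = count_joint_states(dm, InteractionNetwork.from_pairs([("A", "B")]))
        assert len(recs) == 9
        by_state = {r.state: r for r in recs}
        assert (by_state[(1, 1)].n0, by_state[(1, 1)].n1) == (3, 5)
        assert all(
            r.n0 == 0 and r.n1 == 0 for r in recs if r.state != (1, 1)
        )

    def test_hand_counted_mixture(self):
        dm = _dm(
            {"A": [1, -1, 1, 1], "B": [1, 0, 1, 1]},
            ["normal", "normal", "tumor", "tumor"],
        )
        recs = count_joint_states(dm, InteractionNetwork.from_pairs([("A", "B")]))
        by_state = {r.state: (r.n0, r.n1) for r in recs}
        assert by_state[(1, 1)] == (1, 2)
        assert by_state[(-1, 0)] == (1, 0)

    def test_empty_network(self):
        dm = _dm({"A": [1, 1, 1, 1]}, ["normal"] * 2 + ["tumor"] * 2)
        assert count_joint_states(dm, InteractionNetwork(frozenset())) == []

    def test_missing_endpoint_skipped(self):
        dm = _dm({"A": [1, 1, 1, 1]}, ["normal"] * 2 + ["tumor"] * 2)
        net = InteractionNetwork.from_pairs([("A", "Z")])
        assert count_joint_states(dm, net) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_partition_each_phenotype(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_genes=6, nn=3, nt=5)
        dm = discretize(ds, 0.5)
        net = random_network(rng, ds.gene_ids, 7)
        recs = count_joint_states(dm, net)
        for edge in net.edges:
            edge_recs = [r for r in recs if r.edge == edge]
            assert sum(r.n0 for r in edge_recs) == 3
            assert sum(r.n1 for r in edge_recs) == 5


class TestComputeQ:
    def test_absent_in_normal_forces_one(self):
        assert compute_q(StateCountRecord(("A", "B"), (1, 1), 0, 3, 10, 10)) == 1.0

    def test_equal_frequencies_give_half(self):
        rec = StateCountRecord(("A", "B"), (0, 0), 4, 8, 10, 20)  # f0 = f1 = 0.4
        assert compute_q(rec) == pytest.approx(0.5)

    def test_worked_value(self):
        rec = StateCountRecord(("A", "B"), (1, 1), 2, 10, 10, 20)
        assert compute_q(rec) == pytest.approx(0.5 / 0.7, abs=1e-6)

    def test_undefined_when_state_never_observed(self):
        assert compute_q(StateCountRecord(("A", "B"), (1, 1), 0, 0, 10, 10)) is None

    def test_requires_nonempty_groups(self):
        with pytest.raises(ValueError):
            compute_q(StateCountRecord(("A", "B"), (1, 1), 0, 1, 0, 10))

    @given(
        n0=st.integers(0, 10),
        n1=st.integers(0, 20),
        delta=st.integers(1, 5),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_counts(self, n0, n1, delta):
        """q increases with N1 at fixed N0 and decreases with N0 at fixed N1."""
        def q(a, b):
            return compute_q(StateCountRecord(("A", "B"), (1, 1), a, b, 10, 20))

        base = q(n0, n1)
        if base is None:
            return
        assert 0.0 <= base <= 1.0
        up = q(n0, min(n1 + delta, 20))
        if up is not None and n1 + delta <= 20:
            assert up >= base
        down = q(min(n0 + delta, 10), n1)
        if down is not None and n0 + delta <= 10:
            assert down <= base


def _rec(n0, n1, nn=100, nt=100):
    return StateCountRecord(("A", "B"), (1, 1), n0, n1, nn, nt)


class TestCallDifferentialPPIs:
    def test_tumor_specific_state_is_activated(self):
        calls = call_differential_ppis([_rec(0, 25)])  # f1=0.25, q=1
        assert [(c.edge, c.direction) for c in calls] == [(("A", "B"), ACTIVATED)]

    def test_balanced_state_not_called(self):
        assert call_differential_ppis([_rec(50, 50)]) == []

    def test_rare_state_below_frequency_floor_not_called(self):
        # q ~ 0.0625 < 0.10 but max frequency 0.15 fails the 20% floor
        calls = call_differential_ppis([_rec(15, 1)])
        assert calls == []

    def test_thresholds_are_strict(self):
        # exactly at the floor (f=0.20) and exactly at q=0.90: no call
        assert call_differential_ppis([_rec(0, 20)]) == []
        rec = _rec(10, 90)  # q = 0.9 exactly
        assert compute_q(rec) == pytest.approx(0.9)
        assert call_differential_ppis([rec]) == []

    def test_edge_can_carry_both_directions(self):
        recs = [
            StateCountRecord(("A", "B"), (1, 1), 0, 30, 100, 100),
            StateCountRecord(("A", "B"), (-1, -1), 30, 0, 100, 100),
        ]
        calls = call_differential_ppis(recs)
        assert {c.direction for c in calls} == {ACTIVATED, REPRESSED}
        assert summarize_calls(calls) == {
            "n_activated": 1, "n_repressed": 1, "n_distinct_edges": 1,
        }

    def test_best_state_is_most_extreme(self):
        recs = [
            StateCountRecord(("A", "B"), (1, 1), 2, 30, 100, 100),
            StateCountRecord(("A", "B"), (1, 0), 0, 25, 100, 100),
        ]
        (call,) = call_differential_ppis(recs)
        assert call.best_state.state == (1, 0)  # q = 1 beats q < 1
        df = dppis_to_frame([call])
        assert df.loc[0, "q"] == 1.0


class TestOracleEquivalence:
    """Naive per-sample recount reproduces all counts, q values, and calls."""

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_recount(self, seed):
        rng = np.random.default_rng(seed)
        nn, nt = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        ds = random_dataset(rng, n_genes=int(rng.integers(4, 8)), nn=nn, nt=nt)
        net = random_network(rng, ds.gene_ids, int(rng.integers(1, 11)))
        dm = discretize(ds, 0.5)

        recs = count_joint_states(dm, net)
        oracle_counts = naive_state_counts(dm, net)
        assert len(recs) == 9 * len(net.edges)
        for r in recs:
            n0, n1 = oracle_counts[(r.edge, r.state)]
            assert (r.n0, r.n1) == (n0, n1)

        calls = call_differential_ppis(recs)
        assert {(c.edge, c.direction) for c in calls} == naive_calls(
            oracle_counts, nn, nt
        )


class TestLabelSwapAntisymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_swap_maps_q_to_one_minus_q_and_flips_calls(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_genes=8, nn=5, nt=7)
        net = random_network(rng, ds.gene_ids, 10)
        dm = discretize(ds, 0.5)
        dm_sw = discretize(swap_labels(ds), 0.5)

        recs = {(r.edge, r.state): r for r in count_joint_states(dm, net)}
        recs_sw = {(r.edge, r.state): r for r in count_joint_states(dm_sw, net)}
        for key, r in recs.items():
            q, q_sw = compute_q(r), compute_q(recs_sw[key])
            if q is None:
                assert q_sw is None
            else:
                assert q_sw == pytest.approx(1.0 - q, abs=1e-12)

        calls = {(c.edge, c.direction) for c in
                 call_differential_ppis(list(recs.values()))}
        calls_sw = {(c.edge, c.direction) for c in
                    call_differential_ppis(list(recs_sw.values()))}
        flip = {ACTIVATED: REPRESSED, REPRESSED: ACTIVATED}
        assert calls_sw == {(e, flip[d]) for e, d in calls}
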