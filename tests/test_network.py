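"""SRI construction, community detection and weighted modularity."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from commrobust import (
    AssociationNetwork,
    ObservationStream,
    build_sri_network,
    detect_communities,
    modularity,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def modularity_pairwise(w: np.ndarray, labels) -> float:
    """Explicit Newman–Girvan double sum: (1/2m) Σ_ij (w_ij − k_i k_j / 2m) δ_ij."""
    labels = np.asarray(labels)
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield part + [[first]]


def best_partition_bruteforce(net):
    best_q, best = -1.0, None
    for part in set_partitions(list(range(net.n))):
        labels = {}
        for ci, block in enumerate(part):
            for i in block:
                labels[net.roster[i]] = ci
        q = modularity_pairwise(net.weights, [labels[r] for r in net.roster])
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def random_network(rng, n=8, density=0.5):
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.random()
    return AssociationNetwork([f"n{k}" for k in range(n)], w)


# ---------------------------------------------------------------------------
# SRI
# ---------------------------------------------------------------------------

class TestSri:
    def test_worked_example(self, four_group_stream):
        net = build_sri_network(four_group_stream)
        i = {r: k for k, r in enumerate(net.roster)}
        assert net.weights[i["A"], i["B"]] == pytest.approx(0.5)  # 2/(2+0+1+1)
        assert net.weights[i["A"], i["C"]] == 0.0  # 0/3: C never observed with A

    def test_always_together_pair_is_one(self):
        s = ObservationStream([{"A", "B"}] * 5, ["A", "B"], "group")
        assert build_sri_network(s).weights[0, 1] == 1.0

    def test_period_mode_counts_copresence_without_association(self):
        # period 1: A-B associate; period 2: A-C and B-C associate but A-B do not,
        # so period 2 contributes a y_ij term to the A-B denominator.
        m1 = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        m2 = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        s = ObservationStream([m1, m2], ["A", "B", "C"], "period")
        net = build_sri_network(s)
        assert net.weights[0, 1] == pytest.approx(1 / 2)  # x=1, y_ij=1
        assert net.weights[0, 2] == pytest.approx(1 / 2)  # x=1 (p2), y_i=1 (p1)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_sri_network(ObservationStream([], ["A"], "group"))

    def test_permutation_equivariance(self, rng=np.random.default_rng(3)):
        units = [set(np.random.default_rng(s).choice(list("ABCDE"), size=2, replace=False))
                 for s in range(12)]
        s1 = ObservationStream(units, list("ABCDE"), "group")
        perm = ["C", "A", "E", "B", "D"]
        s2 = ObservationStream(units, perm, "group")
        n1, n2 = build_sri_network(s1), build_sri_network(s2)
        idx = [s1.roster.index(r) for r in perm]
        assert np.allclose(n2.weights, n1.weights[np.ix_(idx, idx)])

    def test_duplicating_every_unit_leaves_sri_unchanged(self, four_group_stream):
        doubled = ObservationStream(
            four_group_stream.units * 2, four_group_stream.roster, "group"
        )
        assert np.allclose(
            build_sri_network(doubled).weights,
            build_sri_network(four_group_stream).weights,
        )


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

class TestDetectCommunities:
    def test_two_cliques_match_bruteforce_optimum(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        net = AssociationNetwork(list("abcdef"), w)
        part = detect_communities(net)
        best_q, best_blocks = best_partition_bruteforce(net)
        assert part.c == 2
        assert {frozenset(r for r in net.roster if part.labels[r] == k) for k in range(2)} == {
            frozenset("abc"), frozenset("def"),
        }
        assert part.Q == pytest.approx(best_q)
        assert sorted(map(len, best_blocks)) == [3, 3]

    def test_complete_graph_is_one_community(self):
        w = np.ones((5, 5)) - np.eye(5)
        part = detect_communities(AssociationNetwork(list("abcde"), w))
        best_q, best_blocks = best_partition_bruteforce(AssociationNetwork(list("abcde"), w))
        assert part.c == 1
        assert len(best_blocks) == 1 and part.Q == pytest.approx(best_q) == pytest.approx(0.0)

    def test_isolate_becomes_singleton_community(self):
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            w[a, b] = w[b, a] = 1.0
        part = detect_communities(AssociationNetwork(list("abcd"), w))
        clique_label = part.labels["a"]
        assert part.labels["b"] == part.labels["c"] == clique_label
        assert part.labels["d"] != clique_label

    def test_single_node_and_edgeless_conventions(self):
        one = detect_communities(AssociationNetwork(["a"], np.zeros((1, 1))))
        assert (one.c, one.Q) == (1, 0.0)
        edgeless = AssociationNetwork(list("abc"), np.zeros((3, 3)))
        none = detect_communities(edgeless)
        assert none.c == 3 and none.Q == 0.0
        with pytest.warns(UserWarning, match="zero total weight"):
            assert modularity(edgeless, none.labels) == 0.0

    def test_partition_q_self_consistent(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_network(rng)
            part = detect_communities(net)
            assert part.Q == pytest.approx(modularity(net, part.labels), abs=1e-12)

    def test_deterministic_given_roster_order(self):
        rng = np.random.default_rng(9)
        net = random_network(rng, n=12)
        p1, p2 = detect_communities(net), detect_communities(net)
        assert p1.labels == p2.labels and p1.Q == p2.Q


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

class TestModularity:
    def test_two_disconnected_triangles(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        net = AssociationNetwork(list("abcdef"), w)
        labels = {r: 0 if r in "abc" else 1 for r in net.roster}
        # mixing matrix [[0.5, 0], [0, 0.5]] -> Q = 1 - 0.25 - 0.25
        assert modularity(net, labels) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        rng = np.random.default_rng(1)
        net = random_network(rng)
        assert modularity(net, {r: 0 for r in net.roster}) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_pairwise_oracle_and_igraph(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        labels = {r: int(rng.integers(0, 3)) for r in net.roster}
        q = modularity(net, labels)
        assert q == pytest.approx(modularity_pairwise(net.weights, [labels[r] for r in net.roster]), abs=1e-12)
        import igraph as ig
        iu, ju = np.triu_indices(net.n, k=1)
        mask = net.weights[iu, ju] > 0
        g = ig.Graph(net.n, list(zip(iu[mask].tolist(), ju[mask].tolist())))
        g.es["weight"] = net.weights[iu[mask], ju[mask]].tolist()
        assert q == pytest.approx(
            g.modularity([labels[r] for r in net.roster], weights="weight"), abs=1e-10
        )

    @given(st.integers(0, 1000))
    def test_invariant_under_label_permutation(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n=6)
        if net.weights.sum() == 0:
            return
        labels = {r: int(rng.integers(0, 3)) for r in net.roster}
        perm = {0: 2, 1: 0, 2: 1}
        relabeled = {r: perm[v] for r, v in labels.items()}
        assert modularity(net, labels) == pytest.approx(modularity(net, relabeled), abs=1e-12)

    def test_missing_label_rejected(self):
        net = random_network(np.random.default_rng(0))
        with pytest.raises(ValueError, match="missing"):
            modularity(net, {net.roster[0]: 0})
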