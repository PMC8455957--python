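"""Poisson distances, NJ exactness, bootstrap supports, Newick round trips."""

import collections

import numpy as np
import pytest

from hsp20pipe.phylogeny import (
    DistanceMatrix,
    assign_subfamilies,
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    newick_string,
    poisson_distance,
    poisson_distance_matrix,
    read_newick,
    write_newick,
)


class TestPoissonDistance:
    def test_identical_sequences_have_zero_distance(self):
        d, used = poisson_distance("ACDEF", "ACDEF")
        assert d == 0.0
        assert used == 5

    def test_ten_percent_mismatch_closed_form(self):
        d, _ = poisson_distance("A" * 9 + "C", "A" * 9 + "G")
        assert d == pytest.approx(0.105360516, abs=1e-9)

    def test_pairwise_deletion_ignores_gapped_columns_per_pair(self):
        # the gap column affects (a,c) site counts but not p for (a,b)
        a, b, c = "AAAAAC", "AAAAAG", "AAA-AC"
        d_ab, used_ab = poisson_distance(a, b)
        d_ab2, used_ab2 = poisson_distance(a[:5] + a[5], b)
        assert d_ab == d_ab2
        _, used_ac = poisson_distance(a, c)
        assert used_ac == 5 and used_ab == 6

    def test_all_gapped_pair_is_an_error(self):
        with pytest.raises(ValueError):
            poisson_distance("---", "AAA")


def random_additive_instance(n, rng):
    """Random binary tree with positive branch lengths; returns (ids, D).

    Built edge-by-edge, independent of the NJ code; pairwise path lengths
    give an additive matrix by construction.
    """
    ids = [f"L{i}" for i in range(n)]
    edges = {}

    def add(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    internal = [0]

    def new_internal():
        internal[0] += 1
        return f"I{internal[0]}"

    center = new_internal()
    for leaf in ids[:3]:
        add(center, leaf, rng.uniform(0.1, 1.0))
    for leaf in ids[3:]:
        pairs = [(a, b) for a in edges for b in edges[a] if a < b]
        a, b = pairs[rng.integers(0, len(pairs))]
        w = edges[a][b]
        mid = new_internal()
        del edges[a][b], edges[b][a]
        w1 = w * rng.uniform(0.2, 0.8)
        add(a, mid, w1)
        add(mid, b, w - w1)
        add(mid, leaf, rng.uniform(0.1, 1.0))
    D = np.zeros((n, n))
    for i, src in enumerate(ids):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in edges[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for j, dst in enumerate(ids):
            D[i, j] = dist[dst]
    return ids, D


def four_point_ok(D):
    """Four-point condition check — the independent additivity oracle."""
    n = D.shape[0]
    idx = range(n)
    for i in idx:
        for j in idx:
            for k in idx:
                for l in idx:
                    if len({i, j, k, l}) < 4:
                        continue
                    sums = sorted(
                        (D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k])
                    )
                    if not np.isclose(sums[1], sums[2]):
                        return False
    return True


class TestNeighborJoining:
    def test_exact_on_fifty_random_additive_matrices(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            ids, D = random_additive_instance(n, rng)
            assert four_point_ok(D)
            dm = DistanceMatrix(ids=ids, matrix=D, used_sites=np.full((n, n), 1))
            tree = neighbor_joining(dm)
            recovered = tree.tip_tip_distances()
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    assert recovered[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 4.0], [3.0, 4.0, 0.0]])
        dm = DistanceMatrix(ids=["a", "b", "c"], matrix=D,
                            used_sites=np.full((3, 3), 1))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_topology_invariant_to_taxon_permutation(self):
        rng = np.random.default_rng(7)
        ids, D = random_additive_instance(8, rng)
        dm = DistanceMatrix(ids=ids, matrix=D, used_sites=np.full((8, 8), 1))
        t1 = neighbor_joining(dm)
        perm = list(rng.permutation(8))
        ids_p = [ids[i] for i in perm]
        dm_p = DistanceMatrix(
            ids=ids_p, matrix=D[np.ix_(perm, perm)], used_sites=np.full((8, 8), 1)
        )
        t2 = neighbor_joining(dm_p)
        assert bipartitions(t1) == bipartitions(t2)

    def test_tree_length_invariant_to_leaf_relabeling(self):
        rng = np.random.default_rng(8)
        ids, D = random_additive_instance(7, rng)
        dm = DistanceMatrix(ids=ids, matrix=D, used_sites=np.full((7, 7), 1))
        t1 = neighbor_joining(dm)
        relabeled = [f"z{i}" for i in range(7)]
        dm2 = DistanceMatrix(ids=relabeled, matrix=D, used_sites=np.full((7, 7), 1))
        t2 = neighbor_joining(dm2)
        total1 = sum(n.length or 0 for n in t1.traverse() if n.length)
        total2 = sum(n.length or 0 for n in t2.traverse() if n.length)
        assert total1 == pytest.approx(total2)

    def test_non_finite_entry_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        dm = DistanceMatrix(ids=list("abc"), matrix=D,
                            used_sites=np.full((3, 3), 1))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(ids=["a", "b"], matrix=np.zeros((2, 2)),
                            used_sites=np.full((2, 2), 1))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


def _saturated_alignment():
    """Ten concatenated copies of an unambiguous, conflict-free signal."""
    signal = {
        "A": "AAAAA" + "C" + "T" + "GGG",
        "B": "AAAAA" + "G" + "T" + "GGG",
        "C": "TTTTT" + "T" + "C" + "GGG",
        "D": "TTTTT" + "T" + "G" + "GGG",
    }
    return {k: v * 10 for k, v in signal.items()}


class TestBootstrap:
    def test_unambiguous_signal_saturates_all_supports(self):
        tree = bootstrap_support(_saturated_alignment(), n_replicates=200, seed=5)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_are_percentages(self, sim, calibrated_profile):
        from hsp20pipe.profile_hmm import score_with_traceback

        fam = sim.manifest.family_gene_ids[:8]
        aln = {
            g: score_with_traceback(calibrated_profile, sim.proteins[g])[3]
            for g in fam
        }
        tree = bootstrap_support(aln, n_replicates=50, seed=2)
        for node in tree.non_tips():
            if hasattr(node, "support"):
                assert 0.0 <= node.support <= 100.0

    def test_fixed_seed_reproduces_supports(self):
        aln = _saturated_alignment()
        t1 = bootstrap_support(aln, n_replicates=100, seed=3)
        t2 = bootstrap_support(aln, n_replicates=100, seed=3)
        assert newick_string(t1) == newick_string(t2)


def test_newick_round_trip_is_byte_stable(tmp_path):
    rng = np.random.default_rng(4)
    ids, D = random_additive_instance(6, rng)
    dm = DistanceMatrix(ids=ids, matrix=D, used_sites=np.full((6, 6), 1))
    tree = neighbor_joining(dm)
    p1 = tmp_path / "t1.nwk"
    p2 = tmp_path / "t2.nwk"
    write_newick(tree, p1)
    write_newick(read_newick(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_reference_guided_subfamily_labels_follow_nearest_reference():
    rng = np.random.default_rng(10)
    ids, D = random_additive_instance(6, rng)
    dm = DistanceMatrix(ids=ids, matrix=D, used_sites=np.full((6, 6), 1))
    tree = neighbor_joining(dm)
    refs = {ids[0]: "CI", ids[1]: "P"}
    labels = assign_subfamilies(tree, refs)
    assert set(labels) == set(ids)
    assert labels[ids[0]] == "CI" and labels[ids[1]] == "P"
    td = tree.tip_tip_distances()
    for tip in ids[2:]:
        nearest = min(refs, key=lambda r: (td[tip, r], r))
        assert labels[tip] == refs[nearest]
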