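import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkscan import (
    AlignedFamily,
    DistanceMatrix,
    bootstrap_support,
    generate_family,
    nj_tree,
    pairwise_p_distance,
    poisson_correct,
    poisson_distance_matrix,
    read_newick,
    two_class_config,
    write_newick,
)
from linkscan.errors import IncomparablePairError, SaturationError
from linkscan.phylo import bipartitions


# ---------------------------------------------------------------------------
# oracle: random additive trees built by edge subdivision
# ---------------------------------------------------------------------------


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as (adjacency, leaf names).

    Returns an adjacency dict node -> {neighbor: branch_length} whose leaf
    distances are additive by construction.
    """
    adj = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    leaves = [f"t{i}" for i in range(n_taxa)]
    lengths = iter(rng.uniform(0.05, 0.9, size=4 * n_taxa))
    connect(leaves[0], "v0", next(lengths))
    connect(leaves[1], "v0", next(lengths))
    connect(leaves[2], "v0", next(lengths))
    v = 1
    for leaf in leaves[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = f"v{v}"
        v += 1
        disconnect(a, b)
        split = w * rng.uniform(0.2, 0.8)
        connect(a, mid, split)
        connect(b, mid, w - split)
        connect(leaf, mid, next(lengths))
    return adj, leaves


def path_distance(adj, a, b):
    stack = [(a, None, 0.0)]
    while stack:
        node, prev, dist = stack.pop()
        if node == b:
            return dist
        for nb, w in adj[node].items():
            if nb != prev:
                stack.append((nb, node, dist + w))
    raise AssertionError("disconnected")


def oracle_edges(adj, leaves):
    """Map bipartition/leaf-name -> branch length from the adjacency oracle."""
    anchor = min(leaves)
    out = {}
    for a in adj:
        for b, w in adj[a].items():
            if a > b:
                continue
            # leaves reachable from b without crossing a
            seen = set()
            stack = [(b, a)]
            while stack:
                node, prev = stack.pop()
                if node in leaves:
                    seen.add(node)
                for nb in adj[node]:
                    if nb != prev:
                        stack.append((nb, node))
            side = frozenset(seen)
            if len(side) == 1:
                out[next(iter(side))] = w
            elif len(side) == len(leaves) - 1:
                out[next(iter(frozenset(leaves) - side))] = w
            elif 2 <= len(side) <= len(leaves) - 2:
                if anchor in side:
                    side = frozenset(leaves) - side
                out[side] = w
    return out


def tree_edges(tree):
    """Same map extracted from an NJ Clade tree."""
    leaves = frozenset(tree.leaves())
    anchor = min(leaves)
    out = {}

    def visit(clade):
        if clade.is_leaf:
            out[clade.name] = out.get(clade.name, 0.0) + clade.length
            return frozenset([clade.name])
        below = frozenset().union(*(visit(ch) for ch in clade.children))
        if clade is not tree and 2 <= len(below) <= len(leaves) - 2:
            side = leaves - below if anchor in below else below
            out[side] = out.get(side, 0.0) + clade.length
        elif clade is not tree and len(below) == len(leaves) - 1:
            # edge equivalent to the missing leaf's pendant edge
            other = next(iter(leaves - below))
            out[other] = out.get(other, 0.0) + clade.length
        return below

    visit(tree)
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestPDistance:
    def test_identical_sequences(self):
        assert pairwise_p_distance("KTIAK", "KTIAK") == (0.0, 5)

    def test_pairwise_deletion_rule(self):
        # only columns with residues in both sequences count
        p, n = pairwise_p_distance("KTI-A", "KTIA-")
        assert (p, n) == (0.0, 3)

    def test_hand_counted_mismatch_fraction(self):
        # 10 columns; cols 9-10 dropped (gap / X), 8 shared, 1 mismatch (I vs L)
        p, n = pairwise_p_distance("KTIAKTIA--", "KTIAKTLAKX")
        assert n == 8
        assert p == pytest.approx(0.125)

    def test_incomparable_pair(self):
        with pytest.raises(IncomparablePairError):
            pairwise_p_distance("K---", "-TIA")

    def test_ambiguity_excluded(self):
        p, n = pairwise_p_distance("KXTA", "KKTA")
        assert (p, n) == (0.0, 3)


class TestPoissonCorrection:
    def test_closed_form(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(0.1) == pytest.approx(-np.log(0.9), rel=1e-12)

    def test_domain_boundary(self):
        with pytest.raises(SaturationError):
            poisson_correct(1.0)
        with pytest.raises(SaturationError):
            poisson_correct(-0.1)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.floats(0.0, 0.98), st.floats(0.0, 0.98))
    def test_increasing_and_inflating(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert poisson_correct(lo) <= poisson_correct(hi)
        assert poisson_correct(hi) >= hi  # d >= p: correction inflates

    def test_agrees_with_identity_at_small_p(self):
        for p in [0.001, 0.005, 0.01]:
            assert poisson_correct(p) == pytest.approx(p, abs=1e-3)

    def test_convexity(self):
        grid = np.linspace(0.0, 0.9, 50)
        d = np.array([poisson_correct(p) for p in grid])
        assert np.all(np.diff(d, 2) > -1e-12)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(ids=["A", "B", "C"], d=d,
                                      n_sites=np.full((3, 3), 10)))
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_additive_matrix_round_trip(self, n_taxa, seed):
        """NJ recovers topology and exact branch lengths from additive input."""
        rng = np.random.default_rng(seed)
        adj, leaves = random_additive_tree(n_taxa, rng)
        d = np.zeros((n_taxa, n_taxa))
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                d[i, j] = d[j, i] = path_distance(adj, leaves[i], leaves[j])
        tree = nj_tree(DistanceMatrix(ids=leaves, d=d,
                                      n_sites=np.full((n_taxa, n_taxa), 100)))
        want = oracle_edges(adj, leaves)
        got = tree_edges(tree)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        adj, leaves = random_additive_tree(7, rng)
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = path_distance(adj, leaves[i], leaves[j])
        mine = nj_tree(DistanceMatrix(ids=leaves, d=d, n_sites=np.full((n, n), 100)))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=leaves))
        anchor = min(leaves)
        ref_bps = set()
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                if anchor in side:
                    side = frozenset(leaves) - side
                ref_bps.add(side)
        assert bipartitions(mine) == ref_bps

    def test_duplicate_taxa_join_as_zero_length_cherry(self):
        d = np.array([
            [0.0, 0.0, 0.4, 0.5],
            [0.0, 0.0, 0.4, 0.5],
            [0.4, 0.4, 0.0, 0.3],
            [0.5, 0.5, 0.3, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(ids=["A", "B", "C", "D"], d=d,
                                      n_sites=np.full((4, 4), 10)))
        edges = tree_edges(tree)
        assert edges["A"] == pytest.approx(0.0, abs=1e-12)
        assert edges["B"] == pytest.approx(0.0, abs=1e-12)
        assert frozenset(["C", "D"]) in bipartitions(tree) or \
            frozenset(["A", "B"]) in bipartitions(tree)

    def test_nonfinite_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=list("ABC"), d=d, n_sites=np.ones((3, 3))))


# ---------------------------------------------------------------------------
# bootstrap and newick
# ---------------------------------------------------------------------------


def _divergent_family(n_per_class=5, seed=13):
    cfg = two_class_config(n_per_class=n_per_class, seed=seed,
                           class_divergence=0.3, mutation_rate=0.02)
    fam, _ = generate_family(cfg)
    return fam


class TestBootstrap:
    def test_fixed_seed_reproducibility(self):
        fam = _divergent_family()
        t1, n1 = bootstrap_support(fam, n_reps=50, seed=4)
        t2, n2 = bootstrap_support(fam, n_reps=50, seed=4)
        assert n1 == n2
        assert write_newick(t1) == write_newick(t2)

    def test_class_split_strongly_supported(self):
        """Divergent consensus backbones make each class monophyletic with
        near-saturated support for the separating branch."""
        fam = _divergent_family()
        tree, _ = bootstrap_support(fam, n_reps=100, seed=4)
        class_side = frozenset(i for i in fam.ids if i.startswith("elongated"))
        anchor = min(fam.ids)
        if anchor in class_side:
            class_side = frozenset(fam.ids) - class_side
        bps = bipartitions(tree)
        assert class_side in bps
        supports = {}

        def visit(clade, leaves_all):
            if clade.is_leaf:
                return frozenset([clade.name])
            below = frozenset().union(*(visit(ch, leaves_all) for ch in clade.children))
            if clade.support is not None:
                side = leaves_all - below if anchor in below else below
                supports[side] = clade.support
            return below

        visit(tree, frozenset(fam.ids))
        assert supports[class_side] > 0.9

    def test_identical_sequences_give_no_support(self):
        fam = AlignedFamily(ids=["a", "b", "c", "d"], seqs=["KTIA"] * 4)
        tree, n_valid = bootstrap_support(fam, n_reps=20, seed=0)
        assert n_valid == 20

        # every branch has zero length: no supported internal structure
        def check(clade):
            assert clade.length == pytest.approx(0.0, abs=1e-12)
            for ch in clade.children:
                check(ch)
        for ch in tree.children:
            check(ch)


class TestNewick:
    def test_three_taxon_shape(self):
        d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
        tree = nj_tree(DistanceMatrix(ids=["A", "B", "C"], d=d,
                                      n_sites=np.full((3, 3), 5)))
        text = write_newick(tree)
        assert text.startswith("(") and text.endswith(");")
        assert {"A", "B", "C"} == set(read_newick(text).leaves())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_preserves_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        adj, leaves = random_additive_tree(6, rng)
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = path_distance(adj, leaves[i], leaves[j])
        tree = nj_tree(DistanceMatrix(ids=leaves, d=d, n_sites=np.full((n, n), 9)))
        back = read_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        got, want = tree_edges(back), tree_edges(tree)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-6)

    def test_percent_flag(self):
        fam = _divergent_family(n_per_class=3)
        tree, _ = bootstrap_support(fam, n_reps=10, seed=1)
        frac = write_newick(tree)
        pct = write_newick(tree, percent=True)
        assert frac != pct
        back = read_newick(pct)
        sups = []

        def collect(c):
            if c.support is not None:
                sups.append(c.support)
            for ch in c.children:
                collect(ch)
        collect(back)
        assert sups and all(0.0 <= s <= 100.0 for s in sups)
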