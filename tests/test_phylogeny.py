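"""K2P distances and neighbor-joining correctness."""

import itertools
import math

import numpy as np
import pytest

from mitocomp import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    k2p_distance,
    nj_tree,
    read_newick,
)
from mitocomp.phylogeny import SaturationError


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_example(self):
        # P = 0.1 (10 transitions), Q = 0.05 (5 transversions), 100 sites
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert k2p_distance(a, b) == pytest.approx(expected)
        assert round(expected, 4) == 0.1702

    def test_transversion_free_limit(self):
        # Q=0 reduces to the transitions-only form -1/2 ln(1-2P)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_gapped_sites_excluded_pairwise(self):
        assert k2p_distance("ACG-T", "ACGNT") == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(2)
        base = rng.choice(list("ACGT"), size=300)
        aln = {}
        for i in range(4):
            seq = base.copy()
            mut = rng.random(300) < 0.1
            seq[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
            aln[f"t{i}"] = "".join(seq)
        dm = distance_matrix(aln)
        for i, a in enumerate(dm.taxa):
            for j, b in enumerate(dm.taxa):
                if i < j:
                    assert dm.d[i, j] == pytest.approx(
                        k2p_distance(aln[a], aln[b]))


def random_additive_tree(rng, n):
    """Random unrooted binary tree with branch lengths; returns (taxa,
    path-length matrix, bipartition set)."""
    taxa = [f"t{i}" for i in range(n)]
    # start from a star over 3 leaves, attach remaining leaves to random edges
    nodes = {t: {"parent": None} for t in taxa}
    # simpler: build via random sequential clustering and compute distances
    # through explicit adjacency
    adj = {}

    def connect(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    pool = list(taxa)
    rng.shuffle(pool)
    internal = 0
    while len(pool) > 2:
        a = pool.pop()
        b = pool.pop()
        new = f"i{internal}"
        internal += 1
        connect(a, new, rng.uniform(0.1, 1.0))
        connect(b, new, rng.uniform(0.1, 1.0))
        pool.append(new)
    connect(pool[0], pool[1], rng.uniform(0.1, 1.0))

    def path_lengths(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        dist = path_lengths(a)
        for j, b in enumerate(taxa):
            d[i, j] = dist[b]

    # bipartitions: removing each internal edge splits the leaves
    bps = set()
    for u in adj:
        for v, _ in adj[u]:
            if u.startswith("i") and v.startswith("i"):
                # leaves on u's side without crossing v
                seen = {v, u}
                stack = [u]
                side = set()
                while stack:
                    x = stack.pop()
                    for y, _w in adj[x]:
                        if y in seen:
                            continue
                        seen.add(y)
                        if y.startswith("t"):
                            side.add(y)
                        stack.append(y)
                other = frozenset(taxa) - side
                if len(side) >= 2 and len(other) >= 2:
                    bps.add(min(frozenset(side), other,
                                key=lambda s: (len(s), sorted(s))))
    return taxa, d, bps


def ls_topology_oracle(taxa, d):
    """Four-point-condition oracle over the 3 unrooted 4-taxon topologies:
    the pairing (i,j)|(k,l) minimizing d(i,j) + d(k,l) is the generating
    split on additive data."""
    assert len(taxa) == 4
    best, best_score = None, np.inf
    for i, j in itertools.combinations(range(4), 2):
        k, l = [x for x in range(4) if x not in (i, j)]
        score = d[i, j] + d[k, l]
        if score < best_score:
            best_score = score
            best = frozenset({taxa[i], taxa[j]})
    return best


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {c.name: c.length for c in t.children}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):3,C:4,D:5) -> additive distances
        d = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], float)
        taxa = ["A", "B", "C", "D"]
        t = nj_tree(DistanceMatrix(taxa, d))
        assert t.bipartitions() == {frozenset({"A", "B"})}
        assert t.bipartitions() == {ls_topology_oracle(taxa, d)}
        # branch lengths recovered exactly
        path = _leaf_path_lengths(t)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert path[(a, b)] == pytest.approx(d[i, j])

    def test_additive_matrices_recovered_exactly(self):
        """NJ reconstructs the generating topology for random additive
        matrices up to 8 taxa."""
        rng = np.random.default_rng(31)
        for n in (4, 5, 6, 7, 8):
            for _ in range(5):
                taxa, d, bps = random_additive_tree(rng, n)
                t = nj_tree(DistanceMatrix(taxa, d))
                assert t.bipartitions() == bps
                path = _leaf_path_lengths(t)
                for i, a in enumerate(taxa):
                    for j, b in enumerate(taxa):
                        if i < j:
                            assert path[(a, b)] == pytest.approx(d[i, j])

    def test_ultrametric_matches_upgma(self):
        rng = np.random.default_rng(8)
        # ultrametric from a rooted tree with equal tip depths:
        # ((a,b),(c,(d,e))) with merge heights 1, 2, 3, 4
        taxa = list("abcde")
        h = {("a", "b"): 1, ("d", "e"): 2, ("c", "d"): 3, ("c", "e"): 3,
             ("a", "c"): 4, ("a", "d"): 4, ("a", "e"): 4,
             ("b", "c"): 4, ("b", "d"): 4, ("b", "e"): 4}
        d = np.zeros((5, 5))
        for (x, y), v in h.items():
            i, j = taxa.index(x), taxa.index(y)
            d[i, j] = d[j, i] = 2 * v
        nj = nj_tree(DistanceMatrix(taxa, d))
        upgma_bps = _upgma_bipartitions(taxa, d)
        assert nj.bipartitions() == upgma_bps

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_newick_roundtrip(self):
        d = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], float)
        t = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        back = read_newick(t.to_newick())
        assert back.bipartitions() == t.bipartitions()
        orig = sorted((lf.name, round(lf.length, 6)) for lf in t.leaves())
        rt = sorted((lf.name, round(lf.length, 6)) for lf in back.leaves())
        assert rt == orig


def _leaf_path_lengths(tree):
    out = {}
    leaves = tree.leaves()

    def paths(node, acc):
        acc = acc + [(node, node.length or 0.0)]
        if node.is_leaf:
            yield node, acc
        for c in node.children:
            yield from paths(c, acc)

    routes = {leaf.name: {id(n) for n, _ in acc}
              for leaf, acc in paths(tree, [])}
    lengths = {leaf.name: acc for leaf, acc in paths(tree, [])}
    for a, b in itertools.combinations(sorted(l.name for l in leaves), 2):
        shared = routes[a] & routes[b]
        total = sum(w for n, w in lengths[a] if id(n) not in shared)
        total += sum(w for n, w in lengths[b] if id(n) not in shared)
        out[(a, b)] = total
    return out


def _upgma_bipartitions(taxa, d):
    """Tiny UPGMA (average linkage) — bipartitions only."""
    clusters = {t: frozenset({t}) for t in taxa}
    dd = {(a, b): d[taxa.index(a), taxa.index(b)]
          for a in taxa for b in taxa if a < b}
    labels = list(taxa)
    sizes = {t: 1 for t in taxa}
    bps = set()
    step = 0
    while len(labels) > 1:
        (a, b) = min(
            ((x, y) for i, x in enumerate(labels) for y in labels[i + 1:]),
            key=lambda p: dd[tuple(sorted(p))],
        )
        new = f"u{step}"
        step += 1
        merged = clusters[a] | clusters[b]
        clusters[new] = merged
        if 2 <= len(merged) <= len(taxa) - 2:
            other = frozenset(taxa) - merged
            bps.add(min(merged, other, key=lambda s: (len(s), sorted(s))))
        for c in labels:
            if c in (a, b):
                continue
            key_ac = tuple(sorted((a, c)))
            key_bc = tuple(sorted((b, c)))
            val = (dd[key_ac] * sizes[a] + dd[key_bc] * sizes[b]) / (
                sizes[a] + sizes[b])
            dd[tuple(sorted((new, c)))] = val
        sizes[new] = sizes[a] + sizes[b]
        labels = [x for x in labels if x not in (a, b)] + [new]
    return bps


class TestBootstrap:
    def test_fixed_split_gets_full_support(self):
        # two clades separated by 50 fixed differences over 200 sites
        base = "A" * 150
        aln = {
            "a1": base + "A" * 50, "a2": base + "A" * 50,
            "b1": base + "G" * 50, "b2": base + "G" * 50,
        }
        # add a little within-clade noise so distances are not degenerate
        aln["a2"] = "C" + aln["a2"][1:]
        aln["b2"] = "C" + aln["b2"][1:]
        tree, dropped = bootstrap_support(aln, reps=50, seed=0)
        assert dropped == 0
        sup = [n.support for n in tree.walk() if n.support is not None]
        assert sup and all(s == 100.0 for s in sup)

    def test_identical_sequences_give_star(self):
        aln = {f"t{i}": "ACGT" * 50 for i in range(4)}
        tree, _ = bootstrap_support(aln, reps=10, seed=0)
        # zero-length star: any bipartition present carries no support signal
        assert all(
            (c.length or 0.0) == 0.0 for c in tree.walk() if c is not tree
        )

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), size=400)
        aln = {}
        for i in range(5):
            seq = base.copy()
            mut = rng.random(400) < 0.1
            seq[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
            aln[f"t{i}"] = "".join(seq)
        t1, _ = bootstrap_support(aln, reps=20, seed=7)
        t2, _ = bootstrap_support(aln, reps=20, seed=7)
        assert t1.to_newick() == t2.to_newick()
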