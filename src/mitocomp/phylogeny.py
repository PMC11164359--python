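"""K2P distances, neighbor-joining tree construction, and bootstrap support.

The Kimura two-parameter distance separates transition (P) and transversion
(Q) proportions: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).  Trees are
built by Saitou-Nei neighbor joining with the Studier-Keppler criterion
Q(i,j) = (r - 2) d(i,j) - R_i - R_j, which recovers the generating tree
exactly on additive distance matrices.  Bootstrap support is the percentage
of column-resampled replicate trees containing each bipartition of the
full-data tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "TreeNode", "k2p_distance", "distance_matrix",
    "nj_tree", "bootstrap_support", "read_newick",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distance undefined: substitution proportions exceed the model's range."""


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    """Node of an unrooted tree (represented with a nominal root, which is a
    trifurcation for unrooted NJ output).  ``length`` is the branch to the
    parent; ``support`` an optional bootstrap percentage on that branch."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    # -- newick ------------------------------------------------------------

    def to_newick(self, include_support: bool = True) -> str:
        return self._newick_part(include_support) + ";"

    def _newick_part(self, include_support: bool) -> str:
        if self.is_leaf:
            label = self.name or ""
        else:
            inner = ",".join(c._newick_part(include_support)
                             for c in self.children)
            label = f"({inner})"
            if include_support and self.support is not None:
                label += f"{self.support:g}"
            elif self.name:
                label += self.name
        if self.length is not None:
            label += f":{self.length:.6f}"
        return label

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical side's
        leaf set (complement-normalized against the full leaf set)."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Sites with a gap or ambiguity in either sequence are excluded pairwise.
    Raises :class:`SaturationError` when a log argument is non-positive.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    valid = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    if valid == 0:
        raise ValueError("no comparable sites")
    p, q = ts / valid, tv / valid
    a1, a2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(
            f"K2P distance saturated (P={p:.3f}, Q={q:.3f})"
        )
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_IS_PURINE = np.array([1, 0, 1, 0, 0], dtype=np.int8)  # A,C,G,T,other


def _encode_alignment(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = sorted(alignment)
    lengths = {len(alignment[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.stack([
        _BASE_CODE[np.frombuffer(alignment[t].encode(), dtype=np.uint8)]
        for t in taxa
    ])
    return taxa, mat


def _k2p_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    valid = (a < 4) & (b < 4)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no comparable sites")
    diff = valid & (a != b)
    ts = diff & (_IS_PURINE[a] == _IS_PURINE[b])
    p = int(ts.sum()) / n_valid
    q = (int(diff.sum()) - int(ts.sum())) / n_valid
    a1, a2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(
            f"K2P distance saturated (P={p:.3f}, Q={q:.3f})"
        )
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """All pairwise K2P distances of a multiple alignment."""
    taxa, mat = _encode_alignment(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _k2p_from_codes(mat[i], mat[j])
    return DistanceMatrix(taxa=taxa, d=d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Studier-Keppler criterion are broken by the
    lexicographically first taxon pair among current cluster labels, making
    the construction deterministic.  Negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    labels = list(dm.taxa)
    d = {
        (a, b): dm.get(a, b)
        for i, a in enumerate(labels) for b in labels[i + 1:]
    }

    def dist(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    step = 0
    while len(labels) > 3:
        r = len(labels)
        rowsum = {a: sum(dist(a, b) for b in labels) for a in labels}
        best = None
        best_q = math.inf
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (r - 2) * dist(a, b) - rowsum[a] - rowsum[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or key < best)
                ):
                    best_q = q
                    best = key
        a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb, f"{a}|{b}")
        parent_label = f"__nj{step}"
        step += 1
        parent = TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.children = [nodes[a], nodes[b]]
        nodes[parent_label] = parent
        new_d = {}
        for c in labels:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        labels = [x for x in labels if x not in (a, b)] + [parent_label]
        d = {
            (x, y): (
                new_d[x] if y == parent_label
                else new_d[y] if x == parent_label
                else dist(x, y)
            )
            for i, x in enumerate(labels) for y in labels[i + 1:]
        }
    # resolve the final three clusters as a trifurcating root
    a, b, c = labels
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = TreeNode(name=None)
    for label, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes[label]
        node.length = max(ln, 0.0)
        if ln < 0:
            log.info("negative terminal branch %.4g clamped to 0", ln)
        root.children.append(node)
    return root


def _clamp_pair(la: float, lb: float, where: str) -> tuple[float, float]:
    if la < 0:
        log.info("negative branch length %.4g at %s clamped; deficit moved "
                 "to sister", la, where)
        lb += la
        la = 0.0
    if lb < 0:
        log.info("negative branch length %.4g at %s clamped; deficit moved "
                 "to sister", lb, where)
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def bootstrap_support(
    alignment: dict[str, str],
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[TreeNode, int]:
    """NJ tree of the full alignment with bootstrap supports on internal
    branches.

    Columns are resampled with replacement per replicate; replicates whose
    distance matrix saturates are dropped (their count is returned).
    """
    if not alignment:
        raise ValueError("empty alignment")
    taxa, mat = _encode_alignment(alignment)
    tree = nj_tree(distance_matrix(alignment))
    target = tree.bipartitions()
    if not target:
        return tree, 0
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_sites = mat.shape[1]
    n = len(taxa)
    dropped = 0
    used = 0
    for _ in range(reps):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = mat[:, idx]
        try:
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = _k2p_from_codes(rep[i], rep[j])
            rep_tree = nj_tree(DistanceMatrix(taxa=list(taxa), d=d))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        used += 1
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if dropped:
        log.warning("%d of %d bootstrap replicates dropped (saturation)",
                    dropped, reps)
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = frozenset(tree.leaf_names()) - side
        if len(side) < 2 or len(other) < 2:
            continue
        bp = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts[bp] / used if used else None
    return tree, dropped


def read_newick(text_or_path, is_path: bool = False) -> TreeNode:
    """Parse a newick string (or file) into a :class:`TreeNode` tree."""
    import dendropy

    src = {"path": text_or_path} if is_path else {"data": text_or_path}
    dtree = dendropy.Tree.get(schema="newick", **src)

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else dnode.label,
            length=dnode.edge.length,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(dtree.seed_node)
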