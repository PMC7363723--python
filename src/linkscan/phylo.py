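"""Distance-based phylogenetics: Poisson-corrected NJ with column bootstrap.

Pairwise distances are computed on the alignment with *pairwise deletion*:
for each sequence pair, columns where either sequence carries a gap or the
ambiguity code X are dropped, and the proportion of differing sites p among
the remaining columns is converted to an expected number of amino acid
substitutions per site by the Poisson correction d = -ln(1 - p).

Trees are built with Saitou-Nei neighbor joining.  Ties in the Q criterion
are broken by the lexicographically smallest taxon-index pair and negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling branch, so tree construction is fully deterministic.  Branch support
comes from Felsenstein's nonparametric bootstrap: alignment columns are
resampled with replacement, the distance matrix and NJ tree are rebuilt per
replicate, and the support of each internal bipartition of the full-data
tree is the fraction of replicate trees containing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import IncomparablePairError, SaturationError
from .family import AMBIGUOUS, GAP, AlignedFamily

__all__ = [
    "DistanceMatrix",
    "Clade",
    "pairwise_p_distance",
    "poisson_correct",
    "p_distance_matrix",
    "poisson_distance_matrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-pair usable-site counts."""

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Clade:
    """Tree node; leaves carry names, internal edges carry supports."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def pairwise_p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Columns where either sequence has a gap or X are excluded; returns
    (p, number of compared sites).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(seq_a.encode("ascii"), dtype="S1")
    b = np.frombuffer(seq_b.encode("ascii"), dtype="S1")
    skip = np.isin(a, [GAP.encode(), AMBIGUOUS.encode()]) | \
        np.isin(b, [GAP.encode(), AMBIGUOUS.encode()])
    usable = ~skip
    n = int(usable.sum())
    if n == 0:
        raise IncomparablePairError("no unambiguous shared columns between the pair")
    mism = int(np.count_nonzero(a[usable] != b[usable]))
    return mism / n, n


def poisson_correct(p: float) -> float:
    """Poisson distance d = -ln(1 - p); strictly increasing and convex."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p must be in [0, 1), got {p}")
    return float(-np.log1p(-p))


def p_distance_matrix(family: AlignedFamily) -> DistanceMatrix:
    """All-pairs p-distance with pairwise deletion."""
    n = family.n_sequences
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = sum(1 for ch in family.seqs[i] if ch not in (GAP, AMBIGUOUS))
        for j in range(i + 1, n):
            p, m = pairwise_p_distance(family.seqs[i], family.seqs[j])
            d[i, j] = d[j, i] = p
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(ids=list(family.ids), d=d, n_sites=sites)


def poisson_distance_matrix(family: AlignedFamily) -> DistanceMatrix:
    """All-pairs Poisson-corrected distances (substitutions per site)."""
    pm = p_distance_matrix(family)
    d = np.zeros_like(pm.d)
    n = len(pm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(pm.d[i, j])
    return DistanceMatrix(ids=pm.ids, d=d, n_sites=pm.n_sites)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative estimate clamped to zero, deficit moved to the sibling branch
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> Clade:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    The pair minimising Q(i,j) = (N-2) d(i,j) - r_i - r_j is joined at each
    step; exact Q ties are broken by the smallest (i, j) taxon-index pair.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")

    nodes: list[Clade] = [Clade(name=t) for t in dm.ids]
    active = list(range(n))
    D = dm.d.copy()

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] or (q == best[0] and (i, j) < best[1:]):
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new = Clade(children=[nodes[i], nodes[j]])
        u = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point resolution of the last star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return Clade(children=[nodes[i], nodes[j], nodes[k]])


def bipartitions(tree: Clade) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically first leaf is returned as a frozenset.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    out: set[frozenset] = set()

    def visit(clade: Clade) -> frozenset:
        if clade.is_leaf:
            return frozenset([clade.name])
        below = frozenset().union(*(visit(ch) for ch in clade.children))
        if clade is not tree and 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if anchor in below else below
            out.add(side)
        return below

    visit(tree)
    return out


def _annotate_supports(tree: Clade, support: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)

    def visit(clade: Clade) -> frozenset:
        if clade.is_leaf:
            return frozenset([clade.name])
        below = frozenset().union(*(visit(ch) for ch in clade.children))
        if clade is not tree and 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if anchor in below else below
            clade.support = support.get(side, 0.0)
        return below

    visit(tree)


def bootstrap_support(family: AlignedFamily, n_reps: int = 1000, seed: int = 0,
                      correction: str = "poisson") -> tuple[Clade, int]:
    """NJ tree of the full alignment with column-bootstrap branch supports.

    Columns are resampled with replacement ``n_reps`` times; pairwise
    deletion (and saturation checks) are re-applied per replicate, and a
    replicate with an incomparable or saturated pair is dropped with a
    warning, shrinking the support denominator.  Returns the annotated tree
    and the number of valid replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    builder = poisson_distance_matrix if correction == "poisson" else p_distance_matrix
    tree = nj_tree(builder(family))

    rng = np.random.default_rng(seed)
    m = family.alignment_length
    mat = family.to_matrix()
    counts: dict[frozenset, int] = {}
    n_valid = 0
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        rep_seqs = ["".join(row) for row in mat[:, cols]]
        rep = AlignedFamily(ids=list(family.ids), seqs=rep_seqs, meta=family.meta)
        try:
            rep_tree = nj_tree(builder(rep))
        except (IncomparablePairError, SaturationError) as exc:
            warnings.warn(f"bootstrap replicate dropped: {exc}", stacklevel=2)
            continue
        n_valid += 1
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    if n_valid == 0:
        raise IncomparablePairError("every bootstrap replicate was dropped")
    support = {bp: c / n_valid for bp, c in counts.items()}
    _annotate_supports(tree, support)
    return tree, n_valid


def write_newick(tree: Clade, percent: bool = False) -> str:
    """Serialise with branch lengths and supports as internal-node labels."""

    def fmt(clade: Clade) -> str:
        if clade.is_leaf:
            return f"{clade.name}:{clade.length:.10g}"
        inner = ",".join(fmt(ch) for ch in clade.children)
        label = ""
        if clade.support is not None:
            label = f"{clade.support * 100:.4g}" if percent else f"{clade.support:.6g}"
        return f"({inner}){label}:{clade.length:.10g}"

    inner = ",".join(fmt(ch) for ch in tree.children)
    return f"({inner});"


def read_newick(text: str) -> Clade:
    """Parse a Newick string (internal labels read as supports in [0, 1])."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(node) -> Clade:
        if node.is_leaf():
            return Clade(name=node.taxon.label.replace(" ", "_"),
                         length=float(node.edge.length or 0.0))
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                pass
        return Clade(
            length=float(node.edge.length or 0.0),
            support=support,
            children=[convert(ch) for ch in node.child_nodes()],
        )

    return convert(dtree.seed_node)
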