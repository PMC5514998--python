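"""Expression trees over tissues.

Builds neighbor-joining (NJ) trees from expression-correlation distances,
attaches gene-resampling bootstrap supports, and derives the geometric
quantities that the phylogenetic covariance models consume: the shared
root-to-MRCA path matrix (the Brownian-motion covariance up to a rate
constant) and the patristic distance matrix (input to the
Ornstein-Uhlenbeck covariance).

Trees are held as rooted :class:`dendropy.Tree` objects inside a thin
:class:`TissueTree` wrapper. NJ itself is implemented here because the
pipeline requires a platform-independent deterministic tie-break (the
lexicographically smallest taxon-label pair among equal-minimum Q values)
and the Kuhner-Felsenstein treatment of negative branch-length estimates
(clamp to zero, transfer the deficit to the sibling edge so pairwise path
lengths are preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, TurnoverScanError

__all__ = [
    "TissueTree",
    "expression_distance",
    "neighbor_joining",
    "bootstrap_support",
    "shared_path_matrix",
    "patristic_matrix",
]

_Q_TIE_RTOL = 1e-12


@dataclass
class TissueTree:
    """A rooted tree over tissue labels with branch lengths.

    Parameters
    ----------
    tree:
        Rooted ``dendropy.Tree``; every leaf carries a taxon whose label is
        a tissue name, every edge (except possibly the root edge) has a
        non-negative length.
    supports:
        Optional bootstrap supports keyed by unrooted bipartition (the
        frozenset of tip labels on the side *not* containing the reference
        tip, i.e. the lexicographically smallest label).
    """

    tree: dendropy.Tree
    supports: dict[frozenset, float] | None = field(default=None)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_rooted_binary(self) -> bool:
        return self.tree.seed_node.num_child_nodes() == 2

    def to_newick(self) -> str:
        tree = self.tree
        if self.supports:
            tree = self.tree.clone(depth=1)
            _annotate_supports(tree, self.supports)
        return tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        ).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "TissueTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate tip labels in Newick tree")
        return cls(tree=tree)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "TissueTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    splits = _splits_with_nodes(tree)
    for split, node in splits.items():
        if split in supports:
            node.label = f"{supports[split]:.4g}"


def _normalize_split(below: frozenset, all_tips: frozenset, ref: str) -> frozenset:
    """Canonical unrooted bipartition: the side not containing ``ref``."""
    return frozenset(all_tips - below) if ref in below else below


def _splits_with_nodes(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_tips)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        split = _normalize_split(below, all_tips, ref)
        if 2 <= len(split) <= len(all_tips) - 2:
            out[split] = node
    return out


def unrooted_splits(ttree: TissueTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of the tree, canonically encoded."""
    return set(_splits_with_nodes(ttree.tree))


# ---------------------------------------------------------------------------
# distances


def expression_distance(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Correlation distance ``1 - corr`` between tissue expression profiles.

    ``profiles`` is a genes x tissues DataFrame. Returns a symmetric
    tissue x tissue DataFrame with zero diagonal, entries in [0, 2].
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if profiles.shape[1] < 4:
        raise ValueError("need at least 4 tissues for a tree-bound distance matrix")
    sds = profiles.std(axis=0, ddof=0)
    zero = sds[sds == 0.0]
    if len(zero):
        raise FormatError(
            "zero-variance tissue column(s): " + ", ".join(map(str, zero.index))
        )
    corr = profiles.corr(method=method)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return dist


# ---------------------------------------------------------------------------
# neighbor joining


def _check_distance_matrix(D: pd.DataFrame) -> None:
    vals = D.values
    if D.shape[0] != D.shape[1] or list(D.index) != list(D.columns):
        raise FormatError("distance matrix must be square with matching labels")
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise FormatError("distance matrix is not symmetric")
    if (vals < -1e-12).any():
        raise FormatError("distance matrix has negative entries")


def neighbor_joining(D: pd.DataFrame) -> TissueTree:
    """Saitou-Nei neighbor joining, midpoint-rooted.

    Uses the Studier-Keppler Q criterion with standard branch-length
    formulas. Exact on additive (tree-realizable) matrices. Negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sibling pendant edge. The returned tree is the unrooted NJ tree
    rooted by midpoint.
    """
    _check_distance_matrix(D)
    labels = list(D.index)
    n0 = len(labels)
    if n0 < 3:
        raise FormatError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    # sort key per active node: smallest tip label in its clade
    sortkey: dict[int, str] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes[i] = node
        sortkey[i] = lab

    d = D.values.astype(float).copy()
    active = list(range(n0))
    next_id = n0
    dist = {(i, j): d[i, j] for i in range(n0) for j in range(n0) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def put(i: int, j: int, v: float) -> None:
        dist[(i, j) if i < j else (j, i)] = v

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((sortkey[i], sortkey[j])))
                if best is None or q < best_q - _Q_TIE_RTOL * max(1.0, abs(best_q)):
                    best_q, best, best_key = q, (i, j), pair_key
                elif (
                    abs(q - best_q) <= _Q_TIE_RTOL * max(1.0, abs(best_q))
                    and pair_key < best_key
                ):
                    best, best_key = (i, j), pair_key
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # Kuhner-Felsenstein: clamp negatives, preserve the pair path length
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        sortkey[u] = min(sortkey[i], sortkey[j])
        for k in active:
            if k in (i, j):
                continue
            put(u, k, max(0.5 * (get(i, k) + get(j, k) - dij), 0.0))
        active = [k for k in active if k not in (i, j)] + [u]

    # closed-form 3-taxon star
    a, b, c = sorted(active, key=lambda k: sortkey[k])
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = True
    if n0 > 3:
        tree.reroot_at_midpoint(update_bipartitions=False)
    if tree.seed_node.edge.length:
        tree.seed_node.edge.length = None
    return TissueTree(tree=tree)


def bootstrap_support(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    method: str = "pearson",
    seed: int = 0,
) -> TissueTree:
    """NJ point-estimate tree with gene-resampling bootstrap supports.

    Genes (rows) are resampled with replacement ``n_boot`` times; the NJ
    tree is rebuilt each time and each internal edge of the point-estimate
    tree receives the fraction of replicates containing the same unrooted
    bipartition.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = neighbor_joining(expression_distance(profiles, method=method))
    target = unrooted_splits(point)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    n_genes = profiles.shape[0]
    values = profiles.values
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = pd.DataFrame(values[idx], columns=profiles.columns)
        try:
            btree = neighbor_joining(expression_distance(boot, method=method))
        except FormatError:  # degenerate resample; counts as non-support
            continue
        bsplits = unrooted_splits(btree)
        for s in target:
            if s in bsplits:
                counts[s] += 1
    point.supports = {s: counts[s] / n_boot for s in target}
    return point


# ---------------------------------------------------------------------------
# geometry


def _require_rooted(ttree: TissueTree) -> None:
    if not ttree.is_rooted_binary():
        raise TurnoverScanError(
            "tree is not rooted (root is not bifurcating); root it first, "
            "e.g. by midpoint rooting"
        )


def shared_path_matrix(ttree: TissueTree) -> pd.DataFrame:
    """Root-to-MRCA shared path lengths C[i, j]; C[i, i] is tip depth.

    This is the Brownian-motion trait covariance on the tree up to the
    rate constant sigma^2. Symmetric positive semidefinite.
    """
    _require_rooted(ttree)
    tree = ttree.tree
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = idx[node.taxon.label]
            below[id(node)] = [k]
            C[k, k] = depth[id(node)]
        else:
            kids = [below[id(ch)] for ch in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = depth[id(node)]
            below[id(node)] = [i for kid in kids for i in kid]
    return pd.DataFrame(C, index=labels, columns=labels)


def patristic_matrix(ttree: TissueTree) -> pd.DataFrame:
    """Pairwise path lengths (sums of branch lengths) between tips."""
    pdm = ttree.tree.phylogenetic_distance_matrix()
    taxa = {l.taxon.label: l.taxon for l in ttree.tree.leaf_node_iter()}
    labels = list(taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return pd.DataFrame(d, index=labels, columns=labels)
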