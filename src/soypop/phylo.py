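"""p-distances, neighbor-joining trees, bootstrap and clade queries.

Distances are genotype p-distances: per pair, the summed absolute
dosage difference over co-called sites divided by twice the number of
co-called sites, so identical samples score 0 and opposite homozygotes
everywhere score 1 (a heterozygote counts half a difference against a
homozygote).  Trees are built with the Saitou–Nei neighbor-joining
algorithm (deterministic smallest-index tie-break, branch lengths kept
as computed, including negatives) and serialised through dendropy;
branch support comes from the standard phylogenetic bootstrap over SNP
columns.  Monophyly and sister-group queries use the tree's
bipartitions, with sister groups read off the midpoint-rooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray  # symmetric, zero diagonal
    n_compared: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def p_distance_matrix(m: GenotypeMatrix, min_compared: int = 1) -> DistanceMatrix:
    """Pairwise genotype p-distances with a co-called-site floor."""
    calls = m.calls
    called = (calls != MISSING).astype(np.float64)
    n_comp = called @ called.T
    ind = [(calls == k).astype(np.float64) for k in (0, 1, 2)]
    diff = np.zeros_like(n_comp)
    for a in range(3):
        for b in range(3):
            if a != b:
                diff += abs(a - b) * (ind[a] @ ind[b].T)
    low = n_comp < min_compared
    np.fill_diagonal(low, False)
    if low.any():
        bad = [
            (m.samples[i], m.samples[j])
            for i, j in zip(*np.nonzero(np.triu(low, 1)))
        ]
        raise ValueError(f"pairs below min_compared={min_compared}: {bad[:10]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_comp > 0, diff / (2.0 * n_comp), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(m.samples), d=d, n_compared=n_comp.astype(int))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion break toward the smallest (i, j) pair in the
    current node order; the final three lineages join at an unrooted
    trifurcation.  Branch lengths are reported as computed (negative
    values possible and retained).
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("need at least 3 leaves")
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    # nb: an empty TaxonNamespace is falsy, so test against None explicitly
    tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    nodes = []
    for sid in dm.ids:
        nd = dendropy.Node(taxon=tns.require_taxon(label=sid))
        nodes.append(nd)
    D = dm.d.astype(float).copy()
    active = list(range(n0))
    # grow D as nodes are added
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: first minimum = smallest (i, j)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        bj = dij - bi
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        parent = dendropy.Node()
        ci, cj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = float(bi)
        cj.edge.length = float(bj)
        nodes.append(parent)
        # extend the distance matrix with the new node's row
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        keep = [a for x, a in enumerate(active) if x not in (i, j)]
        D[k, keep] = new_d[[x for x in range(n) if x not in (i, j)]]
        D[keep, k] = D[k, keep]
        active = keep + [k]
    # final trifurcation
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = float(ln)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartition_keys(tree: dendropy.Tree) -> dict:
    """Map internal (non-trivial) edges to orientation-free leaf-set keys."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    keys = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        key = side if ref not in side else leaves - side
        keys[node] = key
    return keys


def bootstrap_support(
    m: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    min_compared: int = 1,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from SNP-column resampling.

    Supports (percent of replicates containing each original internal
    bipartition) are stored as integer internal-node labels, the
    convention used for Newick export.
    """
    dm = p_distance_matrix(m, min_compared=min_compared)
    tree = nj_tree(dm)
    if n_reps <= 0:
        return tree
    keys = _bipartition_keys(tree)
    hits = {node: 0 for node in keys}
    rng = np.random.default_rng(seed)
    tns = tree.taxon_namespace
    for _ in range(n_reps):
        cols = rng.integers(m.n_snps, size=m.n_snps)
        mb = _take_resampled(m, cols)
        rep = nj_tree(p_distance_matrix(mb, min_compared=0), taxon_namespace=tns)
        rep_keys = set(_bipartition_keys(rep).values())
        for node, key in keys.items():
            if key in rep_keys:
                hits[node] += 1
    for node, h in hits.items():
        node.label = str(int(round(100.0 * h / n_reps)))
    return tree


# take_snps would reject the duplicate SNP ids a bootstrap draw creates;
# rename the resampled columns instead of loosening the core container.
def _take_resampled(m: GenotypeMatrix, cols: np.ndarray) -> GenotypeMatrix:
    snps = m.snps.iloc[cols].reset_index(drop=True).copy()
    snps["id"] = [f"bs{k}" for k in range(len(cols))]
    return GenotypeMatrix(list(m.samples), snps, m.calls[:, cols])


# ---------------------------------------------------------------------------
# clade queries
# ---------------------------------------------------------------------------

def is_monophyletic(tree: dendropy.Tree, leaf_subset) -> tuple[bool, set]:
    """Whether ``leaf_subset`` forms a clade; returns (flag, sister group).

    The sister group is the leaf set of the neighbouring clade across the
    subset's stem edge, read from the midpoint-rooted tree (rooting
    convention documented; NJ trees are otherwise unrooted).  A singleton
    subset is always monophyletic.
    """
    subset = frozenset(leaf_subset)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not subset or not subset < leaves:
        raise ValueError("subset must be a nonempty proper subset of the leaves")
    mono = len(subset) == 1 or any(
        key == subset or key == leaves - subset
        for key in _bipartition_keys(tree).values()
    )
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=True)
    taxa = [t for t in rooted.taxon_namespace if t.label in subset]
    mrca = rooted.mrca(taxa=taxa)
    sister: set = set()
    node = mrca
    while node.parent_node is not None and not sister:
        for sib in node.parent_node.child_nodes():
            if sib is not node:
                sister |= {l.taxon.label for l in sib.leaf_iter()}
        node = node.parent_node
    sister -= set(subset)
    return mono, sister


def clade_branch_lengths(tree: dendropy.Tree, clade_leaves) -> dict:
    """Mean terminal branch length of the clade's leaves and the stem
    length of the clade's MRCA on the midpoint-rooted tree."""
    clade = set(clade_leaves)
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=True)
    term = [
        l.edge.length or 0.0
        for l in rooted.leaf_node_iter()
        if l.taxon.label in clade
    ]
    taxa = [t for t in rooted.taxon_namespace if t.label in clade]
    mrca = rooted.mrca(taxa=taxa)
    stem = mrca.edge.length if mrca.parent_node is not None else 0.0
    return {
        "mean_terminal": float(np.mean(term)) if term else float("nan"),
        "stem": float(stem or 0.0),
    }


def compare_partition_trees(
    m: GenotypeMatrix,
    dom_snps,
    neutral_snps,
    focal_clades: dict,
    min_partition: int = 50,
) -> pd.DataFrame:
    """Trees from all / neutral-only / domestication-only SNP sets.

    Returns a tidy table of per-clade mean terminal branch length and
    stem length in each tree plus the pairwise Robinson–Foulds distances
    (stored in the frame's ``attrs['rf']``).
    """
    import warnings

    id_to_col = {sid: j for j, sid in enumerate(m.snp_ids)}
    dom_cols = [id_to_col[s] for s in dom_snps]
    neu_cols = [id_to_col[s] for s in neutral_snps]
    if not dom_cols or not neu_cols:
        raise ValueError("both SNP partitions must be nonempty")
    for name, cols in (("dom", dom_cols), ("neutral", neu_cols)):
        if len(cols) < min_partition:
            warnings.warn(
                f"{name} partition has only {len(cols)} SNPs; distances may be noisy"
            )
    tns = dendropy.TaxonNamespace()
    trees = {
        "all": nj_tree(p_distance_matrix(m), taxon_namespace=tns),
        "neutral": nj_tree(p_distance_matrix(m.take_snps(neu_cols)), taxon_namespace=tns),
        "dom": nj_tree(p_distance_matrix(m.take_snps(dom_cols)), taxon_namespace=tns),
    }
    rows = []
    for tree_name, tree in trees.items():
        for clade, members in focal_clades.items():
            bl = clade_branch_lengths(tree, members)
            rows.append(
                {
                    "tree": tree_name,
                    "clade": clade,
                    "mean_terminal": bl["mean_terminal"],
                    "stem": bl["stem"],
                }
            )
    out = pd.DataFrame(rows)
    from dendropy.calculate import treecompare

    names = list(trees)
    rf = {}
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            tx, ty = trees[x], trees[y]
            tx.encode_bipartitions()
            ty.encode_bipartitions()
            rf[(x, y)] = int(treecompare.symmetric_difference(tx, ty))
    out.attrs["rf"] = rf
    out.attrs["trees"] = trees
    return out


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
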