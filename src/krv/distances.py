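"""Beta-diversity dissimilarities and compositional transforms.

Implements rarefaction, Bray-Curtis, the UniFrac family (unweighted,
normalized weighted, generalized with exponent alpha) on a rooted tree, the
centered log-ratio (CLR) transform and the phylogenetic isometric log-ratio
(PhILR) transform.  Distances are returned as ``skbio.DistanceMatrix`` objects
over the table's sample ids.
"""

from __future__ import annotations

import zlib

import numpy as np
import skbio
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

from krv._fast import generalized_unifrac_pairs, weighted_unifrac_pairs
from krv.datatypes import CountTable, ValidationError
from krv.io import validate_tree


class TreeIndex:
    """Branch-level view of a rooted tree matched to a taxon ordering.

    Precomputes, for every branch (every non-root node), its length and the
    set of table taxa descending through it, so that branch-proportion
    matrices for UniFrac can be formed by a single sparse product.  Reusable
    across many count tables over the same taxa.
    """

    def __init__(self, tree: skbio.TreeNode, taxon_ids):
        tree = validate_tree(tree)
        self.taxon_ids = np.asarray(taxon_ids, dtype=object)
        leaf_pos = {}
        for leaf in tree.tips():
            leaf_pos[leaf.name] = leaf
        col = {str(t): i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in map(str, self.taxon_ids) if t not in leaf_pos]
        if missing:
            raise ValidationError(f"taxa absent from tree: {missing[:5]}")

        nodes = [node for node in tree.traverse(include_self=False)]
        node_idx = {id(node): b for b, node in enumerate(nodes)}
        self.lengths = np.array([node.length for node in nodes], dtype=float)
        self.n_branches = len(nodes)

        rows, cols = [], []
        for name, leaf in leaf_pos.items():
            if name not in col:
                continue  # tree may carry extra taxa; they never gain mass
            t = col[name]
            node = leaf
            while node.parent is not None:
                rows.append(t)
                cols.append(node_idx[id(node)])
                node = node.parent
        data = np.ones(len(rows))
        self.incidence = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.taxon_ids), self.n_branches)
        )
        self._nodes = nodes
        self._csc = None

    def branch_proportions(self, counts: np.ndarray) -> np.ndarray:
        """(n, B) matrix of the proportion of each sample's reads under each branch."""
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            bad = np.where(totals[:, 0] == 0)[0]
            raise ValidationError(f"samples with zero total count: rows {bad[:5].tolist()}")
        props = counts / totals
        return np.asarray(props @ self.incidence)

    def clade_taxa(self, branch: int) -> np.ndarray:
        """Indices of table taxa under a given branch."""
        if self._csc is None:
            self._csc = self.incidence.tocsc()
        return self._csc[:, branch].indices


def _per_sample_rng(seed: int, sample_id) -> np.random.Generator:
    # keyed by sample id so results do not depend on row order
    return np.random.default_rng((seed, zlib.crc32(str(sample_id).encode())))


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to a fixed total count.

    Deterministic given ``seed``; each sample uses its own random stream keyed
    by its identifier, so per-sample results are independent of row order.
    """
    if table.is_transformed:
        raise ValidationError("rarefaction is defined on raw counts")
    counts = table.counts.astype(np.int64)
    totals = counts.sum(axis=1)
    short = totals < depth
    if np.any(short):
        bad = list(table.sample_ids[short][:10])
        raise ValidationError(f"samples with fewer than {depth} total counts: {bad}")
    out = np.empty_like(counts)
    for i, sid in enumerate(table.sample_ids):
        if totals[i] == depth:
            out[i] = counts[i]
        else:
            rng = _per_sample_rng(seed, sid)
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return CountTable(table.sample_ids, table.taxon_ids, out)


def bray_curtis(table: CountTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity D_ij = sum_t |x_it - x_jt| / sum_t (x_it + x_jt)."""
    if table.is_transformed:
        raise ValidationError("Bray-Curtis is defined on count data, not transformed values")
    totals = table.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if len(zero) >= 2:
        raise ValidationError(
            f"Bray-Curtis undefined for all-zero sample pairs: rows {zero[:5].tolist()}"
        )
    D = squareform(pdist(table.counts, metric="braycurtis"))
    return skbio.DistanceMatrix(D, ids=[str(s) for s in table.sample_ids])


def unifrac(
    table: CountTable,
    tree,
    variant: str = "unweighted",
    alpha: float = 0.5,
) -> skbio.DistanceMatrix:
    """UniFrac distances on a rooted tree.

    ``variant`` is one of ``unweighted`` (presence/absence of branches),
    ``weighted_normalized`` (branch-length weighted abundance differences,
    normalized to [0, 1]) or ``generalized`` (GUniFrac with exponent
    ``alpha``; ``alpha=1`` recovers the normalized weighted variant).
    """
    if table.is_transformed:
        raise ValidationError("UniFrac is defined on count data, not transformed values")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, table.taxon_ids)
    if not np.array_equal(index.taxon_ids, table.taxon_ids):
        raise ValidationError("tree index taxa do not match the count table")
    P = index.branch_proportions(table.counts)
    lengths = index.lengths
    # branches with no mass in any sample contribute nothing to any variant
    active = np.any(P > 0, axis=0)
    if not np.all(active):
        P = P[:, active]
        lengths = lengths[active]
    if variant == "unweighted":
        pres = (P > 0).astype(np.float64)
        both = pres @ (pres * lengths).T
        total = pres @ lengths
        union = total[:, None] + total[None, :] - both
        with np.errstate(divide="ignore", invalid="ignore"):
            D = np.where(union > 0, 1.0 - both / union, 0.0)
        np.fill_diagonal(D, 0.0)
    elif variant == "weighted_normalized":
        D = weighted_unifrac_pairs(np.ascontiguousarray(P), lengths)
    elif variant == "generalized":
        D = generalized_unifrac_pairs(np.ascontiguousarray(P), lengths, float(alpha))
    else:
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    D = (D + D.T) / 2.0
    return skbio.DistanceMatrix(D, ids=[str(s) for s in table.sample_ids])


def clr_transform(table: CountTable, pseudo: float = 1.0) -> CountTable:
    """Centered log-ratio transform with a pseudo-count: rows of the output sum to 0."""
    if table.is_transformed:
        raise ValidationError("input already transformed")
    if pseudo <= 0 and np.any(table.counts == 0):
        raise ValidationError("pseudo-count must be positive when zero counts are present")
    z = np.log(table.counts + pseudo)
    z -= z.mean(axis=1, keepdims=True)
    return CountTable(table.sample_ids, table.taxon_ids, z, is_transformed=True)


# --------------------------------------------------------------------------
# PhILR
# --------------------------------------------------------------------------

def _resolve_binary(tree: skbio.TreeNode) -> skbio.TreeNode:
    """Copy the tree, prune single-child chains and resolve multifurcations
    into binary nodes with zero-length internal branches, deterministically by
    sorted child labels."""
    tree = tree.copy()
    tree.prune()

    def min_leaf(node):
        if node.is_tip():
            return node.name
        return min(min_leaf(c) for c in node.children)

    for node in list(tree.traverse(include_self=True)):
        while len(node.children) > 2:
            kids = sorted(node.children, key=min_leaf)
            a, b = kids[0], kids[1]
            node.remove(a)
            node.remove(b)
            joint = skbio.TreeNode(length=0.0)
            joint.append(a)
            joint.append(b)
            node.append(joint)
    return tree


def philr_basis(tree: skbio.TreeNode, taxon_ids, weighting: str = "blw"):
    """Sequential-binary-partition contrast matrix for the PhILR transform.

    Returns ``(V, node_labels)`` where V is q x (q-1).  With
    ``weighting='uniform'`` the columns form an orthonormal ILR basis
    (V'V = I); with ``weighting='blw'`` each balance is additionally scaled by
    the summed branch lengths of the two child edges defining the split.
    """
    taxon_ids = [str(t) for t in taxon_ids]
    tree = _resolve_binary(tree.shear(taxon_ids))
    col = {t: i for i, t in enumerate(taxon_ids)}
    q = len(taxon_ids)
    V = np.zeros((q, q - 1))
    labels = []
    k = 0
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        if len(node.children) != 2:
            raise ValidationError("tree is not binary after resolution")
        left, right = node.children
        lt = [col[t.name] for t in left.tips()] if not left.is_tip() else [col[left.name]]
        rt = [col[t.name] for t in right.tips()] if not right.is_tip() else [col[right.name]]
        r, s = len(lt), len(rt)
        a = np.sqrt(s / (r * (r + s)))
        b = -np.sqrt(r / (s * (r + s)))
        scale = 1.0
        if weighting == "blw":
            scale = (left.length or 0.0) + (right.length or 0.0)
            if scale == 0.0:
                scale = 1.0  # zero-length resolution nodes keep the plain balance
        elif weighting != "uniform":
            raise ValueError(f"unknown weighting {weighting!r}")
        V[lt, k] = a * scale
        V[rt, k] = b * scale
        labels.append(node.name or f"n{k + 1}")
        k += 1
    if k != q - 1:
        raise ValidationError("expected q - 1 internal nodes for q taxa")
    return V, labels


def philr_transform(
    table: CountTable,
    tree: skbio.TreeNode,
    pseudo: float = 1.0,
    weighting: str = "blw",
) -> CountTable:
    """Phylogenetic ILR transform: one balance per internal node of the
    (binary-resolved) tree, optionally branch-length weighted."""
    if table.is_transformed:
        raise ValidationError("input already transformed")
    if pseudo <= 0 and np.any(table.counts == 0):
        raise ValidationError("pseudo-count must be positive when zero counts are present")
    V, labels = philr_basis(tree, table.taxon_ids, weighting=weighting)
    logx = np.log(table.counts + pseudo)
    balances = logx @ V
    labels = np.asarray(_dedup(labels), dtype=object)
    return CountTable(table.sample_ids, labels, balances, is_transformed=True)


def _dedup(labels):
    seen, out = {}, []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}.{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out
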