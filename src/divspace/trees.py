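"""Functional and phylogenetic trees: construction, transformation, comparison.

All similarity information used downstream derives from rooted ultrametric
trees normalized to total depth 1 (root at depth 0, every tip at depth 1).
Functional dendrograms are built from species traits by UPGMA; the
phylogeny enters as a genus-level ultrametric tree that is expanded to
species level with random Yule subtrees.  Pagel's delta power transform of
node depths moves the emphasis between deep (between-clade) and shallow
(between-sister) divergences; its infinite limit is the "rake" tree in
which all species are equally distinct (the taxonomic limit).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

__all__ = [
    "DELTA_INF",
    "tree_height",
    "node_depths",
    "is_ultrametric",
    "normalize_depth",
    "build_functional_tree",
    "upgma_tree",
    "standardized_trait_distances",
    "pagel_delta_transform",
    "expand_genus_tree",
    "tree_to_distance",
    "mantel_test",
]

#: Sentinel accepted everywhere a Pagel's-delta value is expected.
DELTA_INF = math.inf

_ULTRAMETRIC_TOL = 1e-9


# ---------------------------------------------------------------------------
# ultrametric-tree helpers
# ---------------------------------------------------------------------------

def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Depth of every node measured from the root (sum of edge lengths)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[node] = edge if parent is None else depths[parent] + edge
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip depth."""
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, tol: float = _ULTRAMETRIC_TOL) -> bool:
    """True when all root-to-tip path lengths agree within ``tol`` of the max."""
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return max(tip_depths) - min(tip_depths) <= tol * max(max(tip_depths), 1.0)


def normalize_depth(tree: dendropy.Tree) -> dendropy.Tree:
    """Rescale edge lengths in place so the total depth equals 1."""
    height = tree_height(tree)
    if height <= 0:
        raise ValueError("cannot normalize a tree of zero height")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    return tree


def _copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy with a private taxon namespace (input never mutated)."""
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# functional dendrograms (UPGMA on standardized log traits)
# ---------------------------------------------------------------------------

def standardized_trait_distances(
    traits: pd.DataFrame, trait_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Euclidean distances between species after log-transform and z-scaling.

    Each selected trait is log-transformed and standardized to zero mean /
    unit variance across species; the matrix of pairwise Euclidean
    distances over those standardized log traits is returned with species
    labels sorted lexicographically.
    """
    cols = list(trait_subset) if trait_subset is not None else list(traits.columns)
    sub = traits.loc[:, cols].sort_index()
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 species to build a functional tree")
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)][0]
        raise ValueError(f"missing trait value for species {bad!r}")
    nonpos = sub <= 0
    if nonpos.any().any():
        sp = sub.index[nonpos.any(axis=1)][0]
        tr = sub.columns[nonpos.loc[sp]][0]
        raise ValueError(f"non-positive trait {tr!r} for species {sp!r}")
    logged = np.log(sub.to_numpy(dtype=float))
    std = logged.std(axis=0, ddof=1)
    centered = logged - logged.mean(axis=0)
    scaled = np.divide(centered, std, out=np.zeros_like(centered), where=std > 0)
    dm = pdist(scaled)
    from scipy.spatial.distance import squareform

    return pd.DataFrame(squareform(dm), index=sub.index, columns=sub.index)


def upgma_tree(dmat: pd.DataFrame) -> dendropy.Tree:
    """Average-linkage (UPGMA) dendrogram, depth-normalized to 1.

    A merge at cophenetic distance d places the node at height d/2 above
    the tips; heights are divided by the root height so the output is
    ultrametric with total depth 1.  When the input distances are already
    ultrametric, the output cophenetic distances reproduce them exactly
    (up to the depth normalization).
    """
    labels = list(dmat.index)
    from scipy.spatial.distance import squareform

    condensed = squareform(dmat.to_numpy(), checks=False)
    Z = linkage(condensed, method="average")
    root = to_tree(Z)
    height = root.dist / 2.0
    if height <= 0:
        raise ValueError("all species have identical traits; dendrogram is degenerate")

    def emit(node) -> tuple[str, float]:
        """Return (newick fragment, node height above the tips)."""
        if node.is_leaf():
            return str(labels[node.id]), 0.0
        lh_str, lh = emit(node.left)
        rh_str, rh = emit(node.right)
        h = node.dist / 2.0
        return (
            f"({lh_str}:{float((h - lh) / height)!r},{rh_str}:{float((h - rh) / height)!r})",
            h,
        )

    newick, _ = emit(root)
    tree = dendropy.Tree.get(
        data=newick + ";", schema="newick", preserve_underscores=True
    )
    return tree


def build_functional_tree(
    traits: pd.DataFrame, trait_subset: Sequence[str] | None = None
) -> dendropy.Tree:
    """UPGMA dendrogram over standardized log-trait Euclidean distances.

    Species are sorted lexicographically before clustering so merge-order
    ties resolve reproducibly.  The output is ultrametric with total depth
    normalized to 1.
    """
    return upgma_tree(standardized_trait_distances(traits, trait_subset))


# ---------------------------------------------------------------------------
# Pagel's delta transform
# ---------------------------------------------------------------------------

def pagel_delta_transform(tree: dendropy.Tree, delta: float) -> dendropy.Tree:
    """Raise node depths of a depth-1 ultrametric tree to the power delta.

    ``delta < 1`` inflates deep, close-to-root branches (emphasis on
    between-clade differences); ``delta > 1`` inflates shallow branches
    (emphasis on fine differences).  ``delta = math.inf`` is handled
    analytically: every internal node at depth < 1 collapses to the root,
    producing the rake/star tree, while nodes already at depth 1 (tied to
    the tips, e.g. duplicate species) stay at depth 1.
    """
    if not (delta > 0):
        raise ValueError(f"delta must be > 0 (or inf), got {delta}")
    out = _copy_tree(tree)
    depths = node_depths(out)
    height = max(depths[leaf] for leaf in out.leaf_node_iter())
    if abs(height - 1.0) > 1e-6:
        raise ValueError("tree must be normalized to total depth 1 before delta transform")

    def transform(d: float) -> float:
        d = min(max(d, 0.0), 1.0)
        if math.isinf(delta):
            return 1.0 if d >= 1.0 - _ULTRAMETRIC_TOL else 0.0
        return d**delta

    new_depth = {node: transform(d) for node, d in depths.items()}
    for leaf in out.leaf_node_iter():
        new_depth[leaf] = 1.0  # tips pinned at depth 1
    for node in out.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
        else:
            node.edge.length = new_depth[node] - new_depth[parent]
    return out


# ---------------------------------------------------------------------------
# Yule expansion of a genus-level tree to species level
# ---------------------------------------------------------------------------

def expand_genus_tree(
    genus_tree: dendropy.Tree,
    species_to_genus: Mapping[str, str],
    seed: int | np.random.Generator | None = None,
) -> dendropy.Tree:
    """Replace each genus tip by a random Yule subtree over its species.

    Topologies follow the Yule (equal-rates-Markov) model: starting from a
    single lineage within the genus' terminal branch, a uniformly chosen
    extant lineage splits at each event.  Split depths are the order
    statistics of uniform draws on (parent depth, 1), so subtrees stay
    strictly inside the terminal branch and the expanded tree remains
    ultrametric with the original depth.  Monotypic genera are relabeled in
    place.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tree = _copy_tree(genus_tree)
    genus_tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    groups: dict[str, list[str]] = {}
    for sp, genus in species_to_genus.items():
        if genus not in genus_tips:
            raise ValueError(f"species {sp!r} mapped to genus {genus!r} absent from tree")
        groups.setdefault(genus, []).append(sp)

    depths = node_depths(tree)
    tns = tree.taxon_namespace
    for genus in sorted(groups):
        species = sorted(groups[genus])
        tip = genus_tips[genus]
        if len(species) == 1:
            tip.taxon = tns.new_taxon(label=species[0])
            continue
        k = len(species)
        parent_depth = depths[tip.parent_node] if tip.parent_node is not None else 0.0
        times = np.sort(rng.uniform(parent_depth, 1.0, size=k - 1))
        tip.taxon = None
        active: list[dendropy.Node] = [tip]
        birth = {tip: parent_depth}
        for t in times:
            idx = int(rng.integers(len(active)))
            node = active.pop(idx)
            node.edge.length = t - birth[node]
            for _ in range(2):
                child = dendropy.Node()
                node.add_child(child)
                birth[child] = t
                active.append(child)
        order = rng.permutation(k)
        for node, sp_idx in zip(active, order):
            node.edge.length = 1.0 - birth[node]
            node.taxon = tns.new_taxon(label=species[sp_idx])
    return tree


# ---------------------------------------------------------------------------
# cophenetic distances and Mantel comparison
# ---------------------------------------------------------------------------

def tree_to_distance(tree: dendropy.Tree) -> pd.DataFrame:
    """Cophenetic distance matrix: dist(i, j) = 2 * (1 - depth of MRCA).

    Depths are taken relative to the tree height, so the result does not
    depend on whether the input was already normalized to depth 1.
    """
    depths = node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    if height <= 0:
        raise ValueError("tree has zero height")
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node.taxon.label]]
            continue
        children = [tipsets[c] for c in node.child_nodes()]
        d = 2.0 * (1.0 - depths[node] / height)
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        dist[i, j] = dist[j, i] = d
        tipsets[node] = [i for sub in children for i in sub]
    return pd.DataFrame(dist, index=labels, columns=labels)


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-sided Mantel test between two labeled distance matrices.

    r is the Pearson correlation over strictly-lower-triangle entries; the
    p-value is a permutation p-value with the +1 correction,
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``, where each permutation
    simultaneously relabels rows and columns of the second matrix.
    """
    if list(d1.index) != list(d2.index) or list(d1.columns) != list(d2.columns):
        raise ValueError("distance matrices must share labels in the same order")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    tril = np.tril_indices(n, k=-1)
    x = a[tril]

    def corr(mat: np.ndarray) -> float:
        y = mat[tril]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
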