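"""Tree utilities on top of dendropy: parsing, bipartitions, neighbor joining
starts, and NNI rearrangements on unrooted binary trees.

Unrooted trees are represented as dendropy trees whose seed node has degree 3;
bipartitions are canonicalized as the split side not containing the reference
taxon (the lexicographically smallest label), so clade and complement compare
equal.
"""

from __future__ import annotations

import io
import itertools

import dendropy
import numpy as np


def parse_newick(newick: str, taxon_namespace: dendropy.TaxonNamespace | None = None,
                 rooted: bool = False) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        taxon_namespace=taxon_namespace,
        rooting="force-rooted" if rooted else "force-unrooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if not rooted and len(tree.seed_node.child_nodes()) == 2 \
            and len(tree.leaf_nodes()) > 2:
        # a degree-2 seed would present the same unrooted edge twice
        tree.collapse_basal_bifurcation()
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    ref = min(all_taxa)
    return frozenset(all_taxa - side) if ref in side else frozenset(side)


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, canonicalized."""
    taxa = frozenset(leaf_labels(tree))
    splits: set[frozenset] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(canonical_split(side, taxa))
    return splits


def clades_rooted(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf sets of all internal nodes of a rooted tree (including the root)."""
    out = set()
    for node in tree.postorder_internal_node_iter():
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def has_clade(tree: dendropy.Tree, clade: frozenset) -> bool:
    taxa = frozenset(leaf_labels(tree))
    return canonical_split(frozenset(clade), taxa) in bipartitions(tree)


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def same_unrooted_topology(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> bool:
    return robinson_foulds(tree_a, tree_b) == 0


# ---------------------------------------------------------------------------
# Distance matrices and the neighbor-joining start tree
# ---------------------------------------------------------------------------

def p_distance_matrix(alignment) -> np.ndarray:
    """Pairwise proportion-of-differing-sites matrix, ignoring missing data."""
    arr = alignment.to_array()
    n = alignment.ntaxa
    informative = np.isin(arr, list("ACGTRY"))
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = informative[i] & informative[j]
        if ok.sum() == 0:
            d = 0.75
        else:
            d = float(np.mean(arr[i][ok] != arr[j][ok]))
        dm[i, j] = dm[j, i] = d
    return dm


def nj_tree(dm: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree (via dendropy), returned unrooted."""
    buf = io.StringIO()
    buf.write("," + ",".join(taxa) + "\n")
    for i, t in enumerate(taxa):
        buf.write(t + "," + ",".join(f"{dm[i, j]:.10f}" for j in range(len(taxa))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    tree.collapse_basal_bifurcation()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def random_resolved_tree(taxa: list[str], rng: np.random.Generator,
                         taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Uniform-ish random unrooted binary tree by sequential random joins."""
    ns = taxon_namespace or dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes = []
    for label in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        node.edge.length = 0.05
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 0.05
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for node in nodes:
        tree.seed_node.add_child(node)
    return tree


# ---------------------------------------------------------------------------
# NNI rearrangements
# ---------------------------------------------------------------------------

def internal_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal edges as their child nodes, deterministic postorder."""
    out = []
    for node in tree.postorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            out.append(node)
    return out


def _swap_subtrees(node_a: dendropy.Node, node_b: dendropy.Node) -> None:
    parent_a, parent_b = node_a.parent_node, node_b.parent_node
    parent_a.remove_child(node_a)
    parent_b.remove_child(node_b)
    parent_a.add_child(node_b)
    parent_b.add_child(node_a)


def nni_neighbors(tree: dendropy.Tree, edge_child: dendropy.Node) -> list[dendropy.Tree]:
    """The two NNI rearrangements around one internal edge.

    ``edge_child`` identifies the edge by its child node (an internal node);
    the input tree is left untouched — neighbors are deep copies.
    """
    neighbors = []
    for variant in (0, 1):
        clone = tree.clone(depth=1)
        # locate the cloned edge child by its leaf set
        target_leaves = frozenset(lf.taxon.label for lf in edge_child.leaf_iter())
        v = None
        for node in clone.postorder_internal_node_iter():
            if node.parent_node is not None and \
                    frozenset(lf.taxon.label for lf in node.leaf_iter()) == target_leaves:
                v = node
                break
        if v is None:  # pragma: no cover - clone invariant
            continue
        u = v.parent_node
        v_children = v.child_nodes()
        u_others = [c for c in u.child_nodes() if c is not v]
        if len(v_children) != 2:
            continue
        if len(u_others) >= 2:
            # seed-adjacent edge: swap one child of v with each far subtree
            _swap_subtrees(v_children[1], u_others[variant % len(u_others)])
        else:
            _swap_subtrees(v_children[variant], u_others[0])
        neighbors.append(clone)
    return neighbors
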