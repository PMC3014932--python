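"""Dated (ultrametric) trees: node ages in Mya, leaves at age zero.

Node ages are stored on dendropy nodes as ``.age``; edge lengths are kept
consistent as parent age minus child age. Clades are identified by frozensets
of leaf labels, which is how posterior summaries and calibrations refer to
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class ChronogramError(ValueError):
    pass


@dataclass
class Chronogram:
    """A rooted dated tree with optional per-clade HPD intervals and support."""

    tree: dendropy.Tree
    hpd: dict[frozenset, tuple[float, float]] = field(default_factory=dict)
    clade_support: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sync_edge_lengths(self.tree)
        validate_ultrametric(self.tree)

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def clade_ages(self) -> dict[frozenset, float]:
        out = {}
        for node in self.tree.postorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[clade] = float(node.age)
        return out

    def age_of(self, clade: frozenset) -> float:
        """Age of the MRCA of ``clade`` (which may be a strict subset of a node)."""
        node = mrca(self.tree, clade)
        return float(node.age)

    def newick(self, ages_as_comments: bool = True) -> str:
        tree = self.tree.clone(depth=1)
        for node in tree.postorder_internal_node_iter():
            if ages_as_comments:
                clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
                parts = [f"age={node.age:.6g}"]
                if clade in self.hpd:
                    lo, hi = self.hpd[clade]
                    parts.append(f"height_95%_HPD={{{lo:.6g},{hi:.6g}}}")
                if clade in self.clade_support:
                    parts.append(f"posterior={self.clade_support[clade]:.4g}")
                node.annotations.add_new("info", ",".join(parts))
        return tree.as_string(schema="newick", suppress_annotations=not ages_as_comments).strip()

    def write_nexus(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN TREES;\n")
            fh.write(f"TREE mcc = [&R] {self.newick()}\n")
            fh.write("END;\n")


def mrca(tree: dendropy.Tree, clade: frozenset) -> dendropy.Node:
    taxa = [t for t in tree.taxon_namespace if t.label in clade]
    if len(taxa) != len(clade):
        raise ChronogramError(f"clade labels missing from tree: {clade}")
    return tree.mrca(taxa=taxa)


def sync_edge_lengths(tree: dendropy.Tree) -> None:
    """Derive edge lengths from node ages, or ages from edge lengths."""
    have_ages = all(getattr(n, "age", None) is not None
                    for n in tree.postorder_node_iter())
    if have_ages:
        for node in tree.postorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(node.parent_node.age) - float(node.age)
    else:
        # compute ages from edge lengths assuming ultrametricity
        depth: dict[int, float] = {}
        maxdepth = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
            maxdepth = max(maxdepth, depth[id(node)])
        tol = 1e-6 * max(1.0, maxdepth)
        for node in tree.postorder_node_iter():
            node.age = maxdepth - depth[id(node)]
            if node.is_leaf():
                if abs(node.age) > tol:
                    raise ChronogramError(
                        "edge lengths are not ultrametric: leaf "
                        f"{node.taxon.label!r} at depth {depth[id(node)]:.6g} "
                        f"vs tree depth {maxdepth:.6g}")
                node.age = 0.0


def validate_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    for node in tree.postorder_node_iter():
        if node.parent_node is not None:
            if float(node.parent_node.age) < float(node.age) - tol:
                raise ChronogramError("non-ultrametric: parent younger than child")
        if node.is_leaf() and abs(float(node.age)) > tol:
            raise ChronogramError("leaf not at age zero")


def chronogram_from_newick(newick: str,
                           taxon_namespace: dendropy.TaxonNamespace | None = None
                           ) -> Chronogram:
    """Parse a rooted newick whose edge lengths are time; ages are derived."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxon_namespace,
                             rooting="force-rooted",
                             preserve_underscores=True)
    for node in tree.postorder_node_iter():
        node.age = None
    sync_edge_lengths(tree)
    return Chronogram(tree)


def build_chronogram(joins: list[tuple[frozenset, float]], taxa: list[str],
                     taxon_namespace: dendropy.TaxonNamespace | None = None
                     ) -> Chronogram:
    """Chronogram from (clade, age) pairs describing every internal node."""
    ns = taxon_namespace or dendropy.TaxonNamespace(taxa)
    nodes: dict[frozenset, dendropy.Node] = {}
    for label in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        node.age = 0.0
        nodes[frozenset([label])] = node
    for clade, age in sorted(joins, key=lambda item: len(item[0])):
        node = dendropy.Node()
        node.age = float(age)
        kids = [c for c in nodes if c < clade]
        # maximal disjoint sub-clades
        kids = [c for c in kids if not any(c < other for other in kids)]
        if frozenset().union(*kids) != clade:
            raise ChronogramError(f"incompatible join for clade of size {len(clade)}")
        for c in kids:
            node.add_child(nodes.pop(c))
        nodes[clade] = node
    if len(nodes) != 1:
        raise ChronogramError("joins do not connect all taxa")
    tree = dendropy.Tree(taxon_namespace=ns)
    root = next(iter(nodes.values()))
    tree.seed_node = root
    tree.is_rooted = True
    return Chronogram(tree)
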