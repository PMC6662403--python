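"""Phylogenies: Newick/Nexus I/O, majority-rule consensus, VCV, distances.

Trees are held as :class:`dendropy.Tree` objects and are assumed rooted as
written.  The 50% majority-rule consensus keeps exactly the clades present
in a strict majority of the sample (strictly more than the threshold
fraction, so retained clades are always mutually compatible); a retained
clade's branch length is the mean of that edge's length over the trees
that contain the clade.

The phylogenetic variance–covariance matrix C has C_ij = the root-to-MRCA
depth shared by tips i and j and C_ii = the root-to-tip depth; it is the
covariance structure of a Brownian trait on the tree.  Patristic distances
D_ij (path length between tips) satisfy D = diag(C)1' + 1 diag(C)' - 2C on
rooted trees.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .traits_io import normalize_species_label

__all__ = [
    "PhyloError",
    "TreeSample",
    "VCVMatrix",
    "DistanceMatrix",
    "read_trees",
    "write_tree",
    "majority_consensus",
    "vcv_matrix",
    "patristic_distances",
    "prune_to",
]


class PhyloError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass
class TreeSample:
    """A list of rooted trees over one shared tip set."""

    trees: list[dendropy.Tree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise PhyloError("empty tree sample")
        ref = tip_set(self.trees[0])
        for i, t in enumerate(self.trees[1:], start=2):
            labels = tip_set(t)
            if labels != ref:
                diff = sorted(labels ^ ref)
                raise PhyloError(
                    f"tree {i} has a different tip set; symmetric difference: {diff}"
                )

    @property
    def count(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(tip_set(self.trees[0]))


@dataclass
class VCVMatrix:
    C: np.ndarray
    tip_labels: list[str]


@dataclass
class DistanceMatrix:
    D: np.ndarray
    tip_labels: list[str]


def tip_set(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(
        normalize_species_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()
    )


def read_trees(path: str | Path) -> TreeSample:
    """Read one or more rooted trees from a Newick or Nexus file.

    Tip labels are normalized (whitespace trimmed, spaces -> underscores).
    All trees must share one tip set; trees flagged unrooted ([&U]) are
    rejected rather than silently rerooted, because downstream statistics
    depend on the root.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema=schema,
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise PhyloError(f"{path}: cannot parse {schema} input: {exc}") from exc
    if not trees:
        raise PhyloError(f"{path}: no trees found")
    out = []
    for t in trees:
        if not t.is_rooted:
            raise PhyloError(f"{path}: tree flagged unrooted; reroot it explicitly first")
        for leaf in t.leaf_node_iter():
            leaf.taxon.label = normalize_species_label(leaf.taxon.label)
        out.append(t)
    return TreeSample(out)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True), encoding="utf-8"
    )


def _clades(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Map each internal clade (leaf-label set below a node) to its edge length."""
    out: dict[frozenset[str], float | None] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([normalize_species_label(node.taxon.label)])
        else:
            clade = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = clade
            out[clade] = node.edge.length
    return out


def majority_consensus(sample: TreeSample, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus of a sample of rooted trees.

    Keeps exactly the non-trivial clades whose frequency across the sample
    is *strictly greater* than ``threshold`` (plus the root clade and the
    tips).  Branch length of a kept clade = mean edge length over the trees
    containing it; tip branches get the mean tip-edge length.  Clades kept
    at threshold >= 0.5 are pairwise nested-or-disjoint, so assembly never
    conflicts.
    """
    if not 0.5 <= threshold <= 1.0:
        raise PhyloError(f"threshold must lie in [0.5, 1], got {threshold}")
    n_trees = sample.count
    counts: dict[frozenset[str], int] = defaultdict(int)
    lengths: dict[frozenset[str], list[float]] = defaultdict(list)
    tip_lengths: dict[str, list[float]] = defaultdict(list)
    for tree in sample.trees:
        for clade, elen in _clades(tree).items():
            counts[clade] += 1
            if elen is not None:
                lengths[clade].append(elen)
        for leaf in tree.leaf_node_iter():
            if leaf.edge.length is not None:
                tip_lengths[normalize_species_label(leaf.taxon.label)].append(
                    leaf.edge.length
                )

    all_tips = frozenset(sample.tip_labels)
    kept = [
        c
        for c, k in counts.items()
        if (k / n_trees) > threshold and 1 < len(c) <= len(all_tips)
    ]
    if all_tips not in kept:
        kept.append(all_tips)  # root clade is always present anyway
    kept.sort(key=len, reverse=True)

    taxa = dendropy.TaxonNamespace(sorted(all_tips))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    nodes: dict[frozenset[str], dendropy.Node] = {}

    def mean_or_none(vals: list[float]) -> float | None:
        # sort before summing so the result is exactly input-order invariant
        return float(np.mean(np.sort(vals))) if vals else None

    for clade in kept:
        node = tree.seed_node if clade == all_tips else dendropy.Node()
        if clade != all_tips:
            # parent = smallest already-placed clade strictly containing this one
            parent = min(
                (c for c in nodes if clade < c), key=len
            )
            nodes[parent].add_child(node)
            node.edge.length = mean_or_none(lengths.get(clade, []))
        nodes[clade] = node
    for label in sorted(all_tips):
        parent = min((c for c in nodes if label in c), key=len)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        leaf.edge.length = mean_or_none(tip_lengths.get(label, []))
        nodes[parent].add_child(leaf)
    # deterministic output: order children by their smallest descendant label
    for node in tree.preorder_internal_node_iter():
        node._child_nodes.sort(
            key=lambda c: min(l.taxon.label for l in c.leaf_iter())
        )
    return tree


def _tip_order(tree: dendropy.Tree) -> list[str]:
    labels = [normalize_species_label(l.taxon.label) for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise PhyloError("duplicate tip labels")
    return labels


def vcv_matrix(tree: dendropy.Tree) -> VCVMatrix:
    """Phylogenetic variance–covariance matrix of a rooted tree.

    C_ij = depth (root-to-node path length) of the MRCA of tips i and j;
    C_ii = root-to-tip depth.  Polytomies are handled as-is.  Missing branch
    lengths (other than the root edge) are an error.
    """
    labels = _tip_order(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise PhyloError("tree has missing branch lengths")
        if node.edge.length < 0:
            raise PhyloError("tree has negative branch lengths")
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    leaves_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[normalize_species_label(node.taxon.label)]
            leaves_below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            groups = [leaves_below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])[:, None]
                    ib = np.array(groups[b])[None, :]
                    C[ia, ib] = d
                    C[ib.T, ia.T] = d
            leaves_below[id(node)] = [i for g in groups for i in g]
    return VCVMatrix(C=C, tip_labels=labels)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distance matrix between all tip pairs."""
    labels = _tip_order(tree)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and node.edge.length is None:
            raise PhyloError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    D = np.zeros((n, n))
    taxa = {normalize_species_label(t.label): t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D=D, tip_labels=labels)


def prune_to(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Prune a tree down to the given tip labels (a copy is returned)."""
    pruned = tree.clone(depth=1)
    taxa = [
        t
        for t in pruned.taxon_namespace
        if normalize_species_label(t.label) in keep
    ]
    if len(taxa) < len(keep):
        have = {normalize_species_label(t.label) for t in pruned.taxon_namespace}
        raise PhyloError(f"tips absent from tree: {sorted(keep - have)}")
    pruned.retain_taxa(taxa)
    return pruned
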