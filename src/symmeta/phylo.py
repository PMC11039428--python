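"""Phylogeny handling and Brownian-motion correlation matrices.

Effect sizes from related taxa are not independent: under a Brownian
model of trait evolution the expected covariance between two tips is
the branch length they share on their root-to-tip paths (the depth of
their most recent common ancestor).  Normalising by the tip depths
turns that covariance into a correlation matrix, which enters the
meta-analytic model as the structure of the phylogenetic random effect.

Trees are held as :class:`dendropy.Tree` objects; this module adds the
operations a meta-analysis needs on top: reading/writing newick with
validation, relabelling stand-in tips to species missing from the
source tree, expanding species tips to near-zero-distance population
tips (one per effect-size record), pruning, and conversion to the
correlation matrix.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloError",
    "CorrelationMatrix",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "tip_labels",
    "substitute_tips",
    "expand_populations",
    "prune_to",
    "bm_correlation",
    "read_substitution_table",
]


class PhyloError(ValueError):
    pass


def _check_unique_tips(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    dupes: set[str] = set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    if dupes:
        raise PhyloError(f"duplicate tip labels: {sorted(dupes)}")
    return labels


def read_newick(
    text: str, *, missing_length: float | None = None
) -> dendropy.Tree:
    """Parse a newick string into a rooted tree.

    Branch lengths are required; edges without one raise unless
    ``missing_length`` supplies an imputation constant.  Duplicate tip
    labels raise.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:  # dendropy raises several parse error types
        raise PhyloError(f"malformed newick: {err}") from err
    _check_unique_tips(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if missing_length is None:
                raise PhyloError(
                    f"edge above {_describe(node)} has no branch length"
                )
            node.edge.length = missing_length
        elif node.edge.length < 0:
            raise PhyloError(
                f"negative branch length {node.edge.length} above {_describe(node)}"
            )
    return tree


def _describe(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def read_newick_file(path, **kwargs) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read(), **kwargs)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    # full deep copy (own taxon namespace): label edits must not leak back
    return copy.deepcopy(tree)


def substitute_tips(tree: dendropy.Tree, table: dict[str, str]) -> dendropy.Tree:
    """Relabel stand-in tips to species missing from the source tree.

    ``table`` maps each missing species to the label of its closest
    available relative already present in the tree; the stand-in tip is
    relabelled, leaving topology and branch lengths untouched.
    """
    out = _clone(tree)
    present = set(tip_labels(out))
    missing_standins = [s for s in table.values() if s not in present]
    if missing_standins:
        raise PhyloError(f"stand-in tips absent from tree: {sorted(missing_standins)}")
    clashes = [m for m in table if m in present]
    if clashes:
        raise PhyloError(f"target labels already present: {sorted(clashes)}")
    standin_counts: dict[str, int] = {}
    for standin in table.values():
        standin_counts[standin] = standin_counts.get(standin, 0) + 1
    reused = [s for s, c in standin_counts.items() if c > 1]
    if reused:
        raise PhyloError(f"stand-in used for more than one species: {sorted(reused)}")
    by_label = {leaf.taxon.label: leaf for leaf in out.leaf_node_iter()}
    for missing, standin in table.items():
        by_label[standin].taxon.label = missing
    return out


def expand_populations(
    tree: dendropy.Tree,
    multiplicity: dict[str, list[str]],
    epsilon: float = 1e-6,
) -> dendropy.Tree:
    """Split species tips into per-population tips at negligible distance.

    Each listed tip becomes a polytomy of its population labels, each on
    a pendant branch of length ``epsilon / 2``, so populations of one
    species sit at inter-population distance ``epsilon`` — effectively
    zero relative to the tree, but distinguishable, letting every
    effect-size record map to its own tip.
    """
    if not (0 < epsilon < 1e-5):
        raise PhyloError(
            f"epsilon must be in (0, 1e-5) so populations are effectively "
            f"coincident; got {epsilon}"
        )
    out = _clone(tree)
    existing = set(tip_labels(out))
    new_labels = [lab for labs in multiplicity.values() for lab in labs]
    if len(new_labels) != len(set(new_labels)):
        raise PhyloError("population labels are not unique")
    collisions = set(new_labels) & (existing - set(multiplicity))
    if collisions:
        raise PhyloError(f"population labels collide with existing tips: {sorted(collisions)}")
    unknown = [sp for sp in multiplicity if sp not in existing]
    if unknown:
        raise PhyloError(f"species not in tree: {sorted(unknown)}")
    by_label = {leaf.taxon.label: leaf for leaf in out.leaf_node_iter()}
    ns = out.taxon_namespace
    for species, pops in multiplicity.items():
        if not pops:
            raise PhyloError(f"empty population list for {species!r}")
        node = by_label[species]
        if len(pops) == 1:
            node.taxon.label = pops[0]
            continue
        node.taxon = None
        for lab in pops:
            taxon = ns.new_taxon(label=lab)
            node.new_child(taxon=taxon, edge_length=epsilon / 2.0)
    return out


def prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Induced subtree on ``labels``; unary nodes are suppressed with their
    branch lengths summed, so pairwise tip distances are preserved exactly."""
    labels = list(labels)
    out = _clone(tree)
    present = set(tip_labels(out))
    unknown = [lab for lab in labels if lab not in present]
    if unknown:
        raise PhyloError(f"labels not in tree: {sorted(unknown)}")
    out.retain_taxa_with_labels(labels)
    return out


@dataclass
class CorrelationMatrix:
    """Tip-by-tip Brownian-motion correlation with ordered labels."""

    matrix: np.ndarray
    labels: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("correlation matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise PhyloError("correlation matrix diagonal not unit")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise PhyloError("correlation entries outside [0, 1]")
        self.matrix = m
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def restrict(self, labels) -> "CorrelationMatrix":
        idx = [self._index[lab] for lab in labels]
        return CorrelationMatrix(self.matrix[np.ix_(idx, idx)], list(labels))

    def with_ridge(self, delta: float) -> "CorrelationMatrix":
        """Add delta*I and renormalise the diagonal to 1 (regularisation
        for near-singular matrices from population expansion)."""
        m = self.matrix + delta * np.eye(len(self.labels))
        m /= 1.0 + delta
        return CorrelationMatrix(m, list(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def bm_correlation(tree: dendropy.Tree) -> CorrelationMatrix:
    """Brownian-motion correlation matrix of the tree's tips.

    Covariance C_ij is the depth of the most recent common ancestor of
    tips i and j (shared root-to-tip path length, including any root
    edge); correlation is C_ij / sqrt(C_ii * C_jj).  Works for
    non-ultrametric trees and polytomies.
    """
    _check_unique_tips(tree)
    root = tree.seed_node
    depth: dict[int, float] = {}
    root_edge = root.edge.length if root.edge is not None and root.edge.length else 0.0
    depth[id(root)] = float(root_edge)
    leaves: list[dendropy.Node] = []
    for node in tree.preorder_node_iter():
        if node is not root:
            length = node.edge.length
            if length is None:
                raise PhyloError(f"edge above {_describe(node)} has no branch length")
            depth[id(node)] = depth[id(node.parent_node)] + float(length)
        if node.is_leaf():
            leaves.append(node)
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for leaf in leaves:
        i = index[id(leaf)]
        C[i, i] = depth[id(leaf)]
        if C[i, i] <= 0:
            raise PhyloError(
                f"tip {leaf.taxon.label!r} has zero root-to-tip depth; "
                "correlation undefined"
            )
    # postorder sweep: tips under each child of a node share that node's depth
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [index[id(node)]]
            continue
        groups = [below.pop(id(child)) for child in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    C[i, groups[b]] = d
                    C[np.ix_(groups[b], [i])] = d
        below[id(node)] = [i for g in groups for i in g]
    scale = np.sqrt(np.diag(C))
    R = C / np.outer(scale, scale)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, 0.0, 1.0)
    return CorrelationMatrix(R, labels)


def read_substitution_table(path) -> dict[str, str]:
    """Two-column CSV (missing_species, stand_in) -> substitution map."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PhyloError("substitution table needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
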