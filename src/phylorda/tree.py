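"""Rooted trees and the clade-membership indicator matrix.

Canonical phylogenetic ordination constrains an ordination with the nested
set of clades a tree defines: one binary species x clade column per tree
node, 1 where the species descends from that node.  Branch lengths play no
role in the coding (they are preserved for trait simulation); the laminar
(nested-or-disjoint) column structure is a direct consequence of the tree.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .traits import CodedMatrix, CodingSpec

__all__ = [
    "PhyloTree",
    "CladeMatrix",
    "parse_newick",
    "clade_indicators",
    "clade_column",
    "CladeIndicatorEncoder",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass
class PhyloTree:
    """A rooted tree with labelled leaves, wrapping a dendropy tree."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def checksum(self) -> str:
        return hashlib.sha256(self.to_newick().encode()).hexdigest()[:16]


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a rooted tree.

    Polytomies and unifurcations are preserved; underscores in labels are kept
    literal.  Raises :class:`NewickParseError` on malformed input.
    """
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("leaf labels must be unique")
    return PhyloTree(tree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


@dataclass
class CladeMatrix:
    """Binary species x clade membership indicators.

    Columns correspond to tree nodes; any two columns are nested or disjoint.
    ``provenance`` records the source tree checksum and the options used.
    """

    values: pd.DataFrame
    provenance: dict

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_labels(self) -> list[str]:
        return list(self.values.columns)

    def as_coded(self) -> CodedMatrix:
        """Centered CodedMatrix view for use as ordination constraints."""
        centered = self.values.astype(float)
        centered = centered - centered.mean(axis=0)
        spec = CodingSpec(numeric=tuple(self.values.columns), centered=True)
        return CodedMatrix(centered, spec)

    def subset(self, columns: Sequence[str]) -> "CladeMatrix":
        return CladeMatrix(self.values[list(columns)].copy(), dict(self.provenance))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="species")


def _node_leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def clade_indicators(
    tree: PhyloTree,
    exclude_root: bool = True,
    min_size: int = 2,
    labelled_only: bool = False,
) -> CladeMatrix:
    """Build the clade-membership matrix from a rooted tree.

    One column per internal node whose leaf set has size in
    ``[min_size, n_leaves - 1]``.  The root's all-ones column is constant
    after centering, hence excluded by default.  ``min_size=1`` admits
    terminal branches (needed when a named single-species group — a
    monotypic tribe — is a candidate variable).  With ``labelled_only`` only
    nodes carrying a label are kept; unlabelled nodes are auto-named
    ``node<k>`` in preorder.

    Duplicate leaf sets (e.g. a labelled unifurcation above a leaf) yield a
    single column, the labelled one winning.
    """
    leaves = tree.leaf_labels
    n = len(leaves)
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    columns: dict[str, frozenset[str]] = {}
    seen: dict[frozenset[str], str] = {}
    auto = 0
    for node in tree.tree.preorder_node_iter():
        is_root = node.parent_node is None
        if node.is_leaf() and min_size > 1:
            continue
        support = _node_leafset(node)
        if is_root and exclude_root:
            continue
        if not (min_size <= len(support) <= n - 1):
            continue
        label = getattr(node, "label", None)
        if label is None and node.is_leaf():
            if labelled_only:
                # species names do not make a terminal branch a named clade
                continue
            label = node.taxon.label
        if label is None:
            if labelled_only:
                continue
            auto += 1
            label = f"node{auto}"
        if support in seen:
            prev = seen[support]
            if prev.startswith("node") and not label.startswith("node"):
                del columns[prev]
            else:
                continue
        seen[support] = label
        columns[label] = support
    values = pd.DataFrame(
        {lab: [1 if sp in sup else 0 for sp in leaves] for lab, sup in columns.items()},
        index=pd.Index(leaves, name="species"),
        dtype=int,
    )
    provenance = {
        "tree_checksum": tree.checksum(),
        "exclude_root": exclude_root,
        "min_size": min_size,
        "labelled_only": labelled_only,
    }
    return CladeMatrix(values, provenance)


def clade_column(matrix: CladeMatrix, leaf_set: Iterable[str]) -> str | None:
    """Return the column id whose membership equals ``leaf_set``, else None."""
    target = set(leaf_set)
    for col in matrix.values.columns:
        members = set(matrix.values.index[matrix.values[col] == 1])
        if members == target:
            return col
    return None


class CladeIndicatorEncoder(TransformerMixin, BaseEstimator):
    """sklearn-style encoder: tree in, clade indicator matrix out."""

    def __init__(self, exclude_root: bool = True, min_size: int = 2,
                 labelled_only: bool = False):
        self.exclude_root = exclude_root
        self.min_size = min_size
        self.labelled_only = labelled_only

    def fit(self, tree: PhyloTree, y=None):
        return self

    def transform(self, tree: PhyloTree) -> CladeMatrix:
        return clade_indicators(
            tree,
            exclude_root=self.exclude_root,
            min_size=self.min_size,
            labelled_only=self.labelled_only,
        )

    def fit_transform(self, tree: PhyloTree, y=None) -> CladeMatrix:
        return self.fit(tree).transform(tree)
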