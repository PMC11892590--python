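"""Phylogenies, phylogenetic covariance matrices, and pathwise rates.

A time-calibrated tree supplies the Brownian-motion covariance used as the
random-effect structure of the mixed models; a posterior sample of
rate-scaled trees (branch lengths = time x inferred rate scalars) supplies
the per-species *pathwise rate*: the root-to-tip sum of rate-scaled branch
lengths, summarising how much trait evolution a lineage has undergone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreePosterior",
    "PhyloCovariance",
    "PathwiseRateTable",
    "read_trees",
    "write_trees",
    "phylo_covariance",
    "pathwise_rates",
]


class TreeValidationError(ValueError):
    """Raised when a tree or tree collection violates a structural invariant."""


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _validate_tree(tree: dendropy.Tree, index: int = 0) -> None:
    labels = _tip_labels(tree)
    if any(lab is None for lab in labels):
        raise TreeValidationError(f"tree {index}: unlabeled tip")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"tree {index}: duplicate tip labels {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeValidationError(
                f"tree {index}: negative branch length {edge.length}"
            )


@dataclass
class TreePosterior:
    """An ordered collection of trees over an identical tip set.

    Holds either a single tree (the time tree) or a posterior sample of
    rate-scaled trees.
    """

    trees: list[dendropy.Tree]

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise TreeValidationError("posterior must contain at least one tree")
        ref = set(_tip_labels(self.trees[0]))
        for i, t in enumerate(self.trees):
            _validate_tree(t, i)
            tips = set(_tip_labels(t))
            if tips != ref:
                raise TreeValidationError(
                    f"tree {i} tip set differs from tree 0: "
                    f"only-in-{i}={sorted(tips - ref)[:5]}, "
                    f"missing={sorted(ref - tips)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> dendropy.Tree:
        return self.trees[i]

    @property
    def taxa(self) -> list[str]:
        return sorted(_tip_labels(self.trees[0]))


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance of tip values on a tree.

    Entry (i, j) is the shared root-to-MRCA path length of tips i and j;
    the diagonal holds root-to-tip depths. Under Brownian motion with rate
    sigma^2 the tip values have covariance sigma^2 * matrix.
    """

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, rtol=0, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        self.matrix = (m + m.T) / 2.0

    def subset(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])

    def cholesky(self, jitter_rel: float = 1e-10) -> np.ndarray:
        """Lower Cholesky factor, with jitter <= jitter_rel * trace if needed."""
        m = self.matrix
        try:
            return np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            jit = jitter_rel * np.trace(m)
            return np.linalg.cholesky(m + jit * np.eye(m.shape[0]))


@dataclass
class PathwiseRateTable:
    """Per-species root-to-tip sums across a posterior of rate-scaled trees."""

    species: list[str]
    per_tree: np.ndarray  # (n_species, n_trees)
    summary: pd.Series = field(init=False)  # median across trees

    def __post_init__(self) -> None:
        self.per_tree = np.asarray(self.per_tree, dtype=float)
        if self.per_tree.shape[0] != len(self.species):
            raise ValueError("per_tree rows must match species")
        self.summary = pd.Series(
            np.median(self.per_tree, axis=1), index=self.species, name="pathwise_rate"
        )

    @property
    def n_trees(self) -> int:
        return self.per_tree.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "median_pathwise_rate": self.summary.values,
                "n_trees": self.n_trees,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_trees(source, format: str = "newick") -> TreePosterior:
    """Read one or more trees from a file path, file object, or string.

    Parameters
    ----------
    source
        Path, open text file, or the tree text itself (a string containing
        ``;`` is treated as tree text).
    format
        ``"newick"`` or ``"nexus"``. Nexus translate tables are resolved to
        labels; quoted labels are unescaped.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    kwargs = dict(
        schema=fmt,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if isinstance(source, str) and (";" in source or "\n" in source):
        trees = dendropy.TreeList.get(data=source, **kwargs)
    elif hasattr(source, "read"):
        trees = dendropy.TreeList.get(file=source, **kwargs)
    else:
        trees = dendropy.TreeList.get(path=str(source), **kwargs)
    if len(trees) == 0:
        raise TreeValidationError("no trees found in source")
    return TreePosterior(list(trees))


def write_trees(posterior: TreePosterior, path=None, format: str = "newick") -> str:
    """Serialize a tree collection; returns the text, optionally writing it."""
    tl = dendropy.TreeList(posterior.trees)
    buf = io.StringIO()
    tl.write(file=buf, schema=format.lower(), unquoted_underscores=True,
             suppress_rooting=True, real_value_format_specifier=".17g")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _depths_and_paths(tree: dendropy.Tree):
    """Root-to-node depth and root-to-tip edge paths, by a single traversal."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        bl = node.edge.length or 0.0
        depth[node] = (depth[parent] + bl) if parent is not None else 0.0
    return depth


def phylo_covariance(tree: dendropy.Tree | TreePosterior,
                     taxa_order: Sequence[str]) -> PhyloCovariance:
    """Shared-path-length (Brownian) covariance matrix in a given tip order.

    Entry (i, j) is the depth of the most recent common ancestor of tips i
    and j, i.e. the branch length shared by their root-to-tip paths.
    """
    if isinstance(tree, TreePosterior):
        tree = tree[0]
    _validate_tree(tree)
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa_order if t not in tips]
    if missing:
        raise TreeValidationError(f"species absent from tree: {missing}")
    depth = _depths_and_paths(tree)
    n = len(taxa_order)

    # MRCA depth via per-tip ancestor chains; fine for the tree sizes used here.
    anc: list[list] = []
    for t in taxa_order:
        chain = []
        node = tips[t]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc.append(chain)
    anc_sets = [set(id(x) for x in chain) for chain in anc]

    m = np.zeros((n, n))
    for i in range(n):
        m[i, i] = depth[anc[i][0]]
        if m[i, i] <= 0:
            raise TreeValidationError(
                f"tip {taxa_order[i]!r} has zero root-to-tip depth"
            )
        for j in range(i):
            mrca = next(nd for nd in anc[i] if id(nd) in anc_sets[j])
            m[i, j] = m[j, i] = depth[mrca]
    return PhyloCovariance(list(taxa_order), m)


def pathwise_rates(trees: TreePosterior, species: Sequence[str]) -> PathwiseRateTable:
    """Root-to-tip branch-length sums per species, per tree, with medians.

    For each rate-scaled tree the pathwise value of a species is the exact
    sum of branch lengths on the unique root-to-tip path; the summary value
    is the median across trees (midpoint of the central order statistics for
    an even count).
    """
    if len(trees) == 0:
        raise TreeValidationError("empty tree posterior")
    shared = set(_tip_labels(trees[0]))
    missing = [s for s in species if s not in shared]
    if missing:
        raise TreeValidationError(f"species absent from trees: {missing}")
    vals = np.zeros((len(species), len(trees)))
    for k, tree in enumerate(trees.trees):
        depth = _depths_and_paths(tree)
        leaf_depth = {leaf.taxon.label: depth[leaf] for leaf in tree.leaf_node_iter()}
        for i, s in enumerate(species):
            vals[i, k] = leaf_depth[s]
    return PathwiseRateTable(list(species), vals)
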