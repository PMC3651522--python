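"""Phylogenetic trees and Felsenstein/CAIC independent contrasts.

Trees are :class:`dendropy.Tree` objects throughout; this module wraps the
parsing, pruning and polytomy-resolution plumbing and implements the
contrasts algorithm itself.

The contrasts computation follows the classic comparative-method recursion:
in a post-order traversal of a binary tree, an internal node whose children
carry values (x_i, x_j) on branches of length (v_i, v_j) contributes

* raw contrast        x_i - x_j
* standardized        (x_i - x_j) / sqrt(v_i + v_j)
* ancestral value     (x_i / v_i + x_j / v_j) / (1 / v_i + 1 / v_j)

and the node's own branch is lengthened by v_i * v_j / (v_i + v_j) to
account for the uncertainty of the ancestral value. A binary tree with
n leaves yields exactly n - 1 contrasts, statistically independent under
Brownian-motion trait evolution. Regression of one trait's standardized
contrasts on another's is through the origin, because the sign of each
contrast is an arbitrary artifact of child ordering.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy
from scipy import stats as sps

from .stats import RegressionResult

__all__ = [
    "TreeError",
    "NewickParseError",
    "ContrastSet",
    "parse_newick",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "set_equal_branch_lengths",
    "resolve_polytomies",
    "prune_to_taxa",
    "independent_contrasts",
    "contrast_regression",
]


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Leaf labels must be unique; branch lengths are optional and polytomies
    are preserved. Parse failures raise :class:`NewickParseError` carrying
    dendropy's position information.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"Newick parse failure: {exc}") from exc
    if not any(tree.leaf_node_iter()):
        raise NewickParseError("tree has no leaves")
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree from a file path."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def set_equal_branch_lengths(tree: dendropy.Tree, length: float = 1.0) -> dendropy.Tree:
    """Return a copy with every non-root branch length set to ``length``.

    This is the standard fallback when divergence times are unknown; all
    contrasts rescale identically so downstream fit statistics are
    invariant to the value chosen.
    """
    if not length > 0:
        raise TreeError(f"equal branch length must be positive, got {length}")
    out = _clone(tree)
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(length)
    return out


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Return a binary copy; polytomies become zero-length binary cascades.

    The resolution order is drawn from a seeded RNG, so identical seeds
    give identical topologies. An already-binary tree is returned as an
    unchanged copy.
    """
    out = _clone(tree)
    out.resolve_polytomies(rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return out


def prune_to_taxa(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Restrict the tree to ``taxa``.

    Degree-2 internal nodes created by pruning are suppressed with their
    incident branch lengths summed, so leaf-to-root path lengths among the
    retained taxa are preserved.
    """
    taxa = list(dict.fromkeys(taxa))
    present = set(leaf_labels(tree))
    missing = [t for t in taxa if t not in present]
    if missing:
        raise TreeError(f"taxa not in tree: {', '.join(sorted(missing))}")
    if len(taxa) < 2:
        raise TreeError(f"need at least 2 taxa to prune to, got {len(taxa)}")
    out = _clone(tree)
    out.retain_taxa_with_labels(taxa)
    return out


@dataclass(frozen=True)
class ContrastSet:
    """Independent contrasts for one trait on one binary tree.

    ``node_ids`` identify internal nodes by post-order index so that
    contrast sets computed for different traits on the same tree pair up
    positionally and by id.
    """

    trait: str
    node_ids: tuple[int, ...]
    raw: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)
    standardized: np.ndarray = field(repr=False)

    @property
    def n_contrasts(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "trait": self.trait,
                "raw_contrast": self.raw,
                "variance": self.variance,
                "standardized_contrast": self.standardized,
            }
        )


def independent_contrasts(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    trait_name: str = "trait",
    zero_length_fraction: float = 1e-8,
) -> ContrastSet:
    """Compute standardized independent contrasts for one trait.

    Parameters
    ----------
    tree
        Rooted strictly binary tree with positive branch lengths. Run
        :func:`resolve_polytomies` first if the topology has polytomies.
    trait
        Mapping from leaf label to trait value; every leaf must be present.
    zero_length_fraction
        Zero-length branches (typically introduced by polytomy resolution)
        are replaced by this fraction of the mean positive branch length so
        contrast variances stay positive.

    Returns
    -------
    ContrastSet
        n_leaves - 1 contrasts in deterministic post-order, first child
        minus second child.
    """
    leaves = leaf_labels(tree)
    missing = [l for l in leaves if l not in trait]
    if missing:
        raise TreeError(f"missing trait value for leaf: {', '.join(sorted(missing))}")

    lengths = [
        nd.edge.length
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    ]
    if any(l is None for l in lengths):
        raise TreeError("tree has branches without lengths; assign lengths first")
    if any(l < 0 for l in lengths):
        raise TreeError("tree has negative branch lengths")
    positive = [l for l in lengths if l > 0]
    if not positive:
        raise TreeError("tree has no positive branch lengths")
    eps = zero_length_fraction * float(np.mean(positive))

    node_value: dict[int, float] = {}
    node_vlen: dict[int, float] = {}  # working branch length above each node
    node_ids: list[int] = []
    raws: list[float] = []
    variances: list[float] = []

    def edge_len(nd: dendropy.Node) -> float:
        l = float(nd.edge.length)
        return l if l > 0 else eps

    for idx, nd in enumerate(tree.postorder_node_iter()):
        key = id(nd)
        if nd.is_leaf():
            node_value[key] = float(trait[nd.taxon.label])
            node_vlen[key] = edge_len(nd)
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise TreeError(
                f"non-binary node with {len(children)} children; "
                "run resolve_polytomies first"
            )
        ci, cj = children
        vi, vj = node_vlen[id(ci)], node_vlen[id(cj)]
        if not (vi > 0 and vj > 0):
            raise TreeError("non-positive effective branch length at contrast node")
        xi, xj = node_value[id(ci)], node_value[id(cj)]
        var = vi + vj
        node_ids.append(idx)
        raws.append(xi - xj)
        variances.append(var)
        node_value[key] = (xi / vi + xj / vj) / (1.0 / vi + 1.0 / vj)
        extra = vi * vj / (vi + vj)
        base = edge_len(nd) if nd.parent_node is not None else 0.0
        node_vlen[key] = base + extra

    raw = np.asarray(raws)
    var = np.asarray(variances)
    return ContrastSet(
        trait=trait_name,
        node_ids=tuple(node_ids),
        raw=raw,
        variance=var,
        standardized=raw / np.sqrt(var),
    )


def contrast_regression(
    x_contrasts: ContrastSet,
    y_contrasts: ContrastSet,
    positivize: bool = False,
) -> RegressionResult:
    """Through-origin regression of response contrasts on predictor contrasts.

    slope b = sum(u w) / sum(u^2); r^2 = 1 - RSS / sum(w^2) (uncentered, the
    no-intercept convention); two-sided p from t with n - 1 degrees of
    freedom. ``positivize`` flips each pair so the predictor contrast is
    non-negative — a presentation convention that cannot change the fit.
    """
    if x_contrasts.node_ids != y_contrasts.node_ids:
        raise TreeError(
            "contrast sets come from different trees (node ids differ); "
            "compute both traits on the same tree"
        )
    u = np.array(x_contrasts.standardized, dtype=float)
    w = np.array(y_contrasts.standardized, dtype=float)
    n = u.size
    if n < 3:
        raise ValueError(f"contrast regression needs >= 3 contrasts, got {n}")
    if np.all(u == 0):
        raise ValueError("all predictor contrasts are zero; slope undefined")
    if positivize:
        flip = np.where(u < 0, -1.0, 1.0)
        u, w = u * flip, w * flip

    suu = float(np.dot(u, u))
    b = float(np.dot(u, w)) / suu
    resid = w - b * u
    rss = float(np.dot(resid, resid))
    tss = float(np.dot(w, w))
    df = n - 1
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    se = np.sqrt(rss / df / suu)
    if se > 0:
        t = b / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    else:
        t = np.inf * np.sign(b) if b != 0 else 0.0
        p = 0.0 if b != 0 else 1.0
    return RegressionResult(
        slope=b,
        intercept=None,
        r_squared=r2,
        t=float(t),
        p=p,
        n=n,
        df_residual=df,
        F=float(t**2) if np.isfinite(t) else np.inf,
        f_df=(1, df),
    )
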