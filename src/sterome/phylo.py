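"""Phylogenetically independent contrasts (PIC) on rooted trees.

Species trait values are not statistically independent: close relatives
resemble each other.  Felsenstein's contrasts transform n tip values on a
rooted, branch-length tree into n - 1 independent differences under a
Brownian-motion model of trait evolution.  At each internal node with
children carrying values x_l, x_r on (extended) branches v_l, v_r:

    contrast        = (x_l - x_r) / sqrt(v_l + v_r)
    ancestral value = (x_l / v_l + x_r / v_r) / (1 / v_l + 1 / v_r)
    parent branch  += v_l * v_r / (v_l + v_r)

Contrast signs are arbitrary (they depend on child ordering), so bivariate
association between two traits is tested by regression *through the origin*
of one trait's contrasts on the other's, which is sign-invariant.  The
through-origin slope equals the phylogenetic GLS slope under the Brownian
covariance.

Newick parsing, serialization and tip pruning are delegated to dendropy; the
contrast recursion itself is implemented here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "PhyloError",
    "PhyloTree",
    "ContrastSet",
    "ContrastRegression",
    "parse_newick",
    "write_newick",
    "drop_tips",
    "compute_contrasts",
    "contrast_regression",
]

#: Floor applied to zero-length branches, as a fraction of tree height.
ZERO_LENGTH_FLOOR = 1e-8


class PhyloError(ValueError):
    """Invalid tree or trait input to a contrasts computation."""


class PhyloTree:
    """A rooted tree with unique tip labels and positive branch lengths.

    Thin wrapper over a :class:`dendropy.Tree`; construct via
    :func:`parse_newick` or from an existing dendropy tree.
    """

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise PhyloError("every tip must be labeled")
        dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
        if dupes:
            raise PhyloError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise PhyloError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise PhyloError("negative branch length")
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return max(
            leaf.distance_from_root() for leaf in self._tree.leaf_node_iter()
        )

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree(n_tips={self.n_tips})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise PhyloError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize back to Newick (round-trips topology, labels, lengths)."""
    return (
        tree.dendropy_tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
    )


def drop_tips(tree: PhyloTree, tips: list[str] | tuple[str, ...]) -> PhyloTree:
    """Remove the named tips, suppressing the resulting degree-2 nodes
    (their branch lengths are summed).

    Used to exclude species whose traits could not be measured.
    """
    present = set(tree.tip_labels)
    unknown = [t for t in tips if t not in present]
    if unknown:
        raise PhyloError(f"cannot drop unknown tips: {unknown}")
    remaining = present - set(tips)
    if len(remaining) < 2:
        raise PhyloError("fewer than two tips would remain; no contrasts possible")
    if not tips:
        return tree.clone()
    # re-parse for a fully independent taxon namespace before pruning
    clone = parse_newick(write_newick(tree)).dendropy_tree
    taxa = [clone.taxon_namespace.get_taxon(t) for t in tips]
    clone.prune_taxa(taxa, suppress_unifurcations=True)
    clone.purge_taxon_namespace()
    return PhyloTree(clone)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts of one trait on one tree.

    ``node_keys`` identifies each internal node by the sorted tuple of its
    descendant tip labels, so contrast sets computed from the same tree align
    node-for-node regardless of traversal details.
    """

    contrasts: np.ndarray  # (n_tips - 1,)
    variances: np.ndarray  # combined variance v_l + v_r per contrast
    node_keys: tuple[tuple[str, ...], ...]
    tip_labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.contrasts)


def compute_contrasts(
    tree: PhyloTree,
    trait: dict[str, float],
    resolve_polytomies: bool = True,
) -> ContrastSet:
    """Felsenstein contrasts of ``trait`` (tip label -> value) on ``tree``.

    Polytomies are resolved to an arbitrary binary topology with zero-length
    branches (floored at ``ZERO_LENGTH_FLOOR`` x tree height for the variance
    math) when ``resolve_polytomies`` is true; otherwise a non-binary node is
    an error.
    """
    missing = [t for t in tree.tip_labels if t not in trait]
    if missing:
        raise PhyloError(f"missing trait values for tips: {missing}")

    work = tree.dendropy_tree.clone(depth=1)
    if resolve_polytomies:
        work.resolve_polytomies()
    floor = ZERO_LENGTH_FLOOR * max(tree.height(), np.finfo(float).tiny)

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    variances: list[float] = []
    node_keys: list[tuple[str, ...]] = []
    clades: dict[int, tuple[str, ...]] = {}

    for node in work.postorder_node_iter():
        nid = id(node)
        edge_len = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            values[nid] = float(trait[node.taxon.label])
            lengths[nid] = max(edge_len, floor)
            clades[nid] = (node.taxon.label,)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise PhyloError(
                f"non-binary node with {len(children)} children; "
                "enable resolve_polytomies"
            )
        left, right = children
        vl, vr = lengths[id(left)], lengths[id(right)]
        xl, xr = values[id(left)], values[id(right)]
        contrasts.append((xl - xr) / math.sqrt(vl + vr))
        variances.append(vl + vr)
        node_keys.append(tuple(sorted(clades[id(left)] + clades[id(right)])))
        values[nid] = (xl / vl + xr / vr) / (1.0 / vl + 1.0 / vr)
        lengths[nid] = max(edge_len, floor) + vl * vr / (vl + vr)
        clades[nid] = clades[id(left)] + clades[id(right)]

    return ContrastSet(
        contrasts=np.asarray(contrasts),
        variances=np.asarray(variances),
        node_keys=tuple(node_keys),
        tip_labels=tree.tip_labels,
    )


@dataclass(frozen=True)
class ContrastRegression:
    """Through-origin regression of y-contrasts on x-contrasts."""

    slope: float
    r2: float
    r2_adj: float
    pvalue: float
    n: int  # number of contrasts


def contrast_regression(cx: ContrastSet, cy: ContrastSet) -> ContrastRegression:
    """Regression through the origin of ``cy`` contrasts on ``cx`` contrasts.

    Both contrast sets must come from the same tree (matched by tip sets and
    node keys).  With n contrasts and one fitted parameter the error has
    n - 1 degrees of freedom; R^2 is the uncentered coefficient and its
    adjustment uses the same n - 1 denominator.
    """
    if set(cx.tip_labels) != set(cy.tip_labels) or cx.node_keys != cy.node_keys:
        raise PhyloError("contrast sets come from different trees or node orders")
    x = cx.contrasts
    y = cy.contrasts
    n = len(x)
    if n < 2:
        raise PhyloError("need at least two contrasts for a regression")
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    if sxx == 0:
        raise PhyloError("x contrasts are all zero; slope undefined")
    slope = sxy / sxx
    df = n - 1
    rss = syy - slope * sxy
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    r2_adj = 1.0 - (1.0 - r2) * n / df
    if rss <= 0:
        pvalue = 0.0
    else:
        se = math.sqrt(rss / (df * sxx))
        tstat = slope / se
        pvalue = float(2.0 * stats.t.sf(abs(tstat), df=df))
    return ContrastRegression(slope=slope, r2=r2, r2_adj=r2_adj, pvalue=pvalue, n=n)
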