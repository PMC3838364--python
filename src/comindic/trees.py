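"""Rooted trees: UPGMA dendrograms, Newick I/O, cophenetic distances.

Functional dendrograms are built from Gower dissimilarities by UPGMA
(size-weighted average linkage), which yields an ultrametric rooted tree:
all tips are equidistant from the root.  Phylogenies arrive as Newick and
are consumed as-is; both feed the originality metrics, either directly
(equal-splits walks the tree) or through their cophenetic distances
(quadratic-entropy weights need a matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .traits import DistanceMatrix


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeError(ValueError):
    """Structurally invalid tree."""


class Node:
    """Tree node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class RootedTree:
    root: Node
    # merge trace (label_a, label_b, height) recorded by upgma, for debugging
    merge_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [t.label for t in self.tips()]
        if len(labels) != len(set(labels)):
            seen, dup = set(), set()
            for lab in labels:
                (dup if lab in seen else seen).add(lab)
            raise TreeError(f"duplicate tip label(s): {sorted(dup)}")
        for node in self.preorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at {node.label or 'internal node'}"
                )

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list:
        return [t.label for t in self.tips()]

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.preorder() if n is not self.root
        )

    def depths(self) -> dict:
        """Root-to-node path lengths (missing lengths count as 0)."""
        out = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[id(node)] = out[id(node.parent)] + (node.length or 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depth = self.depths()
        tip_depths = [depth[id(t)] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol


def upgma(dm: DistanceMatrix) -> RootedTree:
    """UPGMA clustering of a dissimilarity matrix into an ultrametric tree.

    True (size-weighted) average linkage: after merging clusters A and B,
    d(AB, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|).  Node heights are
    half the merge dissimilarity.  When several pairs tie at the minimum,
    the pair whose smallest member label sorts first is merged, so the
    result does not depend on input row order.
    """
    n = len(dm.labels)
    if n < 2:
        raise TreeError("UPGMA needs at least 2 labels")
    # order rows by label so tie-breaking is input-order independent
    order = sorted(range(n), key=lambda i: str(dm.labels[i]))
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()

    clusters = {}
    for i, lab in enumerate(labels):
        clusters[i] = {
            "node": Node(label=lab, length=None),
            "size": 1,
            "height": 0.0,
            "min_label": str(lab),
        }
    active = list(range(n))
    trace = []
    nxt = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                key = (
                    d[i, j],
                    tuple(sorted((clusters[i]["min_label"], clusters[j]["min_label"]))),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, _), i, j = best[0], best[1], best[2]
        height = dist / 2.0
        ci, cj = clusters[i], clusters[j]
        parent = Node()
        for c in (ci, cj):
            c["node"].length = max(height - c["height"], 0.0)
            parent.add_child(c["node"])
        trace.append((ci["min_label"], cj["min_label"], height))
        size = ci["size"] + cj["size"]
        row = (ci["size"] * d[i, :] + cj["size"] * d[j, :]) / size
        d[i, :] = row
        d[:, i] = row
        clusters[i] = {
            "node": parent,
            "size": size,
            "height": height,
            "min_label": min(ci["min_label"], cj["min_label"]),
        }
        active.remove(j)
        nxt += 1
    root = clusters[active[0]]["node"]
    return RootedTree(root, merge_trace=trace)


def cophenetic(tree: RootedTree) -> DistanceMatrix:
    """Pairwise tip-to-tip path-length (cophenetic) distances."""
    tips = tree.tips()
    depth = tree.depths()
    # ancestor chains for LCA lookup
    chains = []
    for t in tips:
        chain = []
        node = t
        while node is not None:
            chain.append(id(node))
            node = node.parent
        chains.append(set(chain))
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = chains[i] & chains[j]
            lca_depth = max(depth[idn] for idn in common)
            d[i, j] = d[j, i] = depth[id(tips[i])] + depth[id(tips[j])] - 2 * lca_depth
    return DistanceMatrix([t.label for t in tips], d)


def _check_parens(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(
                    f"unbalanced parentheses: unexpected ')' at position {pos}"
                )
    if depth != 0:
        raise NewickError(
            f"unbalanced parentheses: {depth} '(' left open at end of input"
        )


def read_newick(text: str) -> RootedTree:
    """Parse a Newick string (branch lengths with ':', trailing ';' optional)."""
    text = text.strip()
    if not text:
        raise NewickError("empty Newick input")
    _check_parens(text)
    try:
        dtree = dendropy.Tree.get(
            data=text if text.endswith(";") else text + ";",
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate tips reported by us
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from None

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge carries no information here
    return RootedTree(root)


def _fmt_len(x) -> str:
    return f":{x:.12g}" if x is not None else ""


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick with 12-significant-digit branch lengths."""

    def render(node: Node) -> str:
        if node.is_tip:
            return f"{node.label}{_fmt_len(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        label = node.label or ""
        return f"({inner}){label}{_fmt_len(node.length)}"

    return render(tree.root) + ";"


def read_newick_file(path) -> RootedTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: RootedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


def write_merge_trace(tree: RootedTree, path) -> None:
    """Export the UPGMA merge trace as a labeled text table."""
    with open(path, "w") as fh:
        fh.write("cluster_a\tcluster_b\theight\n")
        for a, b, h in tree.merge_trace:
            fh.write(f"{a}\t{b}\t{h:.12g}\n")
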