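"""Dendrogram construction, serialization and branch supports.

The merge trace becomes a rooted binary tree whose root is the complete
complex.  Two text encodings are provided:

* the linear format, where the two aggregated elements of each merge are
  parenthesized, comma-separated and followed by ``:distance``, children
  ordered by formation (earlier-formed first);
* standard newick, with either merge distances or branch supports as
  lengths.

Branch supports use the rate of well-designed triples.  Every internal
node is the branch separating the two leaf sets A and B it joins (its
child clades); its support is the proportion of triples {x, y, y'} with
x in one set and y, y' in the other such that
j(y, y') >= max(j(x, y), j(x, y')), where j is the leaf-level
similarity.  Ties count as well-designed; a branch with no admissible
triple (both sides singletons) gets support 1.0 by convention.  On a
leaf similarity perfectly nested with the topology every support is 1:
two elements drawn from the same side always look at least as similar
as either does to the outsider.  Leaves join nothing and carry no
support.

Merge heights may be non-monotone (distances are recomputed per merged
cluster, not linkage-updated), so the renderer makes no ultrametric
assumption.  The vertical ordering of leaves in the drawing is a layout
artifact and should not be read as a chronological ordering.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .clustering import MergeTrace

__all__ = [
    "DendrogramNode",
    "trace_to_tree",
    "to_linear_format",
    "parse_linear_format",
    "to_newick",
    "branch_support",
    "render_dendrogram",
]


@dataclass
class DendrogramNode:
    members: frozenset[str]
    children: tuple["DendrogramNode", ...] = ()
    merge_distance: Optional[float] = None   # None for leaves
    support: Optional[float] = None          # filled by branch_support; None at leaves
    formed_at: tuple[int, int] = (0, 0)      # (merge step, leaf position) ordering key

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        if not self.is_leaf:
            raise ValueError("internal nodes have no single label")
        (label,) = self.members
        return label

    def walk(self) -> Iterator["DendrogramNode"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list[str]:
        return [n.label for n in self.walk() if n.is_leaf]


def trace_to_tree(trace: MergeTrace) -> DendrogramNode:
    """Fold the merge trace into a rooted binary dendrogram."""
    nodes: dict[frozenset[str], DendrogramNode] = {}
    for pos, leaf in enumerate(trace.leaf_order):
        key = frozenset({leaf})
        nodes[key] = DendrogramNode(members=key, formed_at=(0, pos))
    for step in trace.steps:
        a, b = nodes.pop(step.merged_a), nodes.pop(step.merged_b)
        first, second = sorted((a, b), key=lambda n: n.formed_at)
        merged = step.merged_a | step.merged_b
        nodes[merged] = DendrogramNode(
            members=merged,
            children=(first, second),
            merge_distance=step.merge_distance,
            formed_at=(step.step_index, 0),
        )
    if len(nodes) != 1:
        raise ValueError("trace does not reduce to a single root")
    return next(iter(nodes.values()))


def to_linear_format(tree: DendrogramNode) -> str:
    """'(A,B):0.571429' style encoding, children in formation order."""
    if tree.is_leaf:
        return tree.label
    left, right = tree.children
    return (
        f"({to_linear_format(left)},{to_linear_format(right)})"
        f":{tree.merge_distance:.6f}"
    )


_TOKEN = re.compile(r"\(|\)|,|:[0-9.eE+-]+|[^(),:]+")


def parse_linear_format(text: str) -> DendrogramNode:
    """Inverse of :func:`to_linear_format`."""
    tokens = _TOKEN.findall(text.strip())
    pos = 0

    def parse_node() -> DendrogramNode:
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            left = parse_node()
            if tokens[pos] != ",":
                raise ValueError(f"expected ',' at token {pos}: {tokens[pos]!r}")
            pos += 1
            right = parse_node()
            if tokens[pos] != ")":
                raise ValueError(f"expected ')' at token {pos}: {tokens[pos]!r}")
            pos += 1
            if pos >= len(tokens) or not tokens[pos].startswith(":"):
                raise ValueError("internal node missing ':distance'")
            dist = float(tokens[pos][1:])
            pos += 1
            return DendrogramNode(
                members=left.members | right.members,
                children=(left, right),
                merge_distance=dist,
            )
        label = tokens[pos]
        pos += 1
        return DendrogramNode(members=frozenset({label}))

    node = parse_node()
    if pos != len(tokens):
        raise ValueError("trailing tokens after tree")
    return node


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: DendrogramNode, lengths: str = "merge_distance") -> str:
    """Newick string; ``lengths`` is 'merge_distance' or 'support'.

    In merge_distance mode leaves get length 0 (only separating branches
    carry a height); in support mode every internal node carries its
    well-designed-triples rate and leaves none.
    """
    if lengths not in ("merge_distance", "support"):
        raise ValueError("lengths must be 'merge_distance' or 'support'")

    def fmt(node: DendrogramNode) -> str:
        if node.is_leaf:
            body = _newick_label(node.label)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if lengths == "merge_distance":
            value = 0.0 if node.is_leaf else node.merge_distance
        else:
            value = node.support
        if value is None:
            return body
        return f"{body}:{value:.6f}"

    return fmt(tree) + ";"


def _well_designed(sim: pd.DataFrame, x: str, y: str, yp: str) -> bool:
    return sim.loc[y, yp] >= max(sim.loc[x, y], sim.loc[x, yp])


def branch_support(tree: DendrogramNode, leaf_similarity: pd.DataFrame) -> DendrogramNode:
    """Fill the support of every internal branch in place; returns the tree.

    ``leaf_similarity`` is the symmetric leaf-level similarity matrix
    (pseudo-Jaccard by default) indexed by subunit labels.
    """
    all_leaves = set(tree.leaves())
    missing = all_leaves - set(leaf_similarity.index)
    if missing:
        raise KeyError(f"similarity matrix lacks leaves: {sorted(missing)}")

    for node in tree.walk():
        if node.is_leaf:
            node.support = None
            continue
        left, right = node.children
        node.support = _triple_rate(
            leaf_similarity, sorted(left.members), sorted(right.members)
        )
    return tree


def _triple_rate(sim: pd.DataFrame, side_a: list[str], side_b: list[str]) -> float:
    total = good = 0
    for x in side_a:
        for y, yp in itertools.combinations(side_b, 2):
            total += 1
            good += _well_designed(sim, x, y, yp)
    for x in side_b:
        for y, yp in itertools.combinations(side_a, 2):
            total += 1
            good += _well_designed(sim, x, y, yp)
    if total == 0:
        return 1.0
    return good / total


def render_dendrogram(tree: DendrogramNode, path: str | Path) -> Path:
    """Draw the rooted dendrogram horizontally (root left, labels right)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    leaves = tree.leaves()
    ypos = {leaf: i for i, leaf in enumerate(leaves)}

    def height(node: DendrogramNode) -> float:
        return 0.0 if node.is_leaf else float(node.merge_distance or 0.0)

    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.4 * len(leaves) + 1)))

    def draw(node: DendrogramNode) -> float:
        if node.is_leaf:
            y = ypos[node.label]
            ax.text(-0.01, y, " " + node.label, va="center", ha="left", fontsize=9)
            return y
        ys = [draw(c) for c in node.children]
        h = height(node)
        for child, y in zip(node.children, ys):
            ax.plot([height(child), h], [y, y], color="black", lw=1)
        ax.plot([h, h], [min(ys), max(ys)], color="black", lw=1)
        return sum(ys) / len(ys)

    y_root = draw(tree)
    root_h = height(tree)
    ax.plot([root_h, root_h * 1.05 + 0.02], [y_root, y_root], color="black", lw=1)
    ax.invert_xaxis()
    ax.set_yticks([])
    ax.set_xlabel("merge distance (1 - pseudo-Jaccard)")
    ax.spines[["left", "right", "top"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
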