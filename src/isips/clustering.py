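"""Bottom-up agglomerative clustering of subunits into subcomplexes.

Each round merges the pair of current clusters at minimal distance and
then recomputes, directly from the network, the distances between the
new cluster (the union of member neighborhoods) and every remaining
cluster.  No Lance-Williams linkage update is used, so merge heights
may decrease between steps; downstream consumers must not assume an
ultrametric tree.

Ties in the minimum are broken by the lexicographically smallest
(sorted-member-tuple) pair, which makes the trace deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .network import ComplexDefinition, PPINetwork
from .similarity import contingency, distance

__all__ = [
    "MergeStep",
    "MergeTrace",
    "agglomerate",
    "cluster_label",
    "step_matrices_report",
    "parse_step_matrices",
]


def cluster_label(members: Sequence[str] | frozenset[str]) -> str:
    """Human-readable label: bare ID for singletons, '(A,B)' for clusters."""
    ordered = sorted(members)
    if len(ordered) == 1:
        return ordered[0]
    return "(" + ",".join(ordered) + ")"


@dataclass(frozen=True)
class MergeStep:
    step_index: int           # 1-based
    merged_a: frozenset[str]
    merged_b: frozenset[str]
    merge_distance: float
    post_matrix: pd.DataFrame  # labeled by cluster_label of surviving clusters

    def __post_init__(self) -> None:
        if self.merged_a & self.merged_b:
            raise ValueError("merged clusters must be disjoint")


@dataclass
class MergeTrace:
    steps: list[MergeStep]
    leaf_order: tuple[str, ...]
    method: str
    initial_matrix: pd.DataFrame

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def partition_at(self, n_clusters: int) -> set[frozenset[str]]:
        """The partition present when exactly ``n_clusters`` clusters remain."""
        if not (1 <= n_clusters <= self.n_leaves):
            raise ValueError("n_clusters out of range")
        clusters = {frozenset({s}) for s in self.leaf_order}
        for step in self.steps:
            if len(clusters) == n_clusters:
                break
            clusters.discard(step.merged_a)
            clusters.discard(step.merged_b)
            clusters.add(step.merged_a | step.merged_b)
        return clusters


def _pair_key(a: frozenset[str], b: frozenset[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    ta, tb = tuple(sorted(a)), tuple(sorted(b))
    return (ta, tb) if ta <= tb else (tb, ta)


def _matrix(network: PPINetwork, clusters: list[frozenset[str]], method: str,
            cache: dict) -> pd.DataFrame:
    labels = [cluster_label(c) for c in clusters]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, ci in enumerate(clusters):
        for j in range(i + 1, len(clusters)):
            cj = clusters[j]
            key = _pair_key(ci, cj)
            if key not in cache:
                cache[key] = distance(contingency(network, ci, cj), method)
            mat.iloc[i, j] = mat.iloc[j, i] = cache[key]
    return mat


def agglomerate(
    network: PPINetwork, complex_def: ComplexDefinition, method: str = "pseudo_jaccard"
) -> MergeTrace:
    """Cluster all subunits into one root, recording every merge.

    Returns a trace of n-1 steps for n subunits; each step stores the
    pair merged, the distance at which it merged, and the full distance
    matrix after the merge (recomputed from scratch on merged member
    sets).
    """
    if len(complex_def.subunits) < 2:
        raise ValueError("agglomeration needs at least 2 subunits")
    clusters: list[frozenset[str]] = [frozenset({s}) for s in complex_def.subunits]
    cache: dict = {}
    initial = _matrix(network, clusters, method, cache)

    steps: list[MergeStep] = []
    step_index = 0
    while len(clusters) > 1:
        best: tuple | None = None
        for i, ci in enumerate(clusters):
            for j in range(i + 1, len(clusters)):
                cj = clusters[j]
                d = cache[_pair_key(ci, cj)]
                cand = (d, _pair_key(ci, cj), ci, cj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        d, _, ca, cb = best
        merged = ca | cb
        clusters = [c for c in clusters if c not in (ca, cb)]
        # order clusters deterministically: by sorted member tuple
        clusters.append(merged)
        clusters.sort(key=lambda c: tuple(sorted(c)))
        post = _matrix(network, clusters, method, cache)
        step_index += 1
        steps.append(
            MergeStep(
                step_index=step_index,
                merged_a=ca,
                merged_b=cb,
                merge_distance=d,
                post_matrix=post,
            )
        )
    return MergeTrace(
        steps=steps,
        leaf_order=tuple(complex_def.subunits),
        method=method,
        initial_matrix=initial,
    )


def step_matrices_report(trace: MergeTrace) -> str:
    """Plain-text report: the initial matrix then one block per merge."""
    buf = io.StringIO()
    buf.write("# step 0 (initial distances)\n")
    trace.initial_matrix.to_csv(buf, sep="\t", float_format="%.6f", index_label="")
    for step in trace.steps:
        buf.write(
            f"# step {step.step_index} merged {cluster_label(step.merged_a)} + "
            f"{cluster_label(step.merged_b)} at {step.merge_distance:.6f}\n"
        )
        step.post_matrix.to_csv(buf, sep="\t", float_format="%.6f", index_label="")
    return buf.getvalue()


def parse_step_matrices(text: str) -> list[pd.DataFrame]:
    """Inverse of :func:`step_matrices_report` (matrices only)."""
    blocks: list[pd.DataFrame] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith("# step"):
            if current:
                blocks.append(_parse_block(current))
                current = []
        elif line.strip():
            current.append(line)
    if current:
        blocks.append(_parse_block(current))
    return blocks


def _parse_block(lines: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    frame.index.name = None
    return frame
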