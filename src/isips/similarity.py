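"""Pseudo-Jaccard index, alternative association scores and distances.

For two disjoint sets of subunits x and y (single subunits or
subcomplexes), let X be the set of proteins interacting with x and Y the
set interacting with y, and let SUx, SUy be the complex subunits among
them.  The pseudo-Jaccard similarity is

    j(x, y) = (N(X ∩ Y) - N(SUx ∩ SUy)) / (N(X ∪ Y) - N(SUx ∪ SUy)),

i.e. the ordinary Jaccard index of the interactor sets after discarding
intra-complex partners: only proteins *external* to the complex count.
The clustering distance is d = 1 - j.

With a = shared external interactors, b = external interactors private
to x, c = private to y (so the external union is u = a + b + c), five
further classical 2x2 association measures are provided for comparison:
Dice, Minimum Sensitivity, Ochiai (cosine), Overlap (Simpson) and
Kulczynski.  All are symmetric in x, y and lie in [0, 1]; a degenerate
denominator yields similarity 0 (distance 1) so that interactor-less
subunits aggregate last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .network import ComplexDefinition, PPINetwork

logger = logging.getLogger(__name__)

METHODS = ("pseudo_jaccard", "dice", "ms", "ochiai", "overlap", "kulczynski")

__all__ = [
    "ContingencyCounts",
    "METHODS",
    "contingency",
    "score",
    "distance",
    "initial_matrix",
    "pairwise_similarity",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Set sizes entering the similarity formulas for one pair.

    n_xy_int / n_xy_uni count proteins interacting with both / either of
    the two clusters; n_su_int / n_su_uni are the same counts restricted
    to complex subunits.  n_x_ext and n_y_ext are the per-cluster
    external interactor counts, needed by the asymmetric-denominator
    scores (MS, Ochiai, Overlap, Kulczynski).
    """

    n_xy_int: int
    n_xy_uni: int
    n_su_int: int
    n_su_uni: int
    n_x_ext: int
    n_y_ext: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_xy_int <= self.n_xy_uni):
            raise ValueError("need 0 <= N(X∩Y) <= N(X∪Y)")
        if not (0 <= self.n_su_int <= self.n_su_uni):
            raise ValueError("need 0 <= N(SU∩) <= N(SU∪)")
        if self.n_su_int > self.n_xy_int or self.n_su_uni > self.n_xy_uni:
            raise ValueError("subunit counts cannot exceed total counts")

    @property
    def a(self) -> int:
        """Shared external interactors."""
        return self.n_xy_int - self.n_su_int

    @property
    def external_union(self) -> int:
        return self.n_xy_uni - self.n_su_uni

    @property
    def b(self) -> int:
        """External interactors private to x."""
        return self.n_x_ext - self.a

    @property
    def c(self) -> int:
        """External interactors private to y."""
        return self.n_y_ext - self.a


def contingency(
    network: PPINetwork, members_x: Iterable[str], members_y: Iterable[str]
) -> ContingencyCounts:
    """Count shared/total interactors for two disjoint subunit sets.

    The interactor set of a cluster is the union of its members'
    neighbors minus the members of both clusters; subunit neighbors and
    external (non-subunit) neighbors are tallied separately.
    """
    mx, my = set(members_x), set(members_y)
    if mx & my:
        raise ValueError(f"member sets overlap: {sorted(mx & my)}")
    ext_x = network.external_interactors(mx)
    ext_y = network.external_interactors(my)
    su_x = network.subunit_neighbors(mx, exclude=my)
    su_y = network.subunit_neighbors(my, exclude=mx)
    x_all = ext_x | su_x
    y_all = ext_y | su_y
    return ContingencyCounts(
        n_xy_int=len(x_all & y_all),
        n_xy_uni=len(x_all | y_all),
        n_su_int=len(su_x & su_y),
        n_su_uni=len(su_x | su_y),
        n_x_ext=len(ext_x),
        n_y_ext=len(ext_y),
    )


def _safe_ratio(num: float, den: float, label: str) -> float:
    if den <= 0:
        logger.warning("degenerate denominator in %s; similarity set to 0", label)
        return 0.0
    return num / den


def score(counts: ContingencyCounts, method: str = "pseudo_jaccard") -> float:
    """Similarity in [0, 1] for one of the six supported methods."""
    a, b, c = counts.a, counts.b, counts.c
    if method == "pseudo_jaccard":
        return _safe_ratio(a, counts.external_union, method)
    if method == "dice":
        return _safe_ratio(2 * a, 2 * a + b + c, method)
    if method == "ms":
        if a + b <= 0 or a + c <= 0:
            logger.warning("degenerate denominator in ms; similarity set to 0")
            return 0.0
        return min(a / (a + b), a / (a + c))
    if method == "ochiai":
        return _safe_ratio(a, math.sqrt((a + b) * (a + c)), method)
    if method == "overlap":
        return _safe_ratio(a, min(a + b, a + c), method)
    if method == "kulczynski":
        if a + b <= 0 or a + c <= 0:
            logger.warning("degenerate denominator in kulczynski; similarity set to 0")
            return 0.0
        return (a / (a + b) + a / (a + c)) / 2
    raise ValueError(f"unknown similarity method {method!r}; choose from {METHODS}")


def distance(counts: ContingencyCounts, method: str = "pseudo_jaccard") -> float:
    """Clustering distance d = 1 - similarity, in [0, 1]."""
    return 1.0 - score(counts, method)


def initial_matrix(
    network: PPINetwork, complex_def: ComplexDefinition, method: str = "pseudo_jaccard"
) -> pd.DataFrame:
    """Symmetric distance matrix over all subunits (diagonal stored as 0)."""
    subunits = list(complex_def.subunits)
    if len(subunits) < 2:
        raise ValueError("need at least 2 subunits to build a distance matrix")
    mat = pd.DataFrame(0.0, index=subunits, columns=subunits)
    for i, si in enumerate(subunits):
        for sj in subunits[i + 1:]:
            d = distance(contingency(network, {si}, {sj}), method)
            mat.loc[si, sj] = d
            mat.loc[sj, si] = d
    return mat


def pairwise_similarity(
    network: PPINetwork, complex_def: ComplexDefinition, method: str = "pseudo_jaccard"
) -> pd.DataFrame:
    """Leaf-level similarity matrix (1 on the diagonal); feeds branch supports."""
    dmat = initial_matrix(network, complex_def, method)
    sim = 1.0 - dmat
    for su in complex_def.subunits:
        sim.loc[su, su] = 1.0
    return sim


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """TSV with labels as header row/column, 6 decimal places."""
    matrix.to_csv(path, sep="\t", float_format="%.6f", index_label="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
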