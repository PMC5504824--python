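"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles — per-node
adjacency scans, explicit set construction, exhaustive triple
enumeration — deliberately avoiding the code paths under test.
"""

from __future__ import annotations

import itertools
import math
import random

import networkx as nx


def random_ppi_graph(
    rng: random.Random, max_subunits: int = 8, max_externals: int = 30
) -> tuple[nx.Graph, list[str]]:
    """A random small complex-centric graph (every external touches a subunit)."""
    n_su = rng.randint(2, max_subunits)
    n_ext = rng.randint(0, max_externals)
    subunits = [f"S{i}" for i in range(n_su)]
    externals = [f"E{i}" for i in range(n_ext)]
    g = nx.Graph()
    g.add_nodes_from(subunits)
    for a, b in itertools.combinations(subunits, 2):
        if rng.random() < 0.3:
            g.add_edge(a, b)
    for e in externals:
        touched = [s for s in subunits if rng.random() < 0.25]
        if not touched:
            touched = [rng.choice(subunits)]
        for s in touched:
            g.add_edge(e, s)
    return g, subunits


def interactor_sets(
    g: nx.Graph, subunits: set[str], mx: set[str], my: set[str]
) -> tuple[set[str], set[str], set[str], set[str]]:
    """(X_external, X_subunit, Y_external, Y_subunit) by per-node scan."""
    ex, ux, ey, uy = set(), set(), set(), set()
    for node in g.nodes:
        if node in mx or node in my:
            continue
        hits_x = any(g.has_edge(node, m) for m in mx)
        hits_y = any(g.has_edge(node, m) for m in my)
        if hits_x:
            (ux if node in subunits else ex).add(node)
        if hits_y:
            (uy if node in subunits else ey).add(node)
    return ex, ux, ey, uy


def oracle_counts(
    g: nx.Graph, subunits: set[str], mx: set[str], my: set[str]
) -> tuple[int, int, int, int, int, int]:
    """(N_int, N_uni, N_su_int, N_su_uni, |E_x|, |E_y|)."""
    ex, ux, ey, uy = interactor_sets(g, subunits, mx, my)
    x_all, y_all = ex | ux, ey | uy
    return (
        len(x_all & y_all), len(x_all | y_all),
        len(ux & uy), len(ux | uy),
        len(ex), len(ey),
    )


def oracle_scores(
    g: nx.Graph, subunits: set[str], mx: set[str], my: set[str]
) -> dict[str, float]:
    """All six similarities straight from the external interactor sets."""
    ex, _, ey, _ = interactor_sets(g, subunits, mx, my)
    a = len(ex & ey)
    b = len(ex - ey)
    c = len(ey - ex)
    out: dict[str, float] = {}
    out["pseudo_jaccard"] = a / (a + b + c) if a + b + c else 0.0
    out["dice"] = 2 * a / (2 * a + b + c) if 2 * a + b + c else 0.0
    if a + b and a + c:
        out["ms"] = min(a / (a + b), a / (a + c))
        out["kulczynski"] = (a / (a + b) + a / (a + c)) / 2
        out["ochiai"] = a / math.sqrt((a + b) * (a + c))
        out["overlap"] = a / min(a + b, a + c)
    else:
        out["ms"] = out["kulczynski"] = out["ochiai"] = out["overlap"] = 0.0
    return out


def oracle_agglomerate(
    g: nx.Graph, subunits: list[str], method: str = "pseudo_jaccard"
) -> list[tuple[frozenset, frozenset, float]]:
    """Naive re-run of the agglomeration with the oracle distances."""
    su_set = set(subunits)
    clusters = [frozenset({s}) for s in subunits]
    merges = []
    while len(clusters) > 1:
        best = None
        for ci, cj in itertools.combinations(clusters, 2):
            d = 1.0 - oracle_scores(g, su_set, set(ci), set(cj))[method]
            ta, tb = sorted((tuple(sorted(ci)), tuple(sorted(cj))))
            cand = (d, (ta, tb), ci, cj)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, ci, cj = best
        merges.append((ci, cj, d))
        clusters = [c for c in clusters if c not in (ci, cj)] + [ci | cj]
    return merges


def oracle_branch_support(sim, side_a: list[str], side_b: list[str]) -> float:
    """Exhaustive well-designed-triples rate for one A|B split."""
    total = good = 0
    for a_side, b_side in ((side_a, side_b), (side_b, side_a)):
        for x in a_side:
            for y, yp in itertools.combinations(b_side, 2):
                total += 1
                if sim.loc[y, yp] >= max(sim.loc[x, y], sim.loc[x, yp]):
                    good += 1
    return good / total if total else 1.0
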