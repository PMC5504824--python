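"""Per-subcomplex interactor reports.

For each cluster of the merge trace, list the external (non-subunit)
proteins interacting with its members, together with the number of
members each touches.  Two modes exist: ``at_least_two`` (a protein must
touch >= 2 members) and ``all_members`` (it must touch every member);
for 2-member subcomplexes the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .clustering import MergeTrace, cluster_label
from .network import PPINetwork

MODES = ("at_least_two", "all_members")

__all__ = ["SubcomplexReport", "MODES", "subcomplex_interactors", "write_reports"]


@dataclass(frozen=True)
class SubcomplexReport:
    subcomplex: frozenset[str]
    interactors: tuple[tuple[str, int], ...]  # (protein, members touched), sorted
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.interactors, columns=["protein", "members_touched"])


def subcomplex_interactors(
    network: PPINetwork, members: Iterable[str], mode: str = "at_least_two"
) -> SubcomplexReport:
    """External proteins touching the subcomplex, filtered by ``mode``.

    Listed proteins are never subunits; ordering is by member-touch
    count descending, then protein ID.
    """
    members = frozenset(members)
    if len(members) < 2:
        raise ValueError("a subcomplex report needs at least 2 members")
    if mode not in MODES:
        raise ValueError(f"unknown report mode {mode!r}; choose from {MODES}")
    touch_counts: dict[str, int] = {}
    for protein in network.external_interactors(members):
        touch_counts[protein] = sum(
            1 for m in members if network.graph.has_edge(protein, m)
        )
    threshold = len(members) if mode == "all_members" else 2
    rows = [(p, c) for p, c in touch_counts.items() if c >= threshold]
    rows.sort(key=lambda item: (-item[1], item[0]))
    return SubcomplexReport(subcomplex=members, interactors=tuple(rows), mode=mode)


def write_reports(
    network: PPINetwork, trace: MergeTrace, out_dir: str | Path,
    mode: str = "at_least_two",
) -> Path:
    """One TSV block per subcomplex of the trace, plus a combined file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combined = out_dir / f"subcomplex_interactors_{mode}.tsv"
    with combined.open("w") as handle:
        handle.write("subcomplex\tprotein\tmembers_touched\n")
        for step in trace.steps:
            members = step.merged_a | step.merged_b
            report = subcomplex_interactors(network, members, mode)
            label = cluster_label(members)
            for protein, count in report.interactors:
                handle.write(f"{label}\t{protein}\t{count}\n")
    return combined
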