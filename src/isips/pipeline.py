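"""End-to-end run: interaction tables -> subcomplex hierarchy + reports.

This is the library-level driver behind the command line: it reads the
subunit list and every interaction table in the database directory
(plus an optional scored-prediction table), filters and deduplicates
the records, builds the complex-centric network, clusters the subunits
and writes every artifact into the output directory.  All data outputs
are deterministic text files; timestamps appear only in logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import clustering, mitab, reports, similarity, tree
from .network import ComplexDefinition, PPINetwork, build_network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    input_list: Path
    db_dir: Path
    out_dir: Path
    preppi_path: Optional[Path] = None
    preppi_cutoff: float = 0.5
    method: str = "pseudo_jaccard"
    report_mode: str = "at_least_two"
    dialect: str = "generic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.preppi_cutoff <= 1.0):
            raise ValueError("preppi cutoff must lie in [0,1]")
        if self.method not in similarity.METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.report_mode not in reports.MODES:
            raise ValueError(f"unknown report mode {self.report_mode!r}")


@dataclass
class RunResult:
    complex_def: ComplexDefinition
    network: PPINetwork
    trace: clustering.MergeTrace
    root: tree.DendrogramNode
    artifacts: dict[str, Path]


def _db_files(db_dir: Path) -> list[Path]:
    # the synth generator drops inputlist.txt next to its database files
    files = sorted(
        p for p in db_dir.iterdir()
        if p.is_file()
        and p.suffix in {".txt", ".tsv", ".mitab", ".tab"}
        and not p.name.startswith("inputlist")
    )
    if not files:
        raise FileNotFoundError(f"no interaction tables (*.txt/*.tsv/*.mitab) in {db_dir}")
    return files


def run_pipeline(config: RunConfig) -> RunResult:
    complex_def = ComplexDefinition.from_file(config.input_list)
    db_dir = Path(config.db_dir)
    if not db_dir.is_dir():
        raise FileNotFoundError(f"database directory not found: {db_dir}")

    records: list[mitab.InteractionRecord] = []
    for path in _db_files(db_dir):
        parsed = mitab.read_mitab(path, dialect=config.dialect)
        logger.info("%s: %d records", path.name, len(parsed))
        records.extend(parsed)
    if config.preppi_path is not None:
        predicted = mitab.read_preppi(config.preppi_path, cutoff=config.preppi_cutoff)
        logger.info(
            "%s: %d predictions above cutoff %.2f",
            Path(config.preppi_path).name, len(predicted), config.preppi_cutoff,
        )
        records.extend(predicted)

    filtered = mitab.filter_records(records, complex_def.subunits)
    if not filtered:
        raise RuntimeError(
            "no interactions found for any subunit; consider adding predicted "
            "interactions (a scored table with a lower cutoff) so that every "
            "subunit has partners in the network"
        )
    tables = mitab.deduplicate(filtered)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = dict(mitab.write_tiers(tables, out_dir))

    net = build_network(tables.nonredundant_pairs(), complex_def)
    n_nodes, n_edges = net.summary()
    logger.info("network: %d proteins, %d interactions", n_nodes, n_edges)
    artifacts["edge_list"] = out_dir / "network_edges.tsv"
    net.write_edge_list(artifacts["edge_list"])
    artifacts["graphml"] = out_dir / "network.graphml"
    net.write_graphml(artifacts["graphml"])
    artifacts["summary"] = out_dir / "network_summary.tsv"
    artifacts["summary"].write_text(
        f"n_proteins\tn_interactions\n{n_nodes}\t{n_edges}\n"
    )

    trace = clustering.agglomerate(net, complex_def, method=config.method)
    artifacts["step_matrices"] = out_dir / "step_matrices.txt"
    artifacts["step_matrices"].write_text(clustering.step_matrices_report(trace))

    root = tree.trace_to_tree(trace)
    leaf_sim = similarity.pairwise_similarity(net, complex_def, method=config.method)
    tree.branch_support(root, leaf_sim)

    artifacts["linear"] = out_dir / "subcomplexes_linear.txt"
    artifacts["linear"].write_text(tree.to_linear_format(root) + "\n")
    artifacts["newick_distance"] = out_dir / "subcomplexes_distance.nwk"
    artifacts["newick_distance"].write_text(
        tree.to_newick(root, lengths="merge_distance") + "\n"
    )
    artifacts["newick_support"] = out_dir / "subcomplexes_support.nwk"
    artifacts["newick_support"].write_text(tree.to_newick(root, lengths="support") + "\n")
    artifacts["dendrogram"] = out_dir / "dendrogram.svg"
    tree.render_dendrogram(root, artifacts["dendrogram"])
    artifacts["reports"] = reports.write_reports(
        net, trace, out_dir, mode=config.report_mode
    )
    return RunResult(
        complex_def=complex_def, network=net, trace=trace, root=root, artifacts=artifacts
    )
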