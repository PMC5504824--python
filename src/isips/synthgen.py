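"""Synthetic MITAB inputs with planted subcomplex structure.

The generator emulates the regime the clustering method assumes:
subunits of the same subcomplex share many external interactors, while
subunits of different subcomplexes share few.  Each module gets
``shared_within`` hub proteins connected to all of its subunits; each
pair of modules gets ``shared_cross`` bridge proteins connected to one
subunit of each; every subunit gets ``private_per_subunit`` private
partners; finally each absent subunit-protein edge is added with
probability ``noise_edge_prob``.  Output is a valid generic-dialect
MITAB file set (equal taxa, sequential synthetic PubMed IDs, a sprinkle
of duplicate rows and self-interactions to exercise the upstream
filters) plus a ground-truth JSON sidecar.

Two fixed fixtures are also provided: a 5-subunit/12-protein network
whose (A, B) pair realizes the worked contingency counts
(N(X∩Y)=6, N(X∪Y)=10, N(SU∩)=3, N(SU∪)=3, hence d(A,B)=4/7 and first
merge {A,B}), and a 12-row toy MITAB table with hand-counted
duplicates, one self-interaction and one cross-taxon row.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass
from pathlib import Path

from .network import ComplexDefinition

__all__ = [
    "PlantedModel",
    "generate_planted",
    "fig2_fixture",
    "toy_mitab_fixture",
    "write_mitab",
]

_TAXON = "559292"  # S. cerevisiae S288C, the organism the defaults emulate

_N_COLUMNS = 15  # MITAB 2.5 core column count


def _mitab_row(
    a: str,
    b: str,
    pmid: str,
    taxon_a: str = _TAXON,
    taxon_b: str = _TAXON,
    source: str = "synthdb",
) -> str:
    cells = ["-"] * _N_COLUMNS
    cells[0] = f"uniprotkb:{a}"
    cells[1] = f"uniprotkb:{b}"
    cells[8] = f"pubmed:{pmid}" if pmid else "-"
    cells[9] = f"taxid:{taxon_a}" if taxon_a else "-"
    cells[10] = f"taxid:{taxon_b}" if taxon_b else "-"
    cells[12] = source
    return "\t".join(cells)


def write_mitab(path: str | Path, rows: list[str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(row + "\n" for row in rows))
    return path


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted two-level interactor structure.

    Defaults are the benchmark conditions used throughout the test
    suite: two modules of three subunits, 10 within-module shared
    interactors, 1 cross-module bridge, 2 private partners per subunit
    and a 5% noise-edge rate.
    """

    modules: tuple[tuple[str, ...], ...] = (
        ("M1S1", "M1S2", "M1S3"),
        ("M2S1", "M2S2", "M2S3"),
    )
    shared_within: int = 10
    shared_cross: int = 1
    private_per_subunit: int = 2
    noise_edge_prob: float = 0.05
    seed: int = 0
    duplicate_every: int = 5  # every k-th record is emitted twice (same pmid)

    def __post_init__(self) -> None:
        if len(self.modules) < 2 or any(len(m) < 2 for m in self.modules):
            raise ValueError("need >= 2 modules of >= 2 subunits")
        if min(self.shared_within, self.shared_cross, self.private_per_subunit) < 0:
            raise ValueError("interactor counts must be >= 0")
        if not (0.0 <= self.noise_edge_prob <= 1.0):
            raise ValueError("noise_edge_prob must lie in [0,1]")

    @property
    def subunits(self) -> tuple[str, ...]:
        return tuple(itertools.chain.from_iterable(self.modules))

    @property
    def partition(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.modules}


def _planted_edges(model: PlantedModel) -> list[tuple[str, str]]:
    rng = random.Random(model.seed)
    edges: list[tuple[str, str]] = []
    externals: list[str] = []

    for k, module in enumerate(model.modules, start=1):
        for i in range(model.shared_within):
            hub = f"W{k}_{i + 1}"
            externals.append(hub)
            for su in module:
                edges.append((su, hub))
    for (k, mod_k), (l, mod_l) in itertools.combinations(
        enumerate(model.modules, start=1), 2
    ):
        for i in range(model.shared_cross):
            bridge = f"X{k}{l}_{i + 1}"
            externals.append(bridge)
            edges.append((rng.choice(mod_k), bridge))
            edges.append((rng.choice(mod_l), bridge))
    for su in model.subunits:
        for i in range(model.private_per_subunit):
            private = f"V{su}_{i + 1}"
            externals.append(private)
            edges.append((su, private))

    if model.noise_edge_prob > 0:
        existing = {frozenset(e) for e in edges}
        for su in model.subunits:
            for protein in externals:
                if frozenset((su, protein)) in existing:
                    continue
                if rng.random() < model.noise_edge_prob:
                    edges.append((su, protein))
    return edges


def generate_planted(
    model: PlantedModel, out_dir: str | Path
) -> tuple[dict[str, Path], ComplexDefinition, set[frozenset[str]]]:
    """Write the MITAB file set for a planted model.

    Returns the written paths (two database files, the subunit input
    list and the ground-truth JSON), the complex definition and the
    planted partition.  Deterministic given ``model.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = _planted_edges(model)

    rows_by_db: dict[str, list[str]] = {"db1": [], "db2": []}
    pmid = 100000
    for idx, (a, b) in enumerate(edges):
        pmid += 1
        db = "db1" if idx % 2 == 0 else "db2"
        row = _mitab_row(a, b, str(pmid), source=db)
        rows_by_db[db].append(row)
        if model.duplicate_every and (idx + 1) % model.duplicate_every == 0:
            rows_by_db[db].append(row)  # exact duplicate, same pmid
    # self-interactions (removed by the filter) on the first subunit of
    # each module
    for module in model.modules:
        pmid += 1
        rows_by_db["db1"].append(_mitab_row(module[0], module[0], str(pmid)))

    paths = {
        db: write_mitab(out_dir / f"{db}.mitab.txt", rows) for db, rows in rows_by_db.items()
    }
    complex_def = ComplexDefinition(model.subunits, name="planted")
    input_list = out_dir / "inputlist.txt"
    input_list.write_text("".join(su + "\n" for su in model.subunits))
    paths["inputlist"] = input_list
    truth = {f"module_{k}": sorted(m) for k, m in enumerate(model.modules, start=1)}
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    paths["ground_truth"] = truth_path
    return paths, complex_def, model.partition


# ---------------------------------------------------------------------------
# fixed fixtures

#: Frozen 17-node example network: 5 subunits (A..E) and 12 external
#: proteins (P1..P12).  A and B both touch subunits C, D, E; their
#: external sets are {P1..P4} and {P1,P2,P3,P5,P6,P7}, giving shared
#: external count a=3 on an external union of 7 and making (A, B) the
#: unique minimum-distance pair at d = 4/7.
FIG2_SUBUNITS = ("A", "B", "C", "D", "E")
FIG2_EDGES: tuple[tuple[str, str], ...] = (
    ("A", "C"), ("A", "D"), ("A", "E"),
    ("B", "C"), ("B", "D"), ("B", "E"),
    ("A", "P1"), ("A", "P2"), ("A", "P3"), ("A", "P4"),
    ("B", "P1"), ("B", "P2"), ("B", "P3"), ("B", "P5"), ("B", "P6"), ("B", "P7"),
    ("C", "P1"), ("C", "P8"), ("C", "P9"),
    ("D", "P8"), ("D", "P10"), ("D", "P11"),
    ("E", "P9"), ("E", "P12"),
)


def fig2_fixture(out_dir: str | Path) -> tuple[Path, ComplexDefinition]:
    """Write the worked-example network as a clean one-file MITAB set."""
    out_dir = Path(out_dir)
    rows = [
        _mitab_row(a, b, str(2000 + i), source="fig2")
        for i, (a, b) in enumerate(FIG2_EDGES, start=1)
    ]
    path = write_mitab(out_dir / "fig2.mitab.txt", rows)
    input_list = out_dir / "inputlist.txt"
    input_list.parent.mkdir(parents=True, exist_ok=True)
    input_list.write_text("".join(su + "\n" for su in FIG2_SUBUNITS))
    return path, ComplexDefinition(FIG2_SUBUNITS, name="fig2")


#: Hand-audited 12-row toy table over subunits {S1, S2}.  Expected
#: bookkeeping, counted once by hand when the fixture was frozen:
#: 12 parsed records; the filter removes one self-interaction (S1,S1),
#: one cross-taxon row (S1,P4) and one row touching no subunit (P5,P6),
#: leaving 9; the partially-redundant tier drops the two exact
#: pair+PubMed duplicates, leaving 7; the non-redundant tier has 5
#: unordered pairs with pmid counts {P1-S1: 2, P2-S1: 1, P2-S2: 1,
#: P3-S2: 2, S1-S2: 1}.
TOY_SUBUNITS = ("S1", "S2")
TOY_EXPECTED_TIER_SIZES = {"full": 9, "partially_redundant": 7, "non_redundant": 5}
TOY_EXPECTED_PMID_COUNTS = {
    ("P1", "S1"): 2,
    ("P2", "S1"): 1,
    ("P2", "S2"): 1,
    ("P3", "S2"): 2,
    ("S1", "S2"): 1,
}

_TOY_ROWS = (
    ("S1", "P1", "1001", _TAXON, _TAXON, "dbA"),
    ("S1", "P1", "1001", _TAXON, _TAXON, "dbB"),   # duplicate pair+pmid
    ("P1", "S1", "1002", _TAXON, _TAXON, "dbA"),   # flipped orientation, new pmid
    ("S1", "P2", "1003", _TAXON, _TAXON, "dbA"),
    ("S2", "P2", "1003", _TAXON, _TAXON, "dbA"),
    ("S2", "P3", "1004", _TAXON, _TAXON, "dbA"),
    ("S1", "S1", "1005", _TAXON, _TAXON, "dbA"),   # self-interaction
    ("S1", "P4", "1006", _TAXON, "9606", "dbA"),   # cross-taxon
    ("S2", "P3", "1004", _TAXON, _TAXON, "dbB"),   # duplicate pair+pmid
    ("P5", "P6", "1007", _TAXON, _TAXON, "dbA"),   # touches no subunit
    ("S1", "S2", "1008", _TAXON, _TAXON, "dbA"),
    ("S2", "P3", "1009", _TAXON, _TAXON, "dbB"),   # same pair, new pmid
)


def toy_mitab_fixture(out_dir: str | Path) -> tuple[Path, ComplexDefinition]:
    """Write the hand-audited 12-row toy MITAB file."""
    rows = [_mitab_row(*row) for row in _TOY_ROWS]
    path = write_mitab(Path(out_dir) / "toy.mitab.txt", rows)
    return path, ComplexDefinition(TOY_SUBUNITS, name="toy")
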