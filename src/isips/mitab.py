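"""Reading, filtering and deduplicating PSI-MI TAB interaction tables.

Interaction records come from MITAB exports (iRefIndex, BioGRID, IntAct)
or from a scored-prediction table in the PrePPI style (two protein IDs
plus a confidence score per row).  Records are filtered down to the
complex-centric set -- same-taxon, non-self, touching at least one
subunit -- and collapsed into three nested redundancy tiers:

* ``full``                -- every surviving record, input order kept;
* ``partially_redundant`` -- one record per (unordered pair, PubMed ID);
* ``non_redundant``       -- one row per unordered pair, annotated with
  the number of distinct supporting PubMed IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "MitabDialect",
    "DIALECTS",
    "RedundancyTables",
    "read_mitab",
    "read_preppi",
    "filter_records",
    "deduplicate",
    "write_tiers",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One parsed protein-protein interaction row.

    ``taxon_a``/``taxon_b`` are NCBI taxon IDs as strings ("" when the
    source table has no taxon column).  ``score`` is only set for
    predicted records.
    """

    protein_a: str
    protein_b: str
    taxon_a: str = ""
    taxon_b: str = ""
    pubmed_ids: frozenset[str] = field(default_factory=frozenset)
    source_db: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"confidence score {self.score!r} outside [0,1]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair key (lexicographically sorted)."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)

    def is_self_interaction(self) -> bool:
        return self.protein_a == self.protein_b

    def same_taxon(self) -> bool:
        # Absent taxa compare equal so taxon-less tables (predictions)
        # pass the filter.
        return self.taxon_a == self.taxon_b


@dataclass(frozen=True)
class MitabDialect:
    """0-based column positions of the fields a dialect guarantees."""

    name: str
    id_a: int = 0
    id_b: int = 1
    pub: int = 8
    taxon_a: int = 9
    taxon_b: int = 10
    source: int = 12

    @property
    def min_columns(self) -> int:
        return max(self.id_a, self.id_b, self.pub, self.taxon_a, self.taxon_b) + 1


# MITAB 2.5/2.6 share these positions; per-source exports only differ in
# trailing columns, which we never read.
DIALECTS: dict[str, MitabDialect] = {
    name: MitabDialect(name) for name in ("generic", "irefindex", "biogrid", "intact")
}

_ID_PREFIXES = ("uniprotkb:", "refseq:", "entrezgene/locuslink:", "ddbj/embl/genbank:")


def _strip_prefix(token: str, prefixes: Sequence[str]) -> str:
    low = token.lower()
    for p in prefixes:
        if low.startswith(p):
            return token[len(p):]
    return token


def _parse_identifier(cell: str) -> Optional[str]:
    cell = cell.strip()
    if not cell or cell == "-":
        return None
    # first alternative of a |-separated identifier cell
    token = cell.split("|")[0].strip()
    token = _strip_prefix(token, _ID_PREFIXES)
    return token or None


def _parse_taxon(cell: str) -> str:
    cell = cell.strip()
    if not cell or cell == "-":
        return ""
    token = cell.split("|")[0].strip()
    token = _strip_prefix(token, ("taxid:",))
    # drop "(Saccharomyces cerevisiae)" style suffixes
    return token.split("(")[0].strip()


def _parse_pubmed(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell or cell == "-":
        return frozenset()
    out = set()
    for token in cell.split("|"):
        token = token.strip()
        token = _strip_prefix(token, ("pubmed:",))
        if token and token != "-":
            out.add(token)
    return frozenset(out)


def read_mitab(path: str | Path, dialect: str = "generic") -> list[InteractionRecord]:
    """Parse one MITAB file into records.  No filtering happens here.

    Rows whose interactor identifiers cannot be parsed are skipped and
    counted in the log.  A header line starting with ``#`` or with the
    conventional ``ID(s) interactor`` / ``uidA`` labels is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction table not found: {path}")
    if dialect not in DIALECTS:
        raise ValueError(f"unknown MITAB dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]

    records: list[InteractionRecord] = []
    skipped = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or _looks_like_header(line):
                continue
            cells = line.split("\t")
            if len(cells) < spec.min_columns:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {spec.min_columns} columns for "
                    f"dialect {dialect!r} (identifier/taxon/publication), got {len(cells)}"
                )
            id_a = _parse_identifier(cells[spec.id_a])
            id_b = _parse_identifier(cells[spec.id_b])
            if id_a is None or id_b is None:
                skipped += 1
                continue
            source = ""
            if len(cells) > spec.source:
                source = cells[spec.source].strip()
            records.append(
                InteractionRecord(
                    protein_a=id_a,
                    protein_b=id_b,
                    taxon_a=_parse_taxon(cells[spec.taxon_a]),
                    taxon_b=_parse_taxon(cells[spec.taxon_b]),
                    pubmed_ids=_parse_pubmed(cells[spec.pub]),
                    source_db=source or path.stem,
                )
            )
    if skipped:
        logger.info("%s: skipped %d rows with unparseable identifiers", path, skipped)
    return records


def _looks_like_header(line: str) -> bool:
    first = line.split("\t", 1)[0].lower()
    return first.startswith(("id(s) interactor", "#id", "uida", "uid a", "protein1"))


def read_preppi(path: str | Path, cutoff: float = 0.5) -> list[InteractionRecord]:
    """Read a scored prediction table, keeping rows with score > cutoff.

    The comparison is strict, matching the convention that records pass
    when their confidence exceeds the cut-off; ``cutoff=0.0`` therefore
    keeps every (positively scored) row and ``cutoff=1.0`` keeps none.
    Returned records carry ``source_db="PrePPI"``, no taxa and no PubMed
    IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"prediction table not found: {path}")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in [0,1], got {cutoff}")

    records: list[InteractionRecord] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or _looks_like_header(line):
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (id, id, score)")
            id_a = _parse_identifier(cells[0])
            id_b = _parse_identifier(cells[1])
            if id_a is None or id_b is None:
                continue
            try:
                score = float(cells[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {cells[2]!r}") from exc
            if score > cutoff:
                records.append(
                    InteractionRecord(
                        protein_a=id_a, protein_b=id_b, source_db="PrePPI", score=score
                    )
                )
    return records


def filter_records(
    records: Iterable[InteractionRecord], subunits: Iterable[str]
) -> list[InteractionRecord]:
    """Keep same-taxon, non-self records touching at least one subunit."""
    subunit_set = set(subunits)
    kept: list[InteractionRecord] = []
    n_self = n_taxon = n_outside = 0
    for rec in records:
        if rec.is_self_interaction():
            n_self += 1
            continue
        if not rec.same_taxon():
            n_taxon += 1
            continue
        if rec.protein_a not in subunit_set and rec.protein_b not in subunit_set:
            n_outside += 1
            continue
        kept.append(rec)
    logger.info(
        "filter: kept %d records (removed %d self, %d cross-taxon, %d without a subunit)",
        len(kept), n_self, n_taxon, n_outside,
    )
    return kept


@dataclass
class RedundancyTables:
    """The three nested interaction tiers."""

    full: list[InteractionRecord]
    partially_redundant: list[InteractionRecord]
    non_redundant: list[InteractionRecord]
    pmid_counts: dict[tuple[str, str], int]

    def nonredundant_pairs(self) -> list[tuple[str, str]]:
        return [rec.pair for rec in self.non_redundant]


def deduplicate(records: Sequence[InteractionRecord]) -> RedundancyTables:
    """Collapse filtered records into the three redundancy tiers.

    * full: the input, order preserved.
    * partially redundant: within each unordered pair, records sharing a
      PubMed ID are collapsed to one (first occurrence wins); a record
      citing several PubMed IDs is redundant only if all of them were
      already seen for the pair.  Records with no PubMed ID (predictions)
      collapse to a single row per pair.
    * non-redundant: one row per unordered pair, carrying the union of
      PubMed IDs; pmid_count is the number of distinct IDs (0 for
      prediction-only pairs).
    """
    full = list(records)

    partially: list[InteractionRecord] = []
    seen_pair_pmid: set[tuple[tuple[str, str], str]] = set()
    seen_pair_nopmid: set[tuple[str, str]] = set()
    for rec in full:
        key = rec.pair
        if rec.pubmed_ids:
            novel = {p for p in rec.pubmed_ids if (key, p) not in seen_pair_pmid}
            seen_pair_pmid.update((key, p) for p in rec.pubmed_ids)
            if novel:
                partially.append(rec)
        else:
            if key not in seen_pair_nopmid:
                seen_pair_nopmid.add(key)
                partially.append(rec)

    # the non-redundant tier must not depend on input row order: rows are
    # sorted by pair and carry the merged PubMed and source-label sets
    pmids_by_pair: dict[tuple[str, str], frozenset[str]] = {}
    sources_by_pair: dict[tuple[str, str], set[str]] = {}
    taxa_by_pair: dict[tuple[str, str], tuple[str, str]] = {}
    for rec in full:
        key = rec.pair
        pmids_by_pair[key] = pmids_by_pair.get(key, frozenset()) | rec.pubmed_ids
        sources_by_pair.setdefault(key, set()).add(rec.source_db)
        taxa_by_pair.setdefault(key, (rec.taxon_a, rec.taxon_b))
    order = sorted(pmids_by_pair)
    non_redundant = [
        InteractionRecord(
            protein_a=k[0],
            protein_b=k[1],
            taxon_a=taxa_by_pair[k][0],
            taxon_b=taxa_by_pair[k][1],
            pubmed_ids=pmids_by_pair[k],
            source_db="|".join(sorted(filter(None, sources_by_pair[k]))),
        )
        for k in order
    ]
    pmid_counts = {k: len(pmids_by_pair[k]) for k in order}
    return RedundancyTables(full, partially, non_redundant, pmid_counts)


def _tier_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        a, b = rec.pair
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "taxon_a": rec.taxon_a,
                "taxon_b": rec.taxon_b,
                "pubmed_ids": "|".join(sorted(rec.pubmed_ids)),
                "source_db": rec.source_db,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", "taxon_a", "taxon_b", "pubmed_ids", "source_db"],
    )


def write_tiers(tables: RedundancyTables, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tier TSVs; non-redundant gains a pmid_count column."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "full": out_dir / "interactions_full.tsv",
        "partially_redundant": out_dir / "interactions_partially_redundant.tsv",
        "non_redundant": out_dir / "interactions_non_redundant.tsv",
    }
    _tier_frame(tables.full).to_csv(paths["full"], sep="\t", index=False)
    _tier_frame(tables.partially_redundant).to_csv(
        paths["partially_redundant"], sep="\t", index=False
    )
    nr = _tier_frame(tables.non_redundant)
    nr["pmid_count"] = [tables.pmid_counts[rec.pair] for rec in tables.non_redundant]
    nr.to_csv(paths["non_redundant"], sep="\t", index=False)
    return paths
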