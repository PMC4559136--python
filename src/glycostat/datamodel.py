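"""Taxonomy-annotated structure collections.

A :class:`Collection` holds structure records — each a parsed glycan with its
source organisms, publications, NMR-spectrum count and structure type — plus
a taxonomy forest with explicit ranks.  Collections are read from and written
to a plain tab-separated dump with the header::

    structure_id  notation  lineage  year  nmr_count  structure_type  [publication_id]

where ``lineage`` is a semicolon-separated list of ``rank=name`` pairs
(``domain=Bacteria;phylum=Proteobacteria;genus=Escherichia;species=E. coli``)
and one row encodes one (structure, organism, publication) association; rows
sharing a ``structure_id`` are merged into one record.  The optional
``publication_id`` column identifies papers shared between structures; when
absent a per-structure surrogate id is derived from the year.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .notation import GlycanGraph, Vocabulary, DEFAULT_VOCABULARY, parse_structure

__all__ = [
    "RANKS",
    "STRUCTURE_TYPES",
    "DEFAULT_DOMAIN_GROUPS",
    "TaxonNode",
    "Taxonomy",
    "StructureRecord",
    "Collection",
    "DumpError",
    "read_dump",
    "write_dump",
]

RANKS = ["domain", "kingdom", "phylum", "class", "genus", "species", "strain"]
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

STRUCTURE_TYPES = {
    "mono_oligomer",
    "polymer",
    "mono_homopolymer",
    "cyclic",
    "biological_repeat",
}

#: grouping of taxonomic domains into database-like partitions: prokaryotic
#: organisms on one side, plant/fungal on the other.  Configurable per
#: collection; unlisted domains form their own group.
DEFAULT_DOMAIN_GROUPS = {
    "Bacteria": "prokaryotic",
    "Archaea": "prokaryotic",
    "Protista": "prokaryotic",
    "Plants": "plant_fungal",
    "Algae": "plant_fungal",
    "Fungi": "plant_fungal",
}


class DumpError(ValueError):
    pass


@dataclass(eq=False)
class TaxonNode:
    """A node of the taxonomy forest.  Identity is by object, names are
    unique within a parent."""

    name: str
    rank: str
    parent: TaxonNode | None = None
    children: list[TaxonNode] = field(default_factory=list)

    def __post_init__(self):
        if self.rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {self.rank!r}")

    @property
    def lineage(self) -> list[TaxonNode]:
        chain = []
        node: TaxonNode | None = self
        while node is not None:
            chain.append(node)
            node = node.parent
        return list(reversed(chain))

    def ancestor(self, rank: str) -> TaxonNode | None:
        for node in self.lineage:
            if node.rank == rank:
                return node
        return None

    @property
    def domain(self) -> TaxonNode:
        return self.lineage[0]

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def __repr__(self):
        return f"TaxonNode({self.rank}={self.name!r})"


class Taxonomy:
    """Forest of taxon nodes with rank-aware lookup."""

    def __init__(self):
        self.roots: list[TaxonNode] = []

    def add_lineage(self, pairs: list[tuple[str, str]]) -> TaxonNode:
        """Insert (or find) the chain of taxa given as (rank, name) pairs,
        ordered root-first with strictly descending ranks; return the leaf."""
        if not pairs:
            raise ValueError("empty lineage")
        last_idx = -1
        for rank, _name in pairs:
            idx = _RANK_INDEX.get(rank)
            if idx is None:
                raise ValueError(f"unknown rank {rank!r}")
            if idx <= last_idx:
                raise ValueError("lineage ranks must strictly descend")
            last_idx = idx
        node: TaxonNode | None = None
        siblings = self.roots
        for rank, name in pairs:
            found = next((c for c in siblings if c.name == name and c.rank == rank), None)
            if found is None:
                found = TaxonNode(name=name, rank=rank, parent=node)
                siblings.append(found)
            node = found
            siblings = found.children
        assert node is not None
        return node

    def walk(self):
        for root in self.roots:
            yield from root.walk()

    def find(self, name: str, rank: str | None = None) -> TaxonNode:
        hits = [t for t in self.walk() if t.name == name and (rank is None or t.rank == rank)]
        if not hits:
            raise KeyError(f"taxon {name!r}" + (f" at rank {rank}" if rank else "") + " not found")
        if len(hits) > 1:
            raise KeyError(f"taxon name {name!r} is ambiguous; specify the rank")
        return hits[0]

    def at_rank(self, rank: str, scope: TaxonNode | None = None) -> list[TaxonNode]:
        source = scope.walk() if scope is not None else self.walk()
        return [t for t in source if t.rank == rank]


@dataclass
class StructureRecord:
    """One glycan structure with its annotations.

    ``organisms`` are leaf-level taxa (species or strain); a record assigned
    to several organisms counts once per taxon under set semantics.
    """

    id: str
    notation: str
    graph: GlycanGraph
    structure_type: str
    organisms: list[TaxonNode]
    publications: list[tuple[str, int]]
    nmr_count: int = 0

    def __post_init__(self):
        if self.structure_type not in STRUCTURE_TYPES:
            raise ValueError(f"unknown structure type {self.structure_type!r}")
        if not self.organisms:
            raise ValueError(f"record {self.id}: at least one organism required")
        for _pid, year in self.publications:
            if not (1900 <= year <= 2100):
                raise ValueError(f"record {self.id}: year {year} out of range")
        if self.nmr_count < 0:
            raise ValueError("nmr_count must be non-negative")

    @property
    def years(self) -> list[int]:
        return [y for _p, y in self.publications]


class Collection:
    """An indexed set of structure records plus their taxonomy."""

    def __init__(
        self,
        records: list[StructureRecord],
        taxonomy: Taxonomy,
        domain_groups: dict[str, str] | None = None,
    ):
        self.records = records
        self.taxonomy = taxonomy
        self.domain_groups = dict(DEFAULT_DOMAIN_GROUPS if domain_groups is None else domain_groups)
        self._by_id = {r.id: r for r in records}
        # index: taxon -> set of record ids assigned at or below it
        self._taxon_records: dict[int, set[str]] = {}
        for record in records:
            for organism in record.organisms:
                for node in organism.lineage:
                    self._taxon_records.setdefault(id(node), set()).add(record.id)

    def __len__(self):
        return len(self.records)

    def record(self, record_id: str) -> StructureRecord:
        return self._by_id[record_id]

    def records_under(self, taxon: TaxonNode) -> list[StructureRecord]:
        """Distinct records assigned to ``taxon`` or any of its subtaxa."""
        ids = self._taxon_records.get(id(taxon))
        if ids is None:
            # known taxon without records, or foreign node
            if not any(taxon is t for t in self.taxonomy.walk()):
                raise KeyError(f"taxon {taxon.name!r} is not part of this collection")
            return []
        return [self._by_id[i] for i in sorted(ids)]

    def population(self, taxon: TaxonNode) -> int:
        """Number of distinct structures assigned to organisms belonging to
        the taxon or its subtaxa."""
        return len(self.records_under(taxon))

    def domain_of(self, record: StructureRecord) -> str:
        return record.organisms[0].domain.name

    def domain_group_of(self, record: StructureRecord) -> str:
        domain = self.domain_of(record)
        return self.domain_groups.get(domain, domain)

    def records_in_domain(self, domain: str) -> list[StructureRecord]:
        return [r for r in self.records if self.domain_of(r) == domain]

    def records_in_domain_group(self, group: str) -> list[StructureRecord]:
        return [r for r in self.records if self.domain_group_of(r) == group]


_HEADER = ["structure_id", "notation", "lineage", "year", "nmr_count", "structure_type"]


def _parse_lineage(text: str, row_no: int) -> list[tuple[str, str]]:
    pairs = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise DumpError(f"row {row_no}: malformed lineage element {part!r}")
        rank, name = part.split("=", 1)
        rank, name = rank.strip(), name.strip()
        if not rank or not name:
            raise DumpError(f"row {row_no}: malformed lineage element {part!r}")
        pairs.append((rank, name))
    if not pairs:
        raise DumpError(f"row {row_no}: empty lineage")
    return pairs


def read_dump(
    path: str | Path,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    domain_groups: dict[str, str] | None = None,
) -> Collection:
    """Read a tab-separated collection dump.

    Rows sharing a ``structure_id`` merge into one record, pooling organisms
    and publications.  Malformed notation or lineage raises :class:`DumpError`
    naming the offending row.
    """
    path = Path(path)
    taxonomy = Taxonomy()
    merged: dict[str, dict] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DumpError("missing header row") from None
        has_pub = header == _HEADER + ["publication_id"]
        if not has_pub and header != _HEADER:
            raise DumpError(f"unexpected header {header!r}")
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            expected = 7 if has_pub else 6
            if len(row) != expected:
                raise DumpError(f"row {row_no}: expected {expected} columns, got {len(row)}")
            sid, notation, lineage_text, year_text, nmr_text, stype = row[:6]
            try:
                year = int(year_text)
                nmr = int(nmr_text)
            except ValueError:
                raise DumpError(f"row {row_no}: non-integer year/nmr_count") from None
            pub_id = row[6] if has_pub else f"pub:{sid}:{year}"
            organism = taxonomy.add_lineage(_parse_lineage(lineage_text, row_no))
            if sid not in merged:
                try:
                    graph = parse_structure(notation, vocab=vocab)
                except Exception as exc:
                    raise DumpError(f"row {row_no}: cannot parse notation: {exc}") from None
                merged[sid] = {
                    "notation": notation,
                    "graph": graph,
                    "type": stype,
                    "organisms": [],
                    "publications": [],
                    "nmr": nmr,
                }
                order.append(sid)
            entry = merged[sid]
            if entry["notation"] != notation:
                raise DumpError(f"row {row_no}: conflicting notation for structure {sid!r}")
            if not any(o is organism for o in entry["organisms"]):
                entry["organisms"].append(organism)
            if (pub_id, year) not in entry["publications"]:
                entry["publications"].append((pub_id, year))
    records = []
    for sid in order:
        e = merged[sid]
        try:
            records.append(
                StructureRecord(
                    id=sid,
                    notation=e["notation"],
                    graph=e["graph"],
                    structure_type=e["type"],
                    organisms=e["organisms"],
                    publications=e["publications"],
                    nmr_count=e["nmr"],
                )
            )
        except ValueError as exc:
            raise DumpError(f"structure {sid!r}: {exc}") from None
    return Collection(records, taxonomy, domain_groups=domain_groups)


def write_dump(collection: Collection, path: str | Path, with_publication_ids: bool = True) -> None:
    """Write a collection as a TSV dump: one row per
    (structure, organism, publication)."""
    path = Path(path)
    header = _HEADER + (["publication_id"] if with_publication_ids else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for record in collection.records:
            lineage_texts = [
                ";".join(f"{n.rank}={n.name}" for n in org.lineage)
                for org in record.organisms
            ]
            for lineage_text in lineage_texts:
                for pub_id, year in record.publications:
                    row = [
                        record.id,
                        record.notation,
                        lineage_text,
                        str(year),
                        str(record.nmr_count),
                        record.structure_type,
                    ]
                    if with_publication_ids:
                        row.append(pub_id)
                    writer.writerow(row)
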