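"""Database-coverage statistics: how structures, publications, organisms and
NMR spectra distribute among the subtaxa of selected taxa.

Each selected taxon is broken down into its immediate subtaxa; deeper
descendants roll up into the immediate-child rows.  Year and structure-type
filters restrict the matching records; a cumulative row counts distinct
entities across all rows so that structures shared between subtaxa are not
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import Collection, STRUCTURE_TYPES, StructureRecord, TaxonNode

__all__ = ["CoverageRow", "coverage_table", "coverage_to_tsv"]


@dataclass(frozen=True)
class CoverageRow:
    taxon: str
    subtaxon: str
    n_structures: int
    structure_share: float
    n_publications: int
    n_organisms: int
    n_nmr: int


def _round2(x: float) -> float:
    import decimal

    return float(
        decimal.Decimal(x).quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    )


def _matches(record: StructureRecord, year_range, structure_type) -> bool:
    if structure_type is not None and record.structure_type != structure_type:
        return False
    if year_range is not None:
        lo, hi = year_range
        if not any(lo <= y <= hi for y in record.years):
            return False
    return True


def _stats(records: list[StructureRecord], taxon: TaxonNode):
    structures = {r.id for r in records}
    publications = {p for r in records for p, _y in r.publications}
    organisms = {
        id(org)
        for r in records
        for org in r.organisms
        if org.ancestor(taxon.rank) is taxon
    }
    nmr = sum(r.nmr_count for r in records)
    return structures, publications, organisms, nmr


def coverage_table(
    collection: Collection,
    rank: str,
    taxa: list[TaxonNode],
    year_range: tuple[int, int] | None = None,
    structure_type: str | None = None,
) -> tuple[list[CoverageRow], CoverageRow]:
    """Coverage rows per immediate subtaxon of each selected taxon, plus a
    cumulative row.

    ``structure_share`` is the subtaxon's percentage of all structures
    matching the selection.  Subtaxa without matching structures are
    omitted.  Records assigned directly to a selected taxon (no subtaxon at
    a lower rank) appear under the taxon's own name.
    """
    if year_range is not None and year_range[0] > year_range[1]:
        raise ValueError(f"invalid year range {year_range!r}")
    if structure_type is not None and structure_type not in STRUCTURE_TYPES:
        raise ValueError(f"unknown structure type {structure_type!r}")
    for taxon in taxa:
        if taxon.rank != rank:
            raise ValueError(f"taxon {taxon.name!r} is not at rank {rank!r}")

    all_matching: dict[str, StructureRecord] = {}
    for taxon in taxa:
        for record in collection.records_under(taxon):
            if _matches(record, year_range, structure_type):
                all_matching[record.id] = record
    total = len(all_matching)

    rows: list[CoverageRow] = []
    for taxon in taxa:
        groups: list[tuple[TaxonNode, list[StructureRecord]]] = []
        covered: set[str] = set()
        for child in taxon.children:
            recs = [
                r
                for r in collection.records_under(child)
                if _matches(r, year_range, structure_type)
            ]
            if recs:
                groups.append((child, recs))
                covered.update(r.id for r in recs)
        direct = [
            r
            for r in collection.records_under(taxon)
            if _matches(r, year_range, structure_type) and r.id not in covered
        ]
        if direct:
            groups.append((taxon, direct))
        for node, recs in groups:
            structures, pubs, orgs, nmr = _stats(recs, node)
            rows.append(
                CoverageRow(
                    taxon=taxon.name,
                    subtaxon=node.name,
                    n_structures=len(structures),
                    structure_share=_round2(100.0 * len(structures) / total) if total else 0.0,
                    n_publications=len(pubs),
                    n_organisms=len(orgs),
                    n_nmr=nmr,
                )
            )

    # cumulative row: distinct entities over every matching record
    records = list(all_matching.values())
    structures = {r.id for r in records}
    publications = {p for r in records for p, _y in r.publications}
    organisms = {
        id(org)
        for r in records
        for org in r.organisms
        if any(org.ancestor(t.rank) is t for t in taxa)
    }
    nmr = sum(r.nmr_count for r in records)
    cumulative = CoverageRow(
        taxon="(all)",
        subtaxon="(cumulative)",
        n_structures=len(structures),
        structure_share=100.0 if total else 0.0,
        n_publications=len(publications),
        n_organisms=len(organisms),
        n_nmr=nmr,
    )
    return rows, cumulative


def coverage_to_tsv(rows: list[CoverageRow], cumulative: CoverageRow) -> str:
    header = "taxon\tsubtaxon\tstructures\tstructure_share_pct\tpublications\torganisms\tnmr_spectra"
    lines = [header]
    for row in list(rows) + [cumulative]:
        lines.append(
            "\t".join(
                [
                    row.taxon,
                    row.subtaxon,
                    str(row.n_structures),
                    f"{row.structure_share:.2f}",
                    str(row.n_publications),
                    str(row.n_organisms),
                    str(row.n_nmr),
                ]
            )
        )
    return "\n".join(lines) + "\n"
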