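"""Fragment abundance statistics over taxonomy-annotated collections.

Answers "which monomers/dimers occur in the glycans of these taxa, how
often, and where else": per-fragment absolute and relative abundance within
a selection of same-rank taxa, the share of selected taxa containing each
fragment, fragments unique to a taxon within a wider scope, and per-domain
fragment frequencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .datamodel import Collection, StructureRecord, TaxonNode
from .fragments import FilterOptions, FragmentKey, enumerate_fragments

__all__ = [
    "AbundanceRow",
    "AbundanceSummary",
    "fragment_abundance",
    "unique_fragments",
    "domain_frequency",
    "rows_to_tsv",
]


@dataclass(frozen=True)
class AbundanceRow:
    fragment: FragmentKey
    absolute: int
    structure_ids: tuple[str, ...]
    relative_in_selection: float
    share_of_taxa: float


@dataclass(frozen=True)
class AbundanceSummary:
    n_fragments: int
    n_structures: int
    n_organisms: int


def _round2(x: float) -> float:
    """Percentages are reported to 2 decimals, half-up."""
    import decimal

    return float(
        decimal.Decimal(x).quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    )


def _structure_fragments(record: StructureRecord, arity: int, opts: FilterOptions) -> Counter:
    return enumerate_fragments(record.graph, arity, opts)


def fragment_abundance(
    collection: Collection,
    taxa: list[TaxonNode],
    arity: int,
    opts: FilterOptions,
    exclude_fragments: set[FragmentKey] | None = None,
) -> tuple[list[AbundanceRow], AbundanceSummary]:
    """Abundance table for the structures assigned to ``taxa``.

    All selected taxa must share a rank.  ``absolute`` counts fragment
    occurrences across the distinct structures matching the selection;
    ``relative_in_selection`` normalizes by the column total;
    ``share_of_taxa`` is the percentage of selected taxa whose structures
    contain the fragment at least once (structure-level presence).  Rows are
    sorted by fragment key.  ``exclude_fragments`` drops known analytical
    artifacts (e.g. alditol-terminated dimers) from the table.
    """
    if not taxa:
        raise ValueError("select at least one taxon")
    ranks = {t.rank for t in taxa}
    if len(ranks) != 1:
        raise ValueError(f"selected taxa must share a rank, got {sorted(ranks)}")

    records: dict[str, StructureRecord] = {}
    for taxon in taxa:
        for record in collection.records_under(taxon):
            records[record.id] = record

    totals: Counter = Counter()
    containing: dict[FragmentKey, set[str]] = {}
    per_taxon_presence: Counter = Counter()
    taxon_fragments: list[set[FragmentKey]] = []
    for taxon in taxa:
        seen: set[FragmentKey] = set()
        for record in collection.records_under(taxon):
            seen.update(_structure_fragments(record, arity, opts))
        taxon_fragments.append(seen)
    for record in records.values():
        frags = _structure_fragments(record, arity, opts)
        for key, count in frags.items():
            totals[key] += count
            containing.setdefault(key, set()).add(record.id)
    if exclude_fragments:
        for key in exclude_fragments:
            totals.pop(key, None)
            containing.pop(key, None)
    for seen in taxon_fragments:
        for key in seen:
            per_taxon_presence[key] += 1

    grand_total = sum(totals.values())
    rows = []
    for key in sorted(totals, key=lambda k: k.sort_key()):
        rows.append(
            AbundanceRow(
                fragment=key,
                absolute=totals[key],
                structure_ids=tuple(sorted(containing[key])),
                relative_in_selection=_round2(100.0 * totals[key] / grand_total)
                if grand_total
                else 0.0,
                share_of_taxa=_round2(100.0 * per_taxon_presence[key] / len(taxa)),
            )
        )
    organisms = {id(org) for r in records.values() for org in r.organisms
                 if any(org.ancestor(t.rank) is t for t in taxa)}
    summary = AbundanceSummary(
        n_fragments=len(rows),
        n_structures=len(records),
        n_organisms=len(organisms),
    )
    return rows, summary


def unique_fragments(
    collection: Collection,
    taxon: TaxonNode,
    scope: str,
    arity: int,
    opts: FilterOptions,
) -> set[FragmentKey]:
    """Fragments occurring in ``taxon`` but nowhere else within ``scope``.

    ``scope`` is ``"all_biota"`` (the whole loaded collection — note this
    only covers the domains actually populated in it), ``"kingdom"`` or
    ``"phylum"`` (the taxon's ancestor at that rank).
    """
    if scope == "all_biota":
        scope_records = list(collection.records)
        in_scope = lambda org: True  # noqa: E731
    elif scope in ("kingdom", "phylum"):
        ancestor = taxon.ancestor(scope)
        if ancestor is None:
            raise ValueError(f"taxon {taxon.name!r} has no ancestor at rank {scope!r}")
        scope_records = collection.records_under(ancestor)
        in_scope = lambda org: org.ancestor(scope) is ancestor  # noqa: E731
    else:
        raise ValueError(f"unknown scope {scope!r}")

    def in_taxon(org) -> bool:
        return any(node is taxon for node in org.lineage)

    inside: set[FragmentKey] = set()
    outside: set[FragmentKey] = set()
    for record in scope_records:
        keys = set(_structure_fragments(record, arity, opts))
        if any(in_taxon(org) for org in record.organisms):
            inside.update(keys)
        # a structure also assigned to organisms outside the taxon counts as
        # an outside occurrence: it is not exclusive to the taxon
        if any(in_scope(org) and not in_taxon(org) for org in record.organisms):
            outside.update(keys)
    return inside - outside


def domain_frequency(
    collection: Collection,
    fragment: FragmentKey,
    domain: str,
    opts: FilterOptions = FilterOptions(),
) -> float:
    """Occurrences of ``fragment`` in a domain's structures, normalized by
    the number of structures in that domain (the fragment frequency).

    ``opts`` must match the options under which ``fragment``'s key was
    produced, otherwise keys cannot compare equal.
    """
    records = collection.records_in_domain(domain)
    if not records:
        raise ValueError(f"domain {domain!r} has no structures")
    total = 0
    for record in records:
        total += _structure_fragments(record, fragment.arity, opts).get(fragment, 0)
    return total / len(records)


def rows_to_tsv(rows: list[AbundanceRow]) -> str:
    """Render an abundance table as tab-separated values."""
    lines = ["fragment\tabsolute\trelative_pct\tshare_of_taxa_pct\tstructure_ids"]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    row.fragment.text(),
                    str(row.absolute),
                    f"{row.relative_in_selection:.2f}",
                    f"{row.share_of_taxa:.2f}",
                    ",".join(row.structure_ids),
                ]
            )
        )
    return "\n".join(lines) + "\n"
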