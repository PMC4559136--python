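"""Monomeric and dimeric fragment enumeration under configurable filters.

A fragment is a single residue (monomer) or an ordered donor–linkage–acceptor
pair (dimer) cut out of a structure graph.  Which residues take part, and how
their identity is canonicalized, is governed by :class:`FilterOptions`:
anomeric forms may be merged, monovalent residues / aglycons / aliases and
superclasses included or dropped, and fragments may additionally be annotated
with the residue position class (terminal / inline / reducing) and branching
degree.

Fragments larger than dimers are deliberately not supported: dimer profiles
already capture the biosynthesized linkages, which is what downstream
statistics operate on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .notation import (
    Anomer,
    Config,
    GlycanGraph,
    Linkage,
    Residue,
    ResidueClass,
    Ring,
    TopologyKind,
    _wrap_cycle,
)

__all__ = [
    "FilterOptions",
    "FragmentKey",
    "EXCLUDED",
    "residue_key",
    "enumerate_monomers",
    "enumerate_dimers",
    "branching_degree",
    "position_class",
]


class _Excluded:
    """Sentinel: the residue is filtered out under the active options."""

    def __repr__(self):  # pragma: no cover - cosmetic
        return "EXCLUDED"

    def __bool__(self):
        return False


EXCLUDED = _Excluded()


@dataclass(frozen=True)
class FilterOptions:
    """Fragment filtering and canonicalization options.

    ``only_saccharides`` and ``include_monovalent`` are interdependent and
    may not both be set: sugars-only mode drops every non-monosaccharide
    residue, so monovalent residues cannot simultaneously be requested.
    ``strict_comparison`` is always on — residues with unknown configurations
    compare unequal to configured ones (``?DGalp`` is not ``bDGalp``).
    """

    combine_anomers: bool = False
    include_undefined_configs: bool = True
    only_saccharides: bool = False
    include_monovalent: bool = True
    include_aglycons: bool = True
    include_aliases: bool = True
    explain_subst: bool = False
    distinguish_position: bool = False
    distinguish_branching: bool = False
    count_monovalent_in_branching: bool = True
    exclude_underdetermined: bool = False
    exclude_superclasses: bool = False
    strict_comparison: bool = True

    def __post_init__(self):
        if self.only_saccharides and self.include_monovalent:
            raise ValueError(
                "only_saccharides and include_monovalent are mutually exclusive"
            )
        if not self.strict_comparison:
            raise ValueError("strict_comparison is always enabled")

    @classmethod
    def saccharides_only(cls, **kw) -> "FilterOptions":
        return cls(only_saccharides=True, include_monovalent=False,
                   include_aglycons=False, include_aliases=False, **kw)


@dataclass(frozen=True)
class FragmentKey:
    """Canonical identity of a monomeric (arity 1) or dimeric (arity 2)
    fragment under a fixed set of filter options."""

    arity: int
    donor: str
    linkage: Linkage | None = None
    acceptor: str | None = None
    position_class: str | None = None
    branching_degree: int | None = None

    def __post_init__(self):
        if self.arity == 1 and (self.linkage is not None or self.acceptor is not None):
            raise ValueError("monomeric fragment cannot carry linkage/acceptor")
        if self.arity == 2 and (self.linkage is None or self.acceptor is None):
            raise ValueError("dimeric fragment needs linkage and acceptor")

    def text(self) -> str:
        """Render as linear-notation fragment text, e.g. ``Gal(1-3)GlcN``."""
        if self.arity == 1:
            body = self.donor
        else:
            body = f"{self.donor}{self.linkage.text()}{self.acceptor}"
        tags = []
        if self.position_class is not None:
            tags.append(self.position_class)
        if self.branching_degree is not None:
            tags.append(f"deg{self.branching_degree}")
        return body + (f" [{','.join(tags)}]" if tags else "")

    def __str__(self):
        return self.text()

    def sort_key(self):
        return (
            self.donor,
            self.linkage.text() if self.linkage else "",
            self.acceptor or "",
            self.position_class or "",
            -1 if self.branching_degree is None else self.branching_degree,
        )


def residue_key(residue: Residue, opts: FilterOptions,
                alias_table: dict[str, str] | None = None):
    """Canonical text identity of a residue, or :data:`EXCLUDED`.

    Anomeric forms are merged into a configuration-free identity when
    ``combine_anomers`` is set (``aDGlcp``/``bDGlcp`` → ``DGlcp``).  Alias
    placeholders are replaced by their declared explanation when
    ``explain_subst`` is on, otherwise kept under their placeholder name so
    that equally named aliases from different structures are pooled together.
    """
    cls = residue.residue_class
    if cls is ResidueClass.MONOVALENT:
        if opts.only_saccharides or not opts.include_monovalent:
            return EXCLUDED
        return residue.name
    if cls is ResidueClass.AGLYCON:
        if opts.only_saccharides or not opts.include_aglycons:
            return EXCLUDED
        return residue.name
    if cls in (ResidueClass.ALIAS, ResidueClass.SUPERCLASS):
        if opts.only_saccharides or not opts.include_aliases or opts.exclude_superclasses:
            return EXCLUDED
        if cls is ResidueClass.ALIAS and opts.explain_subst:
            value = residue.alias_value
            if value is None and alias_table:
                value = alias_table.get(residue.name)
            return value if value is not None else residue.name
        return residue.name
    # monosaccharide; an unknown anomer does not count as underdetermined
    # when anomeric forms are being combined anyway
    underdetermined = (
        residue.config is Config.UNKNOWN
        or residue.ring is Ring.UNKNOWN
        or (residue.anomer is Anomer.UNKNOWN and not opts.combine_anomers)
    )
    if underdetermined and (
        opts.exclude_underdetermined or not opts.include_undefined_configs
    ):
        return EXCLUDED
    if opts.combine_anomers:
        anomer = Anomer.NONE.value
        ring = residue.ring.value
        return f"{anomer}{residue.config.value}{residue.name}{ring}"
    return residue.token()


def branching_degree(graph: GlycanGraph, node: int, count_monovalent: bool = True) -> int:
    """Number of substituents of ``node``, excluding its own acceptor linkage
    at the anomeric (or default) center.

    With ``count_monovalent`` false, monovalent substituents (acetyl, methyl,
    phosphate…) are ignored: GlcN in ``Gal(1-3)GlcNAc(1-2)Man`` is di-branched
    with monovalent residues counted and linear without them.
    """
    degree = 0
    for child, _link in graph.children(node):
        if not count_monovalent and graph.nodes[child].residue_class is ResidueClass.MONOVALENT:
            continue
        degree += 1
    return degree


def position_class(graph: GlycanGraph, node: int) -> str:
    """Classify a residue's position: ``reducing`` (root), ``terminal`` (no
    non-monovalent substituents) or ``inline``.

    Members of a polymer repeating unit's wrap-around cycle have no reducing
    end and are classified ``inline`` by convention.
    """
    if graph.topology_kind is TopologyKind.POLYMER_REPEAT:
        if node in _wrap_cycle(graph):
            return "inline"
    if node == graph.root:
        return "reducing"
    has_sugar_substituent = any(
        graph.nodes[c].residue_class is not ResidueClass.MONOVALENT
        for c, _ in graph.children(node)
    )
    return "inline" if has_sugar_substituent else "terminal"


def _annotate(key_text: str, graph: GlycanGraph, node: int,
              opts: FilterOptions, arity: int,
              linkage: Linkage | None = None,
              acceptor_text: str | None = None) -> FragmentKey:
    pos = position_class(graph, node) if opts.distinguish_position else None
    deg = (
        branching_degree(graph, node, opts.count_monovalent_in_branching)
        if opts.distinguish_branching
        else None
    )
    return FragmentKey(
        arity=arity,
        donor=key_text,
        linkage=linkage,
        acceptor=acceptor_text,
        position_class=pos,
        branching_degree=deg,
    )


def enumerate_monomers(graph: GlycanGraph, opts: FilterOptions) -> Counter:
    """Multiset of monomeric fragment keys: one per non-excluded residue."""
    out: Counter = Counter()
    for i, residue in enumerate(graph.nodes):
        key = residue_key(residue, opts, graph.alias_table)
        if key is EXCLUDED:
            continue
        out[_annotate(key, graph, i, opts, arity=1)] += 1
    return out


def enumerate_dimers(graph: GlycanGraph, opts: FilterOptions) -> Counter:
    """Multiset of dimeric fragment keys: one per edge whose both endpoints
    survive filtering.

    The wrap-around linkage of a polymer repeating unit contributes one dimer
    per repeating unit.  Position/branching annotations, when requested, are
    taken from the acceptor residue, which carries the reducing-end
    semantics of the pair.
    """
    out: Counter = Counter()
    for edge in graph.edges:
        donor_key = residue_key(graph.nodes[edge.donor], opts, graph.alias_table)
        acceptor_key = residue_key(graph.nodes[edge.acceptor], opts, graph.alias_table)
        if donor_key is EXCLUDED or acceptor_key is EXCLUDED:
            continue
        out[
            _annotate(
                donor_key, graph, edge.acceptor, opts,
                arity=2, linkage=edge.linkage, acceptor_text=acceptor_key,
            )
        ] += 1
    return out


def enumerate_fragments(graph: GlycanGraph, arity: int, opts: FilterOptions) -> Counter:
    if arity == 1:
        return enumerate_monomers(graph, opts)
    if arity == 2:
        return enumerate_dimers(graph, opts)
    raise ValueError("fragment arity must be 1 or 2")
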