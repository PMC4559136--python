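"""Parsing and serialization of glycan structures in CSDB-style linear notation.

A structure is an oligomeric molecule or a polymer repeating unit built of
residues joined by glycosidic/ester/ether/amide linkages.  Every attached
entity — including monovalent substituents such as acetyl or methyl groups —
is a distinct residue.  The supported grammar is::

    line      := structure [ "//" alias ( ";" alias )* ]
    alias     := NAME "=" free-text
    structure := [ "-" pos ")" ] chain [ "(" pos "-" ]     # polymer repeat
    chain     := unit ( linkage unit )*
    unit      := branch* residue-token
    branch    := "[" chain linkage "]"
    linkage   := "(" pos "-" pos ")" | "-" pos ")"          # short form:
    pos       := "1".."9" | "?"                             # donor has one
                                                            # default center

A residue token is either a configured monosaccharide
``[a|b|?][D|L|?]Name[p|f|?]`` (e.g. ``aDGlcp``, ``?DGal?``) or a bare name
(``Gal``, ``Ac``, ``LIP``, ``Subst1``).  Shortcut forms are expanded during
parsing: ``GlcNAc`` becomes GlcN with an acetyl attached at position 2 and
``Glc-1OMe`` becomes Glc with a methyl at position 1.

The leftmost residue of a chain is a terminal donor; the rightmost residue of
the main chain is the reducing end (or aglycon) and becomes the graph root.
A polymer repeating unit opens with ``-n)`` and closes with ``(m-``; the two
open valences are joined into a single wrap-around edge.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Anomer",
    "Config",
    "Ring",
    "ResidueClass",
    "Residue",
    "Linkage",
    "Edge",
    "GlycanGraph",
    "NotationError",
    "Vocabulary",
    "DEFAULT_VOCABULARY",
    "parse_structure",
    "expand_shortcuts",
    "serialize",
]


class NotationError(ValueError):
    """Syntax or semantic error in a linear-notation string.

    Carries the 0-based character ``offset`` of the offending position.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class Anomer(str, enum.Enum):
    ALPHA = "a"
    BETA = "b"
    UNKNOWN = "?"
    NONE = ""


class Config(str, enum.Enum):
    D = "D"
    L = "L"
    UNKNOWN = "?"
    NONE = ""


class Ring(str, enum.Enum):
    PYRANOSE = "p"
    FURANOSE = "f"
    UNKNOWN = "?"
    NONE = ""


class ResidueClass(str, enum.Enum):
    MONOSACCHARIDE = "monosaccharide"
    MONOVALENT = "monovalent"
    AGLYCON = "aglycon"
    ALIAS = "alias"
    SUPERCLASS = "superclass"


# Residue-name pattern that marks an alias placeholder ("Subst", "Subst1" ...)
_ALIAS_RE = re.compile(r"^Subst\d*$")

# Configured monosaccharide token: anomer, absolute config, stem, ring size.
_CONFIGURED_RE = re.compile(r"^([ab?])([DL?])([A-Za-z0-9]+?)([pf?])$")

_TOKEN_RE = re.compile(r"[A-Za-z0-9?]+")
_LINKAGE_RE = re.compile(r"\(([1-9?])-([1-9?])\)")
_SHORT_LINKAGE_RE = re.compile(r"-([1-9?])\)")
_SHORTCUT_SUFFIX_RE = re.compile(r"-([1-9])O([A-Z][a-z]*)")


@dataclass(frozen=True)
class Vocabulary:
    """Residue classification vocabulary.

    The classification of residue names lives outside the notation itself, so
    it is shipped as editable configuration.  Unrecognized names default to
    monosaccharides; names declared in a structure's alias block are aliases.
    """

    monovalent: frozenset[str] = frozenset(
        {"Ac", "Me", "Et", "Fo", "P", "S", "EtN", "Am", "Gc", "Py"}
    )
    superclasses: frozenset[str] = frozenset({"LIP", "HEX", "PEN", "SUG", "ALD"})
    aglycons: frozenset[str] = frozenset({"Chol", "Gro", "diosgenin"})
    #: residues with a single default attachment center; their donor position
    #: may be omitted in the notation ("P-6)...").
    single_center: frozenset[str] = frozenset({"P", "S"})

    def classify(self, name: str) -> ResidueClass:
        if _ALIAS_RE.match(name):
            return ResidueClass.ALIAS
        if name in self.monovalent:
            return ResidueClass.MONOVALENT
        if name in self.superclasses:
            return ResidueClass.SUPERCLASS
        if name in self.aglycons:
            return ResidueClass.AGLYCON
        return ResidueClass.MONOSACCHARIDE


DEFAULT_VOCABULARY = Vocabulary()


@dataclass(frozen=True)
class Residue:
    """One residue: a monosaccharide, monovalent substituent, aglycon,
    alias placeholder or superclass."""

    name: str
    anomer: Anomer = Anomer.NONE
    config: Config = Config.NONE
    ring: Ring = Ring.NONE
    residue_class: ResidueClass = ResidueClass.MONOSACCHARIDE
    alias_value: str | None = None

    def __post_init__(self):
        if self.residue_class is not ResidueClass.MONOSACCHARIDE:
            if self.anomer is not Anomer.NONE or self.ring is not Ring.NONE:
                raise ValueError(
                    f"{self.residue_class.value} residue {self.name!r} must "
                    "have no anomeric/ring configuration"
                )
        if self.alias_value is not None and self.residue_class is not ResidueClass.ALIAS:
            raise ValueError("alias_value is only meaningful for alias residues")

    @property
    def underdetermined(self) -> bool:
        """True when any configuration is explicitly unknown ('?')."""
        return (
            self.anomer is Anomer.UNKNOWN
            or self.config is Config.UNKNOWN
            or self.ring is Ring.UNKNOWN
        )

    def token(self) -> str:
        # A residue with unknown anomer and no ring suffix is written without
        # the leading "?" ("DManp" rather than "?DManp"), matching the
        # database convention for mutarotating/underdetermined residues.
        anomer = self.anomer.value
        if self.anomer is Anomer.UNKNOWN and self.ring is Ring.NONE:
            anomer = ""
        return f"{anomer}{self.config.value}{self.name}{self.ring.value}"


@dataclass(frozen=True)
class Linkage:
    """A glycosidic/ester/ether/amide bond: donor position → acceptor position.

    ``donor_position`` is ``None`` for residues with a single default
    attachment center (phosphate, sulfate), written in the short form
    ``P-6)``.  ``"?"`` stands for an explicitly unknown position.
    """

    donor_position: int | str | None
    acceptor_position: int | str

    def __post_init__(self):
        for pos in (self.donor_position, self.acceptor_position):
            if pos is None or pos == "?":
                continue
            if not (isinstance(pos, int) and 1 <= pos <= 9):
                raise ValueError(f"linkage position out of range: {pos!r}")

    def text(self) -> str:
        if self.donor_position is None:
            return f"-{self.acceptor_position})"
        return f"({self.donor_position}-{self.acceptor_position})"


@dataclass(frozen=True)
class Edge:
    donor: int
    linkage: Linkage
    acceptor: int
    wrap: bool = False


class TopologyKind(str, enum.Enum):
    OLIGOMER = "oligomer"
    POLYMER_REPEAT = "polymer_repeat"
    CYCLIC = "cyclic"


@dataclass
class GlycanGraph:
    """Rooted residue/linkage graph of one structure.

    ``edges`` point donor → acceptor (toward the root).  Oligomer graphs are
    trees rooted at the reducing end/aglycon; polymer repeating units carry
    exactly one wrap-around edge in addition to the tree edges.
    """

    nodes: list[Residue]
    edges: list[Edge]
    root: int
    topology_kind: TopologyKind = TopologyKind.OLIGOMER
    alias_table: dict[str, str] = field(default_factory=dict)

    def children(self, node: int) -> list[tuple[int, Linkage]]:
        """Substituents of ``node``: (donor index, linkage) pairs, wrap edges
        excluded."""
        return [(e.donor, e.linkage) for e in self.edges if e.acceptor == node and not e.wrap]

    def validate(self) -> None:
        n = len(self.nodes)
        if not (0 <= self.root < n):
            raise ValueError("root index out of range")
        tree_edges = [e for e in self.edges if not e.wrap]
        wrap_edges = [e for e in self.edges if e.wrap]
        if self.topology_kind is TopologyKind.OLIGOMER:
            if wrap_edges:
                raise ValueError("oligomer cannot have wrap-around edges")
            if len(tree_edges) != n - 1:
                raise ValueError("oligomer must satisfy edges = nodes - 1")
        elif self.topology_kind is TopologyKind.POLYMER_REPEAT:
            if len(wrap_edges) != 1:
                raise ValueError("polymer repeat needs exactly one wrap-around edge")
        out_deg = {}
        for e in tree_edges:
            out_deg[e.donor] = out_deg.get(e.donor, 0) + 1
        for i in range(n):
            expected = 0 if i == self.root else 1
            if out_deg.get(i, 0) != expected:
                raise ValueError(
                    f"node {i} has {out_deg.get(i, 0)} outgoing edges, expected {expected}"
                )


def _parse_residue_token(token: str, offset: int, vocab: Vocabulary) -> Residue:
    m = _CONFIGURED_RE.match(token)
    if m and len(m.group(3)) >= 2:
        anomer, config, name, ring = m.groups()
        return Residue(
            name=name,
            anomer=Anomer(anomer),
            config=Config(config),
            ring=Ring(ring),
            residue_class=ResidueClass.MONOSACCHARIDE,
        )
    # configured stem without a trailing ring letter, e.g. "aDGlcpN" (ring
    # size embedded in the stem) — anomer/config prefix, rest is the name
    m = re.match(r"^([ab?])([DL?])([A-Z][A-Za-z0-9]{2,})$", token)
    if m:
        return Residue(
            name=m.group(3),
            anomer=Anomer(m.group(1)),
            config=Config(m.group(2)),
            residue_class=ResidueClass.MONOSACCHARIDE,
        )
    # config-only prefix, e.g. "DManp": anomeric configuration unknown
    m = re.match(r"^([DL])([A-Z][a-z][A-Za-z0-9]+)$", token)
    if m:
        return Residue(
            name=m.group(2),
            anomer=Anomer.UNKNOWN,
            config=Config(m.group(1)),
            residue_class=ResidueClass.MONOSACCHARIDE,
        )
    cls = vocab.classify(token)
    return Residue(name=token, residue_class=cls)


def expand_shortcuts(
    residue_token: str, vocab: Vocabulary = DEFAULT_VOCABULARY
) -> tuple[str, list[tuple[str, int]]]:
    """Split shortcut forms into a base token and attached monovalent residues.

    ``GlcNAc`` → ``("GlcN", [("Ac", 2)])`` — the N-acetyl of an amino sugar is
    a separate acetyl residue at position 2.  ``Glc-1OMe`` →
    ``("Glc", [("Me", 1)])``.  Tokens without a shortcut pass through
    unchanged.  The expansion is idempotent: the returned base token contains
    no further shortcuts.

    Raises :class:`NotationError` for an ``-nOX`` suffix whose substituent
    ``X`` is not a known monovalent residue.
    """
    attachments: list[tuple[str, int]] = []
    token = residue_token
    m = _SHORTCUT_SUFFIX_RE.search(token)
    if m:
        sub = m.group(2)
        if sub not in vocab.monovalent:
            raise NotationError(f"unknown substituent shortcut -{m.group(1)}O{sub}")
        attachments.append((sub, int(m.group(1))))
        token = token[: m.start()]
    # N-acyl shortcut on an amino sugar: ...NAc → ...N + Ac at C2.
    if token.endswith("NAc") and len(token) > 3:
        token = token[:-2]
        attachments.append(("Ac", 2))
    return token, attachments


class _Parser:
    def __init__(self, text: str, vocab: Vocabulary, strict: bool):
        self.text = text
        self.pos = 0
        self.vocab = vocab
        self.strict = strict
        self.nodes: list[Residue] = []
        self.edges: list[Edge] = []

    def error(self, msg: str) -> NotationError:
        return NotationError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _pos_value(self, ch: str) -> int | str:
        return "?" if ch == "?" else int(ch)

    def try_linkage(self) -> Linkage | None:
        m = _LINKAGE_RE.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            return Linkage(self._pos_value(m.group(1)), self._pos_value(m.group(2)))
        m = _SHORT_LINKAGE_RE.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            return Linkage(None, self._pos_value(m.group(1)))
        return None

    def add_node(self, residue: Residue) -> int:
        self.nodes.append(residue)
        return len(self.nodes) - 1

    def parse_unit(self) -> int:
        """Parse ``branch* residue-token``; return the base residue index."""
        branch_links: list[tuple[int, Linkage]] = []
        while self.peek() == "[":
            self.pos += 1
            _, donor = self.parse_chain(in_branch=True)
            link = self.try_linkage()
            if link is None:
                raise self.error("branch must end with a linkage")
            if self.peek() != "]":
                raise self.error("unbalanced '[': expected ']'")
            self.pos += 1
            branch_links.append((donor, link))
        m = _TOKEN_RE.match(self.text, self.pos)
        if not m:
            raise self.error("expected a residue token")
        raw = m.group(0)
        self.pos = m.end()
        # a shortcut suffix like "-1OMe" extends past the bare token
        sm = _SHORTCUT_SUFFIX_RE.match(self.text, self.pos)
        if sm:
            raw += sm.group(0)
            self.pos = sm.end()
        base_token, attachments = expand_shortcuts(raw, self.vocab)
        base = self.add_node(_parse_residue_token(base_token, m.start(), self.vocab))
        for sub_name, sub_pos in attachments:
            sub = self.add_node(Residue(name=sub_name, residue_class=ResidueClass.MONOVALENT))
            donor_pos = None if sub_name in self.vocab.single_center else 1
            self.edges.append(Edge(sub, Linkage(donor_pos, sub_pos), base))
        for donor, link in branch_links:
            self.edges.append(Edge(donor, link, base))
        return base

    def parse_chain(self, in_branch: bool = False) -> tuple[int, int]:
        """Parse ``unit (linkage unit)*``; return the (leftmost, rightmost)
        main-chain residue indices."""
        first = current = self.parse_unit()
        while True:
            save = self.pos
            link = self.try_linkage()
            if link is None:
                return first, current
            if self.peek() in ("", "]", " ", "/"):
                # dangling linkage belongs to an enclosing construct
                self.pos = save
                return first, current
            nxt = self.parse_unit()
            self.edges.append(Edge(current, link, nxt))
            current = nxt


def _parse_alias_block(block: str, offset: int) -> dict[str, str]:
    table: dict[str, str] = {}
    for part in block.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise NotationError(f"malformed alias declaration {part!r}", offset)
        name, value = part.split("=", 1)
        name, value = name.strip(), value.strip()
        if not name or not value:
            raise NotationError(f"malformed alias declaration {part!r}", offset)
        table[name] = value
    return table


def parse_structure(
    text: str,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    strict: bool = True,
) -> GlycanGraph:
    """Parse one linear-notation line into a :class:`GlycanGraph`.

    The rightmost residue of the main chain becomes the root (reducing end or
    aglycon).  Shortcut forms are expanded, and alias declarations after
    ``//`` populate ``alias_table``.  In strict mode an alias residue used in
    the structure but missing from the alias block is an error.
    """
    line = text.strip()
    if not line:
        raise NotationError("empty structure", 0)
    alias_table: dict[str, str] = {}
    if "//" in line:
        body, alias_block = line.split("//", 1)
        alias_table = _parse_alias_block(alias_block, line.index("//"))
        line = body.strip()

    topology = TopologyKind.OLIGOMER
    wrap_acceptor_pos: int | str | None = None
    if line.startswith("-"):
        m = _SHORT_LINKAGE_RE.match(line)
        if not m:
            raise NotationError("malformed polymer opening, expected '-n)'", 0)
        wrap_acceptor_pos = "?" if m.group(1) == "?" else int(m.group(1))
        line = line[m.end():]
        topology = TopologyKind.POLYMER_REPEAT

    wrap_donor_pos: int | str | None = None
    m = re.search(r"\(([1-9?])-$", line)
    if m:
        if topology is not TopologyKind.POLYMER_REPEAT:
            raise NotationError("polymer closing '(n-' without opening '-n)'", m.start())
        wrap_donor_pos = "?" if m.group(1) == "?" else int(m.group(1))
        line = line[: m.start()]
    elif topology is TopologyKind.POLYMER_REPEAT:
        raise NotationError("polymer opening '-n)' without closing '(n-'", len(line))

    parser = _Parser(line, vocab, strict)
    leftmost, root = parser.parse_chain()
    if parser.pos != len(line):
        raise parser.error(f"unexpected trailing text {line[parser.pos:]!r}")

    if topology is TopologyKind.POLYMER_REPEAT:
        # wrap-around: rightmost residue donates into the leftmost main-chain
        # residue of the next repeating unit.
        parser.edges.append(
            Edge(root, Linkage(wrap_donor_pos, wrap_acceptor_pos), leftmost, wrap=True)
        )

    graph = GlycanGraph(
        nodes=parser.nodes,
        edges=parser.edges,
        root=root,
        topology_kind=topology,
        alias_table=alias_table,
    )
    # attach alias explanations to alias residues
    for i, node in enumerate(graph.nodes):
        if node.residue_class is ResidueClass.ALIAS:
            if node.name in alias_table:
                graph.nodes[i] = replace(node, alias_value=alias_table[node.name])
            elif strict:
                raise NotationError(f"undeclared alias {node.name!r}")
    graph.validate()
    return graph


def _subtree_depth(graph: GlycanGraph, node: int) -> int:
    return 1 + max((_subtree_depth(graph, c) for c, _ in graph.children(node)), default=0)


def _serialize_node(graph: GlycanGraph, node: int, force_main: frozenset[int]) -> str:
    """Serialize the subtree hanging off ``node`` (node itself rightmost).

    Children in ``force_main`` (the polymer wrap-around cycle) must stay on
    the main chain so that the leftmost written residue is the wrap acceptor.
    """
    residue = graph.nodes[node]
    kids = graph.children(node)

    def sort_key(item):
        child, link = item
        # cycle members first, then a non-monovalent deepest child
        is_mono = graph.nodes[child].residue_class is ResidueClass.MONOVALENT
        return (
            child not in force_main,
            is_mono,
            -_subtree_depth(graph, child),
            graph.nodes[child].token(),
        )

    kids = sorted(kids, key=sort_key)
    # the wrap-around acceptor must stay leftmost: once inside the cycle, the
    # main chain may only continue through another cycle member
    chain_allowed = node not in force_main or any(c in force_main for c, _ in kids)
    parts = []
    if kids and chain_allowed:
        main_child, main_link = kids[0]
        parts.append(_serialize_node(graph, main_child, force_main) + main_link.text())
        branch_kids = kids[1:]
    else:
        branch_kids = kids
    for child, link in branch_kids:
        parts.append("[" + _serialize_node(graph, child, force_main) + link.text() + "]")
    parts.append(residue.token())
    return "".join(parts)


def _wrap_cycle(graph: GlycanGraph) -> frozenset[int]:
    """Main-chain members of a polymer repeating unit: the path from the
    wrap-around acceptor up to the root."""
    wrap = next(e for e in graph.edges if e.wrap)
    cycle = {wrap.acceptor}
    cur = wrap.acceptor
    while cur != graph.root:
        cur = next(e.acceptor for e in graph.edges if e.donor == cur and not e.wrap)
        cycle.add(cur)
    return frozenset(cycle)


def serialize(graph: GlycanGraph) -> str:
    """Render a graph back to canonical linear-notation text.

    ``parse_structure(serialize(g))`` is isomorphic to ``g``; the exact string
    may differ from the input (branch ordering is canonicalized).
    """
    force_main: frozenset[int] = frozenset()
    if graph.topology_kind is TopologyKind.POLYMER_REPEAT:
        force_main = _wrap_cycle(graph)
    body = _serialize_node(graph, graph.root, force_main)
    if graph.topology_kind is TopologyKind.POLYMER_REPEAT:
        wrap = next(e for e in graph.edges if e.wrap)
        donor_pos = wrap.linkage.donor_position
        acceptor_pos = wrap.linkage.acceptor_position
        body = f"-{acceptor_pos}){body}({donor_pos}-"
    if graph.alias_table:
        decls = "; ".join(f"{k} = {v}" for k, v in sorted(graph.alias_table.items()))
        body = f"{body} // {decls}"
    return body
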