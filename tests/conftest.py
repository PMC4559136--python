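"""Shared fixtures: hand-written structure collections built at test time."""

from __future__ import annotations

import pytest

from glycostat.datamodel import Collection, read_dump

HEADER = "structure_id\tnotation\tlineage\tyear\tnmr_count\tstructure_type\tpublication_id"

_BACT = "domain=Bacteria;kingdom=Eubacteria;phylum=PhyA;class=ClsA"
_BACT_B = "domain=Bacteria;kingdom=Eubacteria;phylum=PhyB;class=ClsB"
_FUNGI = "domain=Fungi;kingdom=Mycota;phylum=PhyF;class=ClsF"

#: one row per (structure, organism, publication)
SMALL_DUMP_ROWS = [
    # X1/X2: genus GenA1, two species; X2 is shared by both species
    ("X1", "aDGlcp(1-3)bDGalp", f"{_BACT};genus=GenA1;species=A1 alpha", 2000, 1,
     "mono_oligomer", "P1"),
    ("X2", "aDGlcp(1-3)bDGalp(1-4)aDGlcp", f"{_BACT};genus=GenA1;species=A1 alpha",
     2001, 0, "mono_oligomer", "P2"),
    ("X2", "aDGlcp(1-3)bDGalp(1-4)aDGlcp", f"{_BACT};genus=GenA1;species=A1 beta",
     2001, 0, "mono_oligomer", "P2"),
    # X3: genus GenA2, same phylum; shares publication P2
    ("X3", "aDManp(1-2)aDManp", f"{_BACT};genus=GenA2;species=A2 gamma", 2001, 2,
     "polymer", "P2"),
    # X4: phylum PhyB
    ("X4", "aLRhap(1-5)aDManp", f"{_BACT_B};genus=GenB1;species=B1 delta", 2005, 0,
     "mono_oligomer", "P3"),
    # X5: fungal record with a dimer unique to fungi
    ("X5", "bDXylp(1-6)aDGlcp", f"{_FUNGI};genus=GenF1;species=F1 eps", 2010, 3,
     "mono_oligomer", "P4"),
    # X6: one structure assigned to species in two different phyla
    ("X6", "aDGlcp(1-2)aDManp", f"{_BACT};genus=GenA1;species=A1 alpha", 2008, 0,
     "mono_oligomer", "P5"),
    ("X6", "aDGlcp(1-2)aDManp", f"{_BACT_B};genus=GenB1;species=B1 delta", 2008, 0,
     "mono_oligomer", "P5"),
]


def rows_to_dump_text(rows) -> str:
    lines = [HEADER]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def make_collection(tmp_path, rows, name="dump.tsv") -> Collection:
    path = tmp_path / name
    path.write_text(rows_to_dump_text(rows), encoding="utf-8")
    return read_dump(path)


@pytest.fixture
def small_collection(tmp_path) -> Collection:
    return make_collection(tmp_path, SMALL_DUMP_ROWS)


@pytest.fixture
def small_dump_path(tmp_path):
    path = tmp_path / "dump.tsv"
    path.write_text(rows_to_dump_text(SMALL_DUMP_ROWS), encoding="utf-8")
    return path
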