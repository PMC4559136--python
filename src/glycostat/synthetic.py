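"""Seeded generator of synthetic structure collections with planted
taxon-group-specific dimer preferences.

The generator emulates a taxonomy-annotated glycan collection at a small,
controlled scale: ``n_groups`` phyla, each holding ``taxa_per_group`` genera
(one species per genus), each genus carrying ``structures_per_taxon`` linear
oligomer structures.  Consecutive linkages of a structure are drawn from the
group's dimer pool with probability ``1 - noise_rate`` and from a global,
group-unspecific pool otherwise.  By default the group pools are disjoint:
each group links donors through its own acceptor position (``3 + group``),
while the noise pool uses position 2, so the planted partition is
recoverable from dimer occurrence profiles.

Everything is driven by a single seeded generator with a fixed generation
order (groups, then taxa, then structures); the same spec produces a
byte-identical dump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Collection, StructureRecord, Taxonomy
from .notation import parse_structure

__all__ = ["SimulationSpec", "PoolEntry", "generate_collection", "DEFAULT_ALPHABET"]

#: fully configured pyranose residues common in natural glycans
DEFAULT_ALPHABET = ["aDGlcp", "bDGalp", "aDManp", "aLRhap", "bDXylp", "aLFucp"]

#: acceptor linkage position used by the group-unspecific (noise) pool
_NOISE_POSITION = 2

#: weighted dimer preference: donor token, donor position, acceptor
#: position, acceptor token, weight
PoolEntry = tuple[str, int, int, str, float]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic collection.

    ``group_fragment_pools`` maps a group index to a weighted list of
    :data:`PoolEntry` items; when ``None``, disjoint pools are derived from
    ``residue_alphabet``: group ``g`` uses every ordered residue pair linked
    ``(1-{3+g})``, the noise pool the same pairs linked ``(1-2)``.
    """

    n_groups: int = 3
    taxa_per_group: int = 5
    structures_per_taxon: int = 15
    residue_alphabet: tuple[str, ...] = tuple(DEFAULT_ALPHABET)
    group_fragment_pools: dict[int, tuple[PoolEntry, ...]] | None = None
    noise_rate: float = 0.05
    mean_structure_length: int = 6
    seed: int = 0

    def __post_init__(self):
        if not self.residue_alphabet:
            raise ValueError("residue alphabet must not be empty")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must be a probability")
        for name, value in [
            ("n_groups", self.n_groups),
            ("taxa_per_group", self.taxa_per_group),
            ("structures_per_taxon", self.structures_per_taxon),
            ("mean_structure_length", self.mean_structure_length),
        ]:
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.group_fragment_pools is None and self.n_groups > 6:
            raise ValueError("default pools support at most 6 groups")


def _default_pool(alphabet: tuple[str, ...], acceptor_pos: int) -> list[PoolEntry]:
    return [
        (donor, 1, acceptor_pos, acceptor, 1.0)
        for donor in alphabet
        for acceptor in alphabet
    ]


def _pools_for(spec: SimulationSpec) -> tuple[dict[int, list[PoolEntry]], list[PoolEntry]]:
    if spec.group_fragment_pools is not None:
        groups = {g: list(entries) for g, entries in spec.group_fragment_pools.items()}
        missing = [g for g in range(spec.n_groups) if g not in groups]
        if missing:
            raise ValueError(f"group_fragment_pools missing groups {missing}")
        noise = sorted({e for entries in groups.values() for e in entries})
        return groups, noise
    groups = {
        g: _default_pool(spec.residue_alphabet, 3 + g) for g in range(spec.n_groups)
    }
    noise = _default_pool(spec.residue_alphabet, _NOISE_POSITION)
    return groups, noise


def _weighted_choice(rng: np.random.Generator, entries: list[PoolEntry]) -> PoolEntry:
    weights = np.array([e[4] for e in entries], dtype=float)
    idx = rng.choice(len(entries), p=weights / weights.sum())
    return entries[int(idx)]


def _draw_chain(
    rng: np.random.Generator,
    spec: SimulationSpec,
    group_pool: list[PoolEntry],
    noise_pool: list[PoolEntry],
) -> str:
    """One linear oligomer, assembled root-first from pool dimers.

    Each extension prefers pool entries whose acceptor matches the current
    leftmost residue so that realized dimers come from the pool; if the pool
    has no matching acceptor the constraint is dropped for that step.
    """
    length = max(2, int(rng.poisson(spec.mean_structure_length)))
    root_entry = _weighted_choice(
        rng, group_pool if rng.random() >= spec.noise_rate else noise_pool
    )
    head = root_entry[3]
    parts = [head]
    for _ in range(length - 1):
        pool = group_pool if rng.random() >= spec.noise_rate else noise_pool
        candidates = [e for e in pool if e[3] == head] or pool
        donor, dpos, apos, _acc, _w = _weighted_choice(rng, candidates)
        parts.append(f"({dpos}-{apos})")
        parts.append(donor)
        head = donor
    return "".join(reversed(parts))


def generate_collection(spec: SimulationSpec) -> Collection:
    """Generate a deterministic synthetic collection for ``spec``.

    Taxonomy: ``n_groups`` phyla × ``taxa_per_group`` genera, one species
    per genus; ``structures_per_taxon`` records per genus.
    """
    rng = np.random.default_rng(spec.seed)
    group_pools, noise_pool = _pools_for(spec)
    taxonomy = Taxonomy()
    records: list[StructureRecord] = []
    for g in range(spec.n_groups):
        phylum = f"Phylum{g + 1:02d}"
        for t in range(spec.taxa_per_group):
            genus = f"Genus{g + 1:02d}x{t + 1:02d}"
            species = f"{genus} typica"
            leaf = taxonomy.add_lineage(
                [
                    ("domain", "Bacteria"),
                    ("kingdom", "Eubacteria"),
                    ("phylum", phylum),
                    ("genus", genus),
                    ("species", species),
                ]
            )
            for s in range(spec.structures_per_taxon):
                notation = _draw_chain(rng, spec, group_pools[g], noise_pool)
                sid = f"S{g + 1:02d}{t + 1:02d}{s + 1:03d}"
                year = int(1990 + rng.integers(24))
                records.append(
                    StructureRecord(
                        id=sid,
                        notation=notation,
                        graph=parse_structure(notation),
                        structure_type="mono_oligomer",
                        organisms=[leaf],
                        publications=[(f"P{sid}", year)],
                        nmr_count=int(rng.integers(4)),
                    )
                )
    return Collection(records, taxonomy)
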