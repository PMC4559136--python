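"""Glycome-based taxon clustering.

The pipeline mirrors the flow of the online taxon-clustering tool:

1. build a *taxon pool* — taxa of a chosen rank passing population
   thresholds (absolute and/or relative to their database partition);
2. build a *fragment pool* — mono- or dimeric fragments abundant enough in
   the whole collection (minimum containing structures and total instances);
3. encode each taxon as a binary *occurrence code* over the ordered pool
   (bit set when the fragment occurs at least θ times in the taxon's
   structures) — a phylogenetic profile in the sense of Pellegrini et al.;
4. compare codes pairwise by Hamming distance, normalize each cell by the
   summed structure counts of the two taxa (study-bias correction), rescale
   the whole matrix to a maximum of 100;
5. build phenetic trees by hierarchical agglomeration (UPGMA, complete
   linkage, Ward's D2), neighbor joining (classical or BIONJ) or minimum
   evolution (OLS or balanced criterion, NNI search), and export matrices
   (Phylip / TSV / R) and trees (Newick / Nexus).

All procedures are deterministic: ties between equally good candidate pairs
are broken lexicographically by label.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .datamodel import Collection, StructureRecord, TaxonNode
from .fragments import FilterOptions, FragmentKey, enumerate_fragments

__all__ = [
    "PoolThresholds",
    "OccurrenceProfile",
    "DissimilarityMatrix",
    "EmptyPoolError",
    "build_taxon_pool",
    "build_fragment_pool",
    "occurrence_code",
    "hamming",
    "dissimilarity_matrix",
    "hierarchical_tree",
    "nj_tree",
    "minimum_evolution_tree",
    "build_tree",
    "export_matrix",
    "export_tree",
    "ClusteringResult",
    "run_clustering",
    "cut_tree",
]

HIERARCHICAL_METHODS = ("upgma", "complete", "ward_d2")
TREE_METHODS = HIERARCHICAL_METHODS + ("nj", "bionj", "me_ols", "me_balanced")

#: domains whose most biologically active structures are polymers; the
#: "optimized" structure scope takes polymers from these and oligomers from
#: everything else
_POLYMER_DOMAINS = {"Bacteria", "Fungi", "Archaea"}


class EmptyPoolError(ValueError):
    """A taxon or fragment pool came out empty; lower the thresholds."""


@dataclass(frozen=True)
class PoolThresholds:
    """Thresholds steering taxon-pool and fragment-pool construction.

    Defaults follow the published genus/species analyses: presence threshold
    θ=2 occurrences, fragment pool of dimers present at least 120 times in
    at least 100 structures, absolute taxon population minimum of 20
    structures and a relative minimum of 1.2% of the database partition.
    """

    population_abs_min: int = 20
    population_rel_min: float = 0.012
    use_abs: bool = True
    use_rel: bool = False
    fragment_min_structures: int = 100
    fragment_min_instances: int = 120
    presence_threshold: int = 2
    fragment_arity: int = 2
    structure_scope: str = "any"

    def __post_init__(self):
        if self.presence_threshold < 1:
            raise ValueError("presence threshold must be >= 1")
        if self.fragment_arity not in (1, 2):
            raise ValueError("fragment arity must be 1 or 2")
        if self.structure_scope not in ("any", "only_polymers", "only_oligomers", "optimized"):
            raise ValueError(f"unknown structure scope {self.structure_scope!r}")
        if self.fragment_min_instances < self.fragment_min_structures:
            raise ValueError(
                "fragment_min_instances must be >= fragment_min_structures "
                "(a structure may contain several identical fragments)"
            )
        if self.fragment_min_instances == self.fragment_min_structures:
            warnings.warn(
                "fragment instance threshold equals the structure threshold; "
                "it is normally set higher", stacklevel=2,
            )


@dataclass(frozen=True)
class OccurrenceProfile:
    """Binary glycoprofile of one taxon over an ordered fragment pool."""

    taxon: TaxonNode
    bits: tuple[int, ...]
    n_structures: int

    @property
    def label(self) -> str:
        return self.taxon.name

    def bitstring(self) -> str:
        return "".join(map(str, self.bits))


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("matrix diagonal must be zero")

    def max_offdiag(self) -> float:
        if len(self.labels) < 2:
            return 0.0
        mask = ~np.eye(len(self.labels), dtype=bool)
        return float(self.values[mask].max())


def _record_in_scope(collection: Collection, record: StructureRecord, scope: str) -> bool:
    if scope == "any":
        return True
    is_oligomer = record.structure_type == "mono_oligomer"
    if scope == "only_polymers":
        return not is_oligomer
    if scope == "only_oligomers":
        return is_oligomer
    # optimized: polymers from bacteria/fungi/archaea, oligomers elsewhere
    if collection.domain_of(record) in _POLYMER_DOMAINS:
        return not is_oligomer
    return is_oligomer


def _scoped_records(collection: Collection, scope: str) -> list[StructureRecord]:
    return [r for r in collection.records if _record_in_scope(collection, r, scope)]


def build_taxon_pool(
    collection: Collection,
    rank: str,
    scope: TaxonNode | None = None,
    thresholds: PoolThresholds = PoolThresholds(),
    explicit_list: list[TaxonNode] | None = None,
) -> list[tuple[TaxonNode, int]]:
    """Taxa at ``rank`` passing the population thresholds, with their
    structure counts N_t.

    The relative threshold normalizes a taxon's population by the total
    number of structures in the database partition (domain group) the taxon
    belongs to.  ``explicit_list`` bypasses thresholds entirely.  Taxa are
    ordered by name; N_t counts structures within the structure scope.
    """
    if explicit_list is not None:
        taxa = list(explicit_list)
    else:
        taxa = collection.taxonomy.at_rank(rank, scope)
        kept = []
        group_sizes: dict[str, int] = {}
        for record in collection.records:
            group = collection.domain_group_of(record)
            group_sizes[group] = group_sizes.get(group, 0) + 1
        for taxon in taxa:
            pop = collection.population(taxon)
            if pop == 0:
                continue
            if thresholds.use_abs and pop < thresholds.population_abs_min:
                continue
            if thresholds.use_rel:
                group = collection.domain_groups.get(taxon.domain.name, taxon.domain.name)
                total = group_sizes.get(group, 0)
                if total == 0 or pop / total < thresholds.population_rel_min:
                    continue
            kept.append(taxon)
        taxa = kept
    if not taxa:
        raise EmptyPoolError(
            "taxon pool is empty; lower the population thresholds or widen the scope"
        )
    taxa = sorted(taxa, key=lambda t: t.name)
    pool = []
    for taxon in taxa:
        n_scoped = sum(
            1
            for r in collection.records_under(taxon)
            if _record_in_scope(collection, r, thresholds.structure_scope)
        )
        pool.append((taxon, n_scoped))
    return pool


def build_fragment_pool(
    collection: Collection,
    thresholds: PoolThresholds = PoolThresholds(),
    pool_filters: FilterOptions = FilterOptions(),
) -> list[FragmentKey]:
    """Fragments present in at least ``fragment_min_structures`` structures
    with at least ``fragment_min_instances`` total instances, in
    deterministic lexicographic order."""
    per_structure: dict[FragmentKey, int] = {}
    instances: dict[FragmentKey, int] = {}
    for record in _scoped_records(collection, thresholds.structure_scope):
        counts = enumerate_fragments(record.graph, thresholds.fragment_arity, pool_filters)
        for key, count in counts.items():
            per_structure[key] = per_structure.get(key, 0) + 1
            instances[key] = instances.get(key, 0) + count
    pool = [
        key
        for key in per_structure
        if per_structure[key] >= thresholds.fragment_min_structures
        and instances[key] >= thresholds.fragment_min_instances
    ]
    if not pool:
        raise EmptyPoolError("fragment pool is empty; lower the abundance thresholds")
    return sorted(pool, key=lambda k: k.sort_key())


def occurrence_code(
    collection: Collection,
    taxon: TaxonNode,
    pool: list[FragmentKey],
    presence_threshold: int = 2,
    fragment_arity: int = 2,
    pool_filters: FilterOptions = FilterOptions(),
    structure_scope: str = "any",
) -> OccurrenceProfile:
    """Binary occurrence code of ``taxon`` over the ordered fragment pool.

    Bit k is set when pool fragment k occurs at least ``presence_threshold``
    times across the taxon's (scoped) structures.
    """
    if not pool:
        raise ValueError("fragment pool must not be empty")
    totals: dict[FragmentKey, int] = {}
    n_structures = 0
    for record in collection.records_under(taxon):
        if not _record_in_scope(collection, record, structure_scope):
            continue
        n_structures += 1
        for key, count in enumerate_fragments(
            record.graph, fragment_arity, pool_filters
        ).items():
            totals[key] = totals.get(key, 0) + count
    bits = tuple(
        1 if totals.get(key, 0) >= presence_threshold else 0 for key in pool
    )
    return OccurrenceProfile(taxon=taxon, bits=bits, n_structures=n_structures)


def hamming(a: OccurrenceProfile | tuple, b: OccurrenceProfile | tuple) -> int:
    """Number of differing bit positions between two equal-length codes."""
    bits_a = a.bits if isinstance(a, OccurrenceProfile) else tuple(a)
    bits_b = b.bits if isinstance(b, OccurrenceProfile) else tuple(b)
    if len(bits_a) != len(bits_b):
        raise ValueError(f"bit string lengths differ: {len(bits_a)} vs {len(bits_b)}")
    return sum(x != y for x, y in zip(bits_a, bits_b))


def dissimilarity_matrix(profiles: list[OccurrenceProfile]) -> DissimilarityMatrix:
    """Normalized taxon dissimilarity matrix.

    Raw entries are Hamming distances divided by the summed structure counts
    of the two taxa (study-bias normalization); the whole matrix is then
    rescaled so its maximum is 100.  When all profiles coincide the matrix
    is returned unscaled with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    lengths = {len(p.bits) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have differing lengths")
    n = len(profiles)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        denom = profiles[i].n_structures + profiles[j].n_structures
        raw = hamming(profiles[i], profiles[j]) / denom if denom else 0.0
        values[i, j] = values[j, i] = raw
    labels = [p.label for p in profiles]
    max_raw = values.max()
    if max_raw > 0:
        values = values * (100.0 / max_raw)
        return DissimilarityMatrix(labels=labels, values=values, scaled=True)
    warnings.warn("all profiles identical; matrix left unscaled", stacklevel=2)
    return DissimilarityMatrix(labels=labels, values=values, scaled=False)


# ---------------------------------------------------------------------------
# hierarchical agglomeration (Lance–Williams recurrences)


def _pair_key(label_a: str, label_b: str) -> tuple[str, str]:
    return (label_a, label_b) if label_a <= label_b else (label_b, label_a)


def hierarchical_tree(matrix: DissimilarityMatrix, method: str = "upgma") -> TreeNode:
    """Rooted dendrogram by agglomerative clustering.

    ``upgma`` merges by average inter-cluster distance and yields an
    ultrametric tree; ``complete`` by maximum distance; ``ward_d2`` by
    Ward's minimum-variance criterion on squared dissimilarities with merge
    heights reported on the original scale (square roots).  Node heights are
    half the merge distance, so two taxa at distance 100 join with 50-long
    leaf branches.  Equal candidate pairs merge lexicographically smallest
    first, by the smallest leaf label of each cluster.
    """
    if method not in HIERARCHICAL_METHODS:
        raise ValueError(f"unknown hierarchical method {method!r}")
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    squared = method == "ward_d2"
    # cluster state: id -> (node, label, size, height)
    nodes: dict[int, TreeNode] = {}
    labels: dict[int, str] = {}
    sizes: dict[int, int] = {}
    heights: dict[int, float] = {}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        nodes[i] = TreeNode(name=matrix.labels[i])
        labels[i] = matrix.labels[i]
        sizes[i] = 1
        heights[i] = 0.0
    for i, j in itertools.combinations(range(n), 2):
        d = matrix.values[i, j]
        dist[(i, j)] = d * d if squared else d
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            d = dist[(min(i, j), max(i, j))]
            key = (d, _pair_key(labels[i], labels[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _key, ci, cj = best
        d_merge = dist[(min(ci, cj), max(ci, cj))]
        height = (np.sqrt(d_merge) if squared else d_merge) / 2.0
        parent = TreeNode()
        for cid in (ci, cj):
            child = nodes[cid]
            child.length = height - heights[cid]
            parent.append(child)
        nodes[next_id] = parent
        labels[next_id] = min(labels[ci], labels[cj])
        sizes[next_id] = sizes[ci] + sizes[cj]
        heights[next_id] = height
        ni, nj = sizes[ci], sizes[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            d_ik = dist[(min(ci, ck), max(ci, ck))]
            d_jk = dist[(min(cj, ck), max(cj, ck))]
            nk = sizes[ck]
            if method == "upgma":
                d_new = (ni * d_ik + nj * d_jk) / (ni + nj)
            elif method == "complete":
                d_new = max(d_ik, d_jk)
            else:  # ward_d2 on squared dissimilarities
                d_ij = dist[(min(ci, cj), max(ci, cj))]
                d_new = (
                    (ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij
                ) / (ni + nj + nk)
            dist[(min(next_id, ck), max(next_id, ck))] = d_new
        active = [c for c in active if c not in (ci, cj)] + [next_id]
        next_id += 1
    root = nodes[active[0]]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# neighbor joining and BIONJ


def nj_tree(matrix: DissimilarityMatrix, variant: str = "nj") -> TreeNode:
    """Unrooted neighbor-joining tree (classical or BIONJ).

    Both variants pick the pair minimizing the Q criterion; they differ in
    the matrix-reduction step, where BIONJ chooses the convex combination
    minimizing the variance of the reduced matrix.  Both reproduce additive
    matrices exactly; branch lengths may come out negative.  The returned
    tree is rooted at an internal trifurcation (unrooted convention).
    """
    if variant not in ("nj", "bionj"):
        raise ValueError(f"unknown NJ variant {variant!r}")
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=matrix.labels[i]) for i in range(n)
    }
    labels = {i: matrix.labels[i] for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    v: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = v[(i, j)] = float(matrix.values[i, j])

    def D(i, j):
        return d[(min(i, j), max(i, j))]

    def V(i, j):
        return v[(min(i, j), max(i, j))]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (m - 2) * D(i, j) - r[i] - r[j]
            key = (q, _pair_key(labels[i], labels[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _key, ci, cj = best
        d_ij = D(ci, cj)
        li = d_ij / 2.0 + (r[ci] - r[cj]) / (2.0 * (m - 2))
        lj = d_ij - li
        parent = TreeNode()
        nodes[ci].length = li
        nodes[cj].length = lj
        parent.append(nodes[ci])
        parent.append(nodes[cj])
        nodes[next_id] = parent
        labels[next_id] = min(labels[ci], labels[cj])
        others = [k for k in active if k not in (ci, cj)]
        if variant == "bionj" and V(ci, cj) > 0 and m > 3:
            lam = 0.5 + sum(V(cj, k) - V(ci, k) for k in others) / (
                2.0 * (m - 2) * V(ci, cj)
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        for ck in others:
            d_new = lam * (D(ci, ck) - li) + (1.0 - lam) * (D(cj, ck) - lj)
            v_new = lam * V(ci, ck) + (1.0 - lam) * V(cj, ck) - lam * (1.0 - lam) * V(ci, cj)
            d[(min(next_id, ck), max(next_id, ck))] = d_new
            v[(min(next_id, ck), max(next_id, ck))] = v_new
        active = others + [next_id]
        next_id += 1

    a, b, c = sorted(active, key=lambda i: labels[i])
    root = TreeNode()
    la = (D(a, b) + D(a, c) - D(b, c)) / 2.0
    lb = (D(a, b) + D(b, c) - D(a, c)) / 2.0
    lc = (D(a, c) + D(b, c) - D(a, b)) / 2.0
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
        root.append(nodes[idx])
    return root


# ---------------------------------------------------------------------------
# minimum evolution (OLS and balanced criteria, NNI search)


class _Unrooted:
    """Adjacency representation of an unrooted binary leaf-labelled tree."""

    def __init__(self):
        self.adj: dict[int, set[int]] = {}
        self.leaf_name: dict[int, str] = {}
        self._next = 0

    @classmethod
    def from_treenode(cls, tree: TreeNode) -> "_Unrooted":
        ut = cls()

        def walk(node: TreeNode) -> int:
            nid = ut._new(node.name if node.is_tip() else None)
            for child in node.children:
                cid = walk(child)
                ut._connect(nid, cid)
            return nid

        walk(tree)
        ut._suppress_degree_two()
        return ut

    def _new(self, name: str | None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def _connect(self, a: int, b: int):
        self.adj[a].add(b)
        self.adj[b].add(a)

    def _suppress_degree_two(self):
        for nid in list(self.adj):
            if nid in self.leaf_name:
                continue
            if len(self.adj[nid]) == 2:
                a, b = sorted(self.adj[nid])
                self.adj[a].discard(nid)
                self.adj[b].discard(nid)
                self._connect(a, b)
                del self.adj[nid]

    def leaves(self) -> list[int]:
        return sorted(self.leaf_name, key=lambda i: self.leaf_name[i])

    def internal_edges(self) -> list[tuple[int, int]]:
        edges = []
        for a in self.adj:
            for b in self.adj[a]:
                if a < b and a not in self.leaf_name and b not in self.leaf_name:
                    edges.append((a, b))
        # deterministic order: by the sorted leaf names behind each endpoint
        def edge_key(edge):
            a, b = edge
            side = self._side_leaves(a, b)
            return tuple(sorted(self.leaf_name[x] for x in side))

        return sorted(edges, key=edge_key)

    def _side_leaves(self, start: int, blocked: int) -> set[int]:
        seen = {blocked, start}
        stack = [start]
        out = set()
        while stack:
            cur = stack.pop()
            if cur in self.leaf_name:
                out.add(cur)
            for nxt in self.adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if start in self.leaf_name:
            out.add(start)
        return out

    def topological_distances(self) -> dict[tuple[str, str], int]:
        """Edge-count distances between all leaf pairs."""
        out: dict[tuple[str, str], int] = {}
        for leaf in self.leaves():
            dist = {leaf: 0}
            stack = [leaf]
            while stack:
                cur = stack.pop()
                for nxt in self.adj[cur]:
                    if nxt not in dist:
                        dist[nxt] = dist[cur] + 1
                        stack.append(nxt)
            for other in self.leaves():
                if self.leaf_name[leaf] < self.leaf_name[other]:
                    out[(self.leaf_name[leaf], self.leaf_name[other])] = dist[other]
        return out

    def edge_splits(self) -> list[tuple[tuple[int, int], frozenset[str]]]:
        """All edges with the leaf-name set on the smaller-id side."""
        out = []
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    side = frozenset(self.leaf_name[x] for x in self._side_leaves(a, b))
                    out.append(((a, b), side))
        return out

    def nni_neighbors(self, edge: tuple[int, int]):
        """The two NNI rearrangements across an internal edge, as
        (swap_a, swap_b) node pairs to exchange."""
        a, b = edge
        a_subs = sorted(x for x in self.adj[a] if x != b)
        b_subs = sorted(x for x in self.adj[b] if x != a)
        # exchanging a_subs[1] with either neighbor of b gives both
        # alternative topologies around the edge
        return [(a_subs[1], b_subs[0]), (a_subs[1], b_subs[1])]

    def swap(self, edge: tuple[int, int], pair: tuple[int, int]):
        a, b = edge
        x, y = pair
        self.adj[a].remove(x)
        self.adj[x].remove(a)
        self.adj[b].remove(y)
        self.adj[y].remove(b)
        self._connect(a, y)
        self._connect(b, x)

    def copy(self) -> "_Unrooted":
        ut = _Unrooted()
        ut.adj = {k: set(v) for k, v in self.adj.items()}
        ut.leaf_name = dict(self.leaf_name)
        ut._next = self._next
        return ut

    def to_treenode(self, lengths: dict[frozenset[int], float] | None = None) -> TreeNode:
        # root at the internal node adjacent to the lexicographically first leaf
        first = self.leaves()[0]
        root_id = next(iter(self.adj[first]))

        def build(nid: int, parent: int) -> TreeNode:
            if nid in self.leaf_name:
                node = TreeNode(name=self.leaf_name[nid])
            else:
                node = TreeNode()
                for nxt in sorted(
                    (x for x in self.adj[nid] if x != parent),
                    key=lambda x: min(self.leaf_name[l] for l in self._side_leaves(x, nid)),
                ):
                    node.append(build(nxt, nid))
            if lengths is not None and parent >= 0:
                node.length = lengths[frozenset((nid, parent))]
            return node

        return build(root_id, -1)


def _ols_edge_lengths(ut: _Unrooted, matrix: DissimilarityMatrix):
    """Least-squares branch lengths fitting leaf-pair path distances."""
    labels = matrix.labels
    index = {name: i for i, name in enumerate(labels)}
    splits = ut.edge_splits()
    pairs = list(itertools.combinations(sorted(labels), 2))
    A = np.zeros((len(pairs), len(splits)))
    y = np.zeros(len(pairs))
    for row, (u, w) in enumerate(pairs):
        y[row] = matrix.values[index[u], index[w]]
        for col, (_edge, side) in enumerate(splits):
            if (u in side) != (w in side):
                A[row, col] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    lengths = {frozenset(edge): float(val) for (edge, _side), val in zip(splits, x)}
    return lengths


def _tree_length(ut: _Unrooted, matrix: DissimilarityMatrix, scheme: str) -> float:
    if scheme == "balanced":
        # Pauplin's formula: balanced length = Σ 2^(1 - topo_dist) * d
        index = {name: i for i, name in enumerate(matrix.labels)}
        total = 0.0
        for (u, w), p in ut.topological_distances().items():
            total += (2.0 ** (1 - p)) * matrix.values[index[u], index[w]]
        return total
    lengths = _ols_edge_lengths(ut, matrix)
    return float(sum(lengths.values()))


def minimum_evolution_tree(matrix: DissimilarityMatrix, scheme: str = "balanced") -> TreeNode:
    """Minimum-evolution tree under the OLS or balanced total-length
    criterion.

    Search: nearest-neighbor-interchange hill climbing from a BIONJ starting
    topology, first improvement, deterministic edge order.  The balanced
    criterion weights sibling subtrees equally (evaluated through Pauplin's
    closed form); the OLS criterion sums least-squares branch lengths.
    Branch lengths of the final tree are OLS estimates; on additive matrices
    both schemes recover the generating topology and exact lengths.
    """
    if scheme not in ("ols", "balanced"):
        raise ValueError(f"unknown minimum-evolution scheme {scheme!r}")
    if len(matrix.labels) < 3:
        raise ValueError("minimum evolution needs at least three taxa")
    start = nj_tree(matrix, variant="bionj")
    ut = _Unrooted.from_treenode(start)
    current = _tree_length(ut, matrix, scheme)
    improved = True
    while improved:
        improved = False
        for edge in ut.internal_edges():
            for pair in ut.nni_neighbors(edge):
                trial = ut.copy()
                trial.swap(edge, pair)
                score = _tree_length(trial, matrix, scheme)
                if score < current - 1e-12:
                    ut = trial
                    current = score
                    improved = True
                    break
            if improved:
                break
    lengths = _ols_edge_lengths(ut, matrix)
    return ut.to_treenode(lengths)


def build_tree(matrix: DissimilarityMatrix, method: str) -> TreeNode:
    """Dispatch on method name: upgma / complete / ward_d2 / nj / bionj /
    me_ols / me_balanced."""
    if method in HIERARCHICAL_METHODS:
        return hierarchical_tree(matrix, method)
    if method in ("nj", "bionj"):
        return nj_tree(matrix, method)
    if method == "me_ols":
        return minimum_evolution_tree(matrix, "ols")
    if method == "me_balanced":
        return minimum_evolution_tree(matrix, "balanced")
    raise ValueError(f"unknown tree method {method!r}")


# ---------------------------------------------------------------------------
# exports


def export_matrix(matrix: DissimilarityMatrix, fmt: str) -> str:
    """Serialize a dissimilarity matrix: ``phylip`` (square, labels padded
    to 10 characters), ``tsv`` (header + rows) or ``r`` (lower-triangle
    ``dist``-style text)."""
    labels = matrix.labels
    values = matrix.values
    if fmt == "phylip":
        short = [lab[:10] for lab in labels]
        if len(set(short)) != len(short):
            raise ValueError("labels collide after truncation to 10 characters")
        lines = [f"{len(labels)}"]
        for lab, row in zip(short, values):
            lines.append(lab.ljust(10) + " " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"
    if fmt == "tsv":
        lines = ["taxon\t" + "\t".join(labels)]
        for lab, row in zip(labels, values):
            lines.append(lab + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"
    if fmt == "r":
        # lower-triangular layout as printed by R's dist objects
        lines = ["\t" + "\t".join(labels[:-1])]
        for i in range(1, len(labels)):
            vals = "\t".join(f"{values[i, j]:.6f}" for j in range(i))
            lines.append(labels[i] + "\t" + vals)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown matrix format {fmt!r}")


def export_tree(tree: TreeNode, fmt: str) -> str:
    """Serialize a tree as ``newick`` or a minimal ``nexus`` TREES block."""
    buf = io.StringIO()
    tree.write(buf)
    newick = buf.getvalue().strip()
    if fmt == "newick":
        return newick + "\n"
    if fmt == "nexus":
        taxa = sorted(tip.name for tip in tree.tips())
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={len(taxa)};",
            "    TAXLABELS " + " ".join(f"'{t}'" for t in taxa) + ";",
            "END;",
            "BEGIN TREES;",
            f"    TREE glycotree = {newick}",
            "END;",
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown tree format {fmt!r}")


def cut_tree(tree: TreeNode, k: int) -> list[frozenset[str]]:
    """Cut a rooted dendrogram into ``k`` clusters by removing the k-1
    highest-joining internal nodes (standard dendrogram cut)."""
    leaves = [tip.name for tip in tree.tips()]
    if k <= 1:
        return [frozenset(leaves)]
    if k >= len(leaves):
        return [frozenset([name]) for name in sorted(leaves)]
    # node height above leaves: max distance to any descendant tip
    def height(node: TreeNode) -> float:
        if node.is_tip():
            return 0.0
        return max(height(c) + (c.length or 0.0) for c in node.children)

    internal = [n for n in tree.traverse() if not n.is_tip()]
    internal.sort(key=height, reverse=True)
    removed = set(id(n) for n in internal[: k - 1])

    clusters: list[frozenset[str]] = []

    def collect(node: TreeNode):
        if id(node) in removed:
            for child in node.children:
                collect(child)
        else:
            clusters.append(frozenset(tip.name for tip in node.tips()) or frozenset([node.name]))

    collect(tree)
    return clusters


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class ClusteringResult:
    taxon_pool: list[tuple[TaxonNode, int]]
    fragment_pool: list[FragmentKey]
    profiles: list[OccurrenceProfile]
    matrix: DissimilarityMatrix
    tree: TreeNode
    method: str


def run_clustering(
    collection: Collection,
    rank: str = "genus",
    scope: TaxonNode | None = None,
    thresholds: PoolThresholds = PoolThresholds(),
    pool_filters: FilterOptions = FilterOptions(),
    explicit_taxa: list[TaxonNode] | None = None,
    method: str = "upgma",
) -> ClusteringResult:
    """The full pipeline: pools → occurrence codes → normalized matrix →
    tree."""
    taxon_pool = build_taxon_pool(collection, rank, scope, thresholds, explicit_taxa)
    fragment_pool = build_fragment_pool(collection, thresholds, pool_filters)
    profiles = [
        occurrence_code(
            collection,
            taxon,
            fragment_pool,
            thresholds.presence_threshold,
            thresholds.fragment_arity,
            pool_filters,
            thresholds.structure_scope,
        )
        for taxon, _n in taxon_pool
    ]
    matrix = dissimilarity_matrix(profiles)
    tree = build_tree(matrix, method)
    return ClusteringResult(
        taxon_pool=taxon_pool,
        fragment_pool=fragment_pool,
        profiles=profiles,
        matrix=matrix,
        tree=tree,
        method=method,
    )
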