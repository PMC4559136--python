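"""Clustering pipeline: pools, occurrence codes, normalized Hamming
matrices, tree builders and exports."""

import io
import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from glycostat.clustering import (
    DissimilarityMatrix,
    EmptyPoolError,
    OccurrenceProfile,
    PoolThresholds,
    build_fragment_pool,
    build_taxon_pool,
    build_tree,
    cut_tree,
    dissimilarity_matrix,
    export_matrix,
    export_tree,
    hamming,
    hierarchical_tree,
    minimum_evolution_tree,
    nj_tree,
    occurrence_code,
    run_clustering,
)
from glycostat.fragments import FilterOptions
from glycostat.synthetic import SimulationSpec, generate_collection
from glycostat.treecmp import bipartitions

OPTS = FilterOptions()

SMALL_THRESHOLDS = PoolThresholds(
    population_abs_min=1,
    use_abs=True,
    use_rel=False,
    fragment_min_structures=2,
    fragment_min_instances=3,
    presence_threshold=2,
)


@pytest.fixture(scope="module")
def synthetic_collection():
    return generate_collection(
        SimulationSpec(n_groups=2, taxa_per_group=3, structures_per_taxon=10,
                       noise_rate=0.0, seed=11)
    )


def make_profile(name, bits, n):
    from glycostat.datamodel import TaxonNode

    return OccurrenceProfile(
        taxon=TaxonNode(name=name, rank="genus"), bits=tuple(bits), n_structures=n
    )


# ---------------------------------------------------------------------------
# pools and codes


class TestTaxonPool:
    def test_population_threshold(self, synthetic_collection):
        pool = build_taxon_pool(
            synthetic_collection, "genus",
            thresholds=PoolThresholds(population_abs_min=5, use_abs=True, use_rel=False),
        )
        assert len(pool) == 6
        assert all(n == 10 for _t, n in pool)
        with pytest.raises(EmptyPoolError):
            build_taxon_pool(
                synthetic_collection, "genus",
                thresholds=PoolThresholds(population_abs_min=99, use_abs=True, use_rel=False),
            )

    def test_threshold_matches_brute_force(self, small_collection):
        thresholds = PoolThresholds(population_abs_min=2, use_abs=True, use_rel=False)
        pool = build_taxon_pool(small_collection, "genus", thresholds=thresholds)
        expected = sorted(
            t.name
            for t in small_collection.taxonomy.at_rank("genus")
            if small_collection.population(t) >= 2
        )
        assert [t.name for t, _n in pool] == expected

    def test_relative_threshold(self, small_collection):
        # prokaryotic partition holds 5 structures; GenA1 has 3 of them
        thresholds = PoolThresholds(use_abs=False, use_rel=True, population_rel_min=0.5)
        pool = build_taxon_pool(small_collection, "genus", thresholds=thresholds)
        assert [t.name for t, _n in pool] == ["GenA1", "GenF1"]

    def test_explicit_list_bypasses_thresholds(self, small_collection):
        taxa = [small_collection.taxonomy.find("GenA1", "genus"),
                small_collection.taxonomy.find("GenF1", "genus")]
        pool = build_taxon_pool(
            small_collection, "genus",
            thresholds=PoolThresholds(population_abs_min=99, use_abs=True, use_rel=False),
            explicit_list=taxa,
        )
        assert [t.name for t, _n in pool] == ["GenA1", "GenF1"]


class TestFragmentPool:
    def test_thresholds(self, small_collection):
        # aDGlcp(1-3)bDGalp occurs in X1 and X2 (2 structures, 2 instances)
        pool = build_fragment_pool(
            small_collection,
            PoolThresholds(fragment_min_structures=2, fragment_min_instances=2,
                           presence_threshold=1),
            OPTS,
        )
        assert [str(k) for k in pool] == ["aDGlcp(1-3)bDGalp"]
        with pytest.raises(EmptyPoolError):
            build_fragment_pool(
                small_collection,
                PoolThresholds(fragment_min_structures=3, fragment_min_instances=3),
                OPTS,
            )

    def test_permissive_pool_is_every_fragment(self, small_collection):
        pool = build_fragment_pool(
            small_collection,
            PoolThresholds(fragment_min_structures=1, fragment_min_instances=1,
                           presence_threshold=1),
            OPTS,
        )
        seen = set()
        from glycostat.fragments import enumerate_dimers

        for r in small_collection.records:
            seen |= set(enumerate_dimers(r.graph, OPTS))
        assert set(pool) == seen
        assert pool == sorted(pool, key=lambda k: k.sort_key())


class TestOccurrenceCode:
    def test_presence_threshold(self, small_collection):
        genus = small_collection.taxonomy.find("GenA1", "genus")
        pool = build_fragment_pool(
            small_collection,
            PoolThresholds(fragment_min_structures=1, fragment_min_instances=1,
                           presence_threshold=1),
            OPTS,
        )
        code2 = occurrence_code(small_collection, genus, pool, presence_threshold=2)
        code1 = occurrence_code(small_collection, genus, pool, presence_threshold=1)
        by_key2 = dict(zip([str(k) for k in pool], code2.bits))
        by_key1 = dict(zip([str(k) for k in pool], code1.bits))
        # aDGlcp(1-3)bDGalp occurs twice in GenA1 (X1+X2) -> present at θ=2
        assert by_key2["aDGlcp(1-3)bDGalp"] == 1
        # bDGalp(1-4)aDGlcp occurs once (X2) -> present only at θ=1
        assert by_key2["bDGalp(1-4)aDGlcp"] == 0
        assert by_key1["bDGalp(1-4)aDGlcp"] == 1
        assert code2.n_structures == 3

    def test_unpopulated_taxon_all_zero(self, small_collection):
        genus = small_collection.taxonomy.find("GenF1", "genus")
        pool = build_fragment_pool(
            small_collection,
            PoolThresholds(fragment_min_structures=2, fragment_min_instances=2,
                           presence_threshold=1),
            OPTS,
        )
        code = occurrence_code(small_collection, genus, pool, presence_threshold=2)
        assert set(code.bits) == {0}


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 0, 1, 0), (0, 0, 1, 1), 2),
         ((1, 1, 0), (1, 1, 0), 0),
         ((1, 0, 1), (0, 1, 0), 3)],
    )
    def test_values(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming((1, 0), (1, 0, 1))


class TestDissimilarityMatrix:
    def test_normalization_arithmetic(self):
        """Hamming 4 over N_i+N_j = 40 gives raw 0.1; as the matrix maximum
        it rescales to exactly 100."""
        p1 = make_profile("A", [1, 1, 1, 1, 0, 0], 10)
        p2 = make_profile("B", [0, 0, 1, 1, 1, 1], 30)
        m = dissimilarity_matrix([p1, p2])
        assert m.scaled
        assert m.values[0, 1] == pytest.approx(100.0)
        assert m.values[1, 0] == pytest.approx(100.0)
        assert m.values[0, 0] == 0.0

    def test_scaling_preserves_ratios(self):
        p1 = make_profile("A", [1, 1, 0, 0], 10)
        p2 = make_profile("B", [0, 0, 1, 1], 10)  # H=4, raw 0.2
        p3 = make_profile("C", [1, 1, 1, 0], 10)  # H(A,C)=1, raw 0.05
        m = dissimilarity_matrix([p1, p2, p3])
        assert m.max_offdiag() == pytest.approx(100.0)
        i, j = m.labels.index("A"), m.labels.index("C")
        assert m.values[i, j] == pytest.approx(100.0 * 0.05 / 0.2)

    def test_identical_profiles_unscaled_with_warning(self):
        p1 = make_profile("A", [1, 0], 5)
        p2 = make_profile("B", [1, 0], 7)
        with pytest.warns(UserWarning, match="identical"):
            m = dissimilarity_matrix([p1, p2])
        assert not m.scaled
        assert m.values[0, 1] == 0.0


# ---------------------------------------------------------------------------
# hierarchical trees


def tip_distances(tree):
    dm = tree.tip_tip_distances()
    return dm


class TestHierarchical:
    def test_two_taxa_midpoint(self):
        m = DissimilarityMatrix(["A", "B"], np.array([[0.0, 100.0], [100.0, 0.0]]))
        tree = hierarchical_tree(m, "upgma")
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == {"A": 50.0, "B": 50.0}

    def test_three_taxon_hand_agglomeration(self):
        """D(AB)=2, D(AC)=D(BC)=8: A,B join at height 1, C joins at 4."""
        values = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        tree = hierarchical_tree(DissimilarityMatrix(["A", "B", "C"], values), "upgma")
        heights = {}
        for node in tree.traverse():
            if not node.is_tip():
                # height above leaves = distance to any descendant tip
                heights[frozenset(t.name for t in node.tips())] = _height(node)
        assert heights[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert heights[frozenset({"A", "B", "C"})] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_upgma_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        vals = rng.uniform(1.0, 2.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"T{i}" for i in range(n)]
        tree = hierarchical_tree(DissimilarityMatrix(labels, vals), "upgma")
        depths = [_root_to_tip(tree, tip) for tip in tree.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_upgma_recovers_ultrametric_input(self):
        """Cophenetic distances of the UPGMA tree reproduce an ultrametric
        input matrix exactly."""
        rng = np.random.default_rng(42)
        tree, labels, dm = _random_ultrametric(rng, n=7)
        out = hierarchical_tree(DissimilarityMatrix(labels, dm), "upgma")
        got = out.tip_tip_distances(endpoints=labels)
        index = {l: i for i, l in enumerate(labels)}
        for a, b in itertools.combinations(labels, 2):
            assert got[a, b] == pytest.approx(dm[index[a], index[b]], abs=1e-9)

    @pytest.mark.parametrize("method, scipy_method", [
        ("upgma", "average"), ("complete", "complete"), ("ward_d2", "ward"),
    ])
    @pytest.mark.parametrize("seed", [3, 4])
    def test_cophenetic_matches_scipy(self, method, scipy_method, seed):
        """Independent cross-check of the Lance–Williams agglomeration
        against scipy's linkage on tie-free random matrices."""
        rng = np.random.default_rng(seed)
        n = 9
        vals = rng.uniform(1.0, 2.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"T{i}" for i in range(n)]
        tree = hierarchical_tree(DissimilarityMatrix(labels, vals), method)
        got = tree.tip_tip_distances(endpoints=labels)
        Z = linkage(squareform(vals), method=scipy_method)
        expected = squareform(cophenet(Z))
        for i, j in itertools.combinations(range(n), 2):
            assert got[labels[i], labels[j]] == pytest.approx(expected[i, j], abs=1e-9)

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            hierarchical_tree(DissimilarityMatrix(["A"], np.zeros((1, 1))), "upgma")


def _height(node):
    if node.is_tip():
        return 0.0
    return max(_height(c) + (c.length or 0.0) for c in node.children)


def _root_to_tip(tree, tip):
    total = 0.0
    cur = tip
    while cur is not tree:
        total += cur.length or 0.0
        cur = cur.parent
    return total


def _random_ultrametric(rng, n):
    """Random ultrametric matrix built by agglomerating singletons at
    increasing heights (oracle construction, no library)."""
    labels = [f"U{i}" for i in range(n)]
    clusters = [{l} for l in labels]
    dm = np.zeros((n, n))
    index = {l: i for i, l in enumerate(labels)}
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.5, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                dm[index[a], index[b]] = dm[index[b], index[a]] = 2 * height
        clusters[i] |= clusters[j]
        del clusters[j]
    return None, labels, dm


# ---------------------------------------------------------------------------
# neighbor joining / BIONJ / minimum evolution


def random_additive(rng, labels):
    """Random unrooted binary tree with positive branch lengths and its
    leaf-pair path-length matrix (oracle construction)."""
    adj = {}
    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    internal = itertools.count()
    i0 = f"I{next(internal)}"
    for leaf in labels[:3]:
        connect(i0, leaf, float(rng.uniform(0.5, 2.0)))
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = f"I{next(internal)}"
        connect(a, mid, w / 2)
        connect(b, mid, w / 2)
        connect(mid, leaf, float(rng.uniform(0.5, 2.0)))
    n = len(labels)
    dm = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur].items():
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            dm[i, j] = dist[dst]
    splits = set()
    for a in adj:
        for b in adj[a]:
            if a < b and a.startswith("I") and b.startswith("I"):
                side = _side(adj, a, b, labels)
                splits.add(frozenset((side, frozenset(labels) - side)))
    return dm, splits


def _side(adj, start, blocked, labels):
    seen = {blocked, start}
    stack = [start]
    out = set()
    while stack:
        cur = stack.pop()
        if cur in labels:
            out.add(cur)
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(out)


def tree_splits(tree):
    return {frozenset(s) for s in bipartitions(tree)}


class TestNeighborJoining:
    def test_four_taxon_known_tree(self):
        # tree ((A:2,B:3):3,(C:4,D:4)) -> classic additive matrix
        values = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        for variant in ("nj", "bionj"):
            tree = nj_tree(DissimilarityMatrix(list("ABCD"), values), variant)
            got = tree.tip_tip_distances(endpoints=list("ABCD"))
            for i, a in enumerate("ABCD"):
                for j, b in enumerate("ABCD"):
                    if i < j:
                        assert got[a, b] == pytest.approx(values[i, j], abs=1e-9)
            assert tree_splits(tree) == {
                frozenset((frozenset("AB"), frozenset("CD")))
            }

    def test_three_taxa_closed_form(self):
        values = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], float)
        tree = nj_tree(DissimilarityMatrix(list("ABC"), values), "nj")
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["B"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["C"] == pytest.approx((5 + 4 - 3) / 2)

    @pytest.mark.parametrize("variant", ["nj", "bionj"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_additive_matrices_reproduced_exactly(self, variant, seed):
        rng = np.random.default_rng(seed)
        labels = [f"L{i}" for i in range(7)]
        dm, true_splits = random_additive(rng, labels)
        tree = nj_tree(DissimilarityMatrix(labels, dm), variant)
        got = tree.tip_tip_distances(endpoints=labels)
        for i, j in itertools.combinations(range(len(labels)), 2):
            assert got[labels[i], labels[j]] == pytest.approx(dm[i, j], abs=1e-9)
        assert tree_splits(tree) == true_splits

    def test_topology_matches_skbio_nj(self):
        """Independent implementation check on a non-additive matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        n = 6
        vals = rng.uniform(1.0, 2.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"T{i}" for i in range(n)]
        mine = nj_tree(DissimilarityMatrix(labels, vals), "nj")
        ref = skbio_nj(SkbioDM(vals, ids=labels))
        assert tree_splits(mine) == tree_splits(ref)

    def test_equidistant_matrix_deterministic(self):
        values = np.ones((4, 4)) - np.eye(4)
        m = DissimilarityMatrix(list("ABCD"), values)
        t1 = nj_tree(m, "nj")
        t2 = nj_tree(m, "nj")
        assert export_tree(t1, "newick") == export_tree(t2, "newick")

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DissimilarityMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)), "nj")


# exhaustive minimum-evolution oracle -----------------------------------------


def all_topologies(labels):
    """Every unrooted binary topology on the labels, as adjacency dicts."""
    counter = itertools.count()

    def expand(adj, remaining):
        if not remaining:
            yield adj
            return
        leaf = remaining[0]
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        for a, b in edges:
            new_adj = {k: set(v) for k, v in adj.items()}
            mid = f"X{next(counter)}"
            new_adj[a].discard(b)
            new_adj[b].discard(a)
            new_adj[mid] = {a, b, leaf}
            new_adj[a].add(mid)
            new_adj[b].add(mid)
            new_adj[leaf] = {mid}
            yield from expand(new_adj, remaining[1:])

    base = {"X_root": set(labels[:3])}
    for leaf in labels[:3]:
        base[leaf] = {"X_root"}
    yield from expand(base, labels[3:])


def oracle_topo_distances(adj, labels):
    out = {}
    for src in labels:
        dist = {src: 0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    stack.append(nxt)
        for dst in labels:
            if src < dst:
                out[(src, dst)] = dist[dst]
    return out


def oracle_balanced_length(adj, labels, dm, index):
    total = 0.0
    for (a, b), p in oracle_topo_distances(adj, labels).items():
        total += 2.0 ** (1 - p) * dm[index[a], index[b]]
    return total


def oracle_ols_length(adj, labels, dm, index):
    edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
    sides = [_side(adj, a, b, set(labels)) for a, b in edges]
    pairs = list(itertools.combinations(sorted(labels), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dm[index[a], index[b]] for a, b in pairs])
    for r, (a, b) in enumerate(pairs):
        for c, side in enumerate(sides):
            if (a in side) != (b in side):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(x.sum())


def oracle_splits(adj, labels):
    out = set()
    for a in adj:
        for b in adj[a]:
            if str(a) < str(b) and a not in labels and b not in labels:
                side = _side(adj, a, b, set(labels))
                if 1 < len(side) < len(labels) - 1:
                    out.add(frozenset((side, frozenset(labels) - side)))
    return out


class TestMinimumEvolution:
    @pytest.mark.parametrize("scheme", ["ols", "balanced"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_additive_recovers_generating_topology(self, scheme, seed):
        rng = np.random.default_rng(seed)
        labels = [f"L{i}" for i in range(6)]
        dm, true_splits = random_additive(rng, labels)
        tree = minimum_evolution_tree(DissimilarityMatrix(labels, dm), scheme)
        assert tree_splits(tree) == true_splits
        got = tree.tip_tip_distances(endpoints=labels)
        for i, j in itertools.combinations(range(len(labels)), 2):
            assert got[labels[i], labels[j]] == pytest.approx(dm[i, j], abs=1e-9)

    @pytest.mark.parametrize("scheme", ["ols", "balanced"])
    @pytest.mark.parametrize("n", [5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_search(self, scheme, n, seed):
        """NNI search reaches the global criterion minimum found by full
        topology enumeration on mildly perturbed additive matrices."""
        rng = np.random.default_rng(seed)
        labels = [f"L{i}" for i in range(n)]
        dm, _ = random_additive(rng, labels)
        noise = rng.uniform(-0.05, 0.05, size=dm.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        dm = dm + noise
        index = {l: i for i, l in enumerate(labels)}
        oracle = oracle_balanced_length if scheme == "balanced" else oracle_ols_length
        best = min(oracle(adj, labels, dm, index) for adj in all_topologies(labels))
        tree = minimum_evolution_tree(DissimilarityMatrix(labels, dm), scheme)
        # evaluate my tree with the oracle's criterion
        best_adj = None
        my_splits = tree_splits(tree)
        for adj in all_topologies(labels):
            if oracle_splits(adj, labels) == my_splits:
                best_adj = adj
                break
        assert best_adj is not None
        assert oracle(best_adj, labels, dm, index) == pytest.approx(best, abs=1e-9)

    def test_schemes_agree_on_additive(self):
        rng = np.random.default_rng(5)
        labels = [f"L{i}" for i in range(6)]
        dm, _ = random_additive(rng, labels)
        m = DissimilarityMatrix(labels, dm)
        t_ols = minimum_evolution_tree(m, "ols")
        t_bal = minimum_evolution_tree(m, "balanced")
        assert tree_splits(t_ols) == tree_splits(t_bal)


# ---------------------------------------------------------------------------
# exports, cutting, determinism


class TestExports:
    def test_phylip_two_by_two(self):
        m = DissimilarityMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        text = export_matrix(m, "phylip")
        lines = text.strip().split("\n")
        assert lines[0] == "2"
        assert len(lines) == 3
        assert lines[1].startswith("A".ljust(10))

    def test_phylip_truncation_collision(self):
        labels = ["Genus_long_name_one", "Genus_long_name_two"]
        m = DissimilarityMatrix(labels, np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="collide"):
            export_matrix(m, "phylip")

    def test_tsv_columns_in_pool_order(self):
        labels = ["B", "A", "C"]
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        text = export_matrix(DissimilarityMatrix(labels, vals), "tsv")
        header = text.split("\n")[0].split("\t")
        assert header == ["taxon", "B", "A", "C"]

    def test_r_format_lower_triangle(self):
        labels = ["A", "B", "C"]
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        text = export_matrix(DissimilarityMatrix(labels, vals), "r")
        lines = text.strip().split("\n")
        assert len(lines) == 3
        assert lines[1].split("\t")[0] == "B"

    def test_newick_round_trip(self):
        values = np.array([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float)
        tree = nj_tree(DissimilarityMatrix(list("ABCD"), values), "nj")
        text = export_tree(tree, "newick")
        again = TreeNode.read(io.StringIO(text))
        assert tree_splits(again) == tree_splits(tree)
        got = again.tip_tip_distances(endpoints=list("ABCD"))
        want = tree.tip_tip_distances(endpoints=list("ABCD"))
        for a, b in itertools.combinations("ABCD", 2):
            assert got[a, b] == pytest.approx(want[a, b])

    def test_nexus_parses_with_dendropy(self):
        import dendropy

        values = np.array([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float)
        tree = nj_tree(DissimilarityMatrix(list("ABCD"), values), "nj")
        text = export_tree(tree, "nexus")
        parsed = dendropy.Tree.get(data=text, schema="nexus")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set("ABCD")


class TestCutTree:
    def test_cut_recovers_planted_partition(self, synthetic_collection):
        result = run_clustering(
            synthetic_collection, rank="genus",
            thresholds=SMALL_THRESHOLDS, method="upgma",
        )
        clusters = cut_tree(result.tree, 2)
        expected = {
            frozenset({"Genus01x01", "Genus01x02", "Genus01x03"}),
            frozenset({"Genus02x01", "Genus02x02", "Genus02x03"}),
        }
        assert set(clusters) == expected

    def test_extreme_cuts(self, synthetic_collection):
        result = run_clustering(
            synthetic_collection, rank="genus",
            thresholds=SMALL_THRESHOLDS, method="upgma",
        )
        assert len(cut_tree(result.tree, 1)) == 1
        assert len(cut_tree(result.tree, 6)) == 6


class TestDeterminism:
    def test_pipeline_exports_are_reproducible(self, synthetic_collection):
        exports = []
        for _ in range(2):
            result = run_clustering(
                synthetic_collection, rank="genus",
                thresholds=SMALL_THRESHOLDS, method="upgma",
            )
            exports.append(
                (
                    export_matrix(result.matrix, "phylip"),
                    export_matrix(result.matrix, "tsv"),
                    export_matrix(result.matrix, "r"),
                    export_tree(result.tree, "newick"),
                    export_tree(result.tree, "nexus"),
                )
            )
        assert exports[0] == exports[1]
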