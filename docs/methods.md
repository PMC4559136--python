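# Methods

## Structures, residues and the notation subset

A *structure* is one oligomeric molecule or one polymer repeating unit.
Every entity attached through an ester, ether, amide or glycosidic bond is a
distinct residue — including monovalent substituents such as acetyl, methyl,
phosphate or sulfate groups. Residues are classified as monosaccharides,
monovalent residues, aglycons, alias placeholders (`Subst`, `Subst1`, …,
whose chemical identity is supplied in a trailing `// name = explanation`
block) or superclasses (`LIP`, `HEX`, … — generic categories used when the
exact identity is unknown). The classification vocabulary is configuration
(`notation.Vocabulary`), not notation: residue names carry no class marker,
so the monovalent/superclass/aglycon name lists ship as editable defaults
and unrecognized names fall back to "monosaccharide".

The supported grammar covers linear and branched oligomers, polymer
repeating units (`-n) … (m-`, joined into one wrap-around edge), alias
blocks, short-form donors with a single default attachment center
(`P-6)…`), and shortcut forms (`GlcNAc`, `Glc-1OMe`). A configured
monosaccharide token is `[a|b|?][D|L|?]stem[p|f|?]`; two relaxations make
database-style tokens parse: the ring letter may be embedded in the stem
(`aDGlcpN`), and a token starting with a bare configuration letter
(`DManp`) is read as having an *unknown* anomer, which matters for the
underdetermined-residue filter. `?` always means explicitly unknown and, by
strict comparison (always on), compares unequal to any determined value.
Repetition counts, multiple structures per line and side-chain polymers are
rejected with explicit errors rather than guessed at.

Serialization is canonical (branch order normalized, deepest non-monovalent
child kept on the main chain, a polymer's main chain forced through the
wrap-around cycle); `parse(serialize(g))` is isomorphic to `g`, which the
test suite checks against a networkx graph-isomorphism oracle.

## Fragments and filters

Monomeric fragments are residues; dimeric fragments are ordered
donor–linkage–acceptor pairs, one per graph edge, the polymer wrap-around
edge counted once per repeating unit. Fragments larger than dimers are out
of scope: the dimer already identifies the biosynthesized linkage. Filter
semantics worth noting:

- *Combine anomeric forms* folds `aDGlcp`/`bDGlcp` into `DGlcp`; an unknown
  anomer then no longer counts as underdetermined.
- *Sugars only* excludes every non-monosaccharide residue and is mutually
  exclusive with *include monovalent residues*; the N-acetyl of an amino
  sugar is an ordinary monovalent residue, so sugars-only drops
  `Ac(1-2)GlcN` while keeping `Gal(1-3)GlcN`.
- *Explain aliases* substitutes the declared explanation for the
  placeholder name, so equally named placeholders with different
  explanations separate; unexplained, they pool under the placeholder name.
- Branching degree counts a residue's substituents excluding its own
  acceptor linkage, with or without monovalent substituents.
- Position classes: the root is *reducing*, residues with no
  non-monovalent substituent *terminal*, the rest *inline*; members of a
  polymer's wrap-around cycle are *inline* by convention since a repeating
  unit has no reducing end. For a dimer the annotation is taken from the
  acceptor residue, which carries the reducing-end semantics of the pair.
- Position/branching differentiation is implemented and testable even
  though it is an optional, rarely used view.

## Abundance, uniqueness, coverage

Abundance tables count fragment occurrences over the distinct structures
assigned to the selected same-rank taxa (a structure assigned to several
selected taxa counts once). `share_of_taxa` uses structure-level presence:
a taxon "contains" a fragment when any of its structures does. Percentages
are reported to two decimals, half-up. Uniqueness within a scope (phylum /
kingdom / all biota) is organism-aware: a structure assigned to organisms
both inside and outside the taxon contributes an *outside* occurrence, so
its fragments are not unique to the taxon. "All biota" necessarily means
all records in the loaded collection — only the domains actually populated
there — and the CLI says so. Known analytical artifacts (e.g.
alditol-terminated dimers arising from reductive sample workup) are not
auto-detected; callers pass an explicit exclusion list.

Coverage tables distribute each selected taxon over its immediate subtaxa
(deeper descendants roll up), count distinct structures, publications,
organisms and summed NMR-spectrum counts per row, and close with a
cumulative row of distinct entities so structures or papers shared between
subtaxa are not double-counted. A record matches a year filter when any of
its publications falls in the range.

## Clustering pipeline

Parameters, defaults and meaning:

| parameter | default | meaning |
|---|---|---|
| `population_abs_min` | 20 structures | minimum structures assigned to a taxon (or subtaxa) |
| `population_rel_min` | 0.012 | minimum population as a fraction of the taxon's database partition |
| `fragment_min_structures` (A_s) | 100 | minimum structures containing a fragment, collection-wide |
| `fragment_min_instances` (A_i) | 120 | minimum total instances; must be ≥ A_s since one structure can hold several copies |
| `presence_threshold` (θ) | 2 | occurrences within a taxon needed to set its profile bit |
| `fragment_arity` | 2 | dimers (linkage repertoire); 1 profiles composition only |
| `structure_scope` | any | any / only_polymers / only_oligomers / optimized |

The *optimized* scope takes polymers from bacteria, fungi and archaea and
oligomers from everything else; protista and algae fall in "everything
else". The structure scope is applied consistently to fragment counting and
to the per-taxon structure counts N_t used in normalization. The relative
population threshold divides by the size of the taxon's *database
partition* — a configurable grouping of domains that stands in for the
bacterial vs plant–fungal database split (default: bacteria/archaea/protista
vs plants/algae/fungi).

Occurrence codes are phylogenetic profiles in the sense of Pellegrini et
al.: bit k set iff pool fragment k occurs ≥ θ times in the taxon's
structures. The raw dissimilarity is Hamming(b_i, b_j) / (N_i + N_j); the
division suppresses study-depth bias (heavily studied taxa accumulate rare
fragments and would otherwise sit far from everything). The full matrix is
then rescaled to max 100; if all profiles coincide the matrix is returned
unscaled with a warning rather than dividing by zero.

## Tree construction

All methods run on the normalized dissimilarity matrix and are
deterministic: among equally good candidate pairs the lexicographically
smallest pair (by each cluster's smallest leaf label) merges first.

- **UPGMA / complete linkage**: Lance–Williams agglomeration; node height
  is half the merge distance, so UPGMA trees are ultrametric and two taxa
  at distance 100 join with 50-long leaf branches.
- **Ward's D2**: the Ward criterion applied to squared dissimilarities,
  merge heights reported on the original scale (square roots) — matching
  the `ward.D2` convention of R's `hclust` and verified against scipy's
  `ward` linkage.
- **NJ / BIONJ**: Studier–Keppler Q selection; BIONJ differs only in the
  matrix-reduction step, choosing the convex combination minimizing the
  variance of the reduced matrix (λ clamped to [0,1]). Both reproduce
  additive matrices exactly (tested to 1e-9) and may produce negative
  branch lengths, which are kept. Output is unrooted (a trifurcating root
  node).
- **Minimum evolution**: NNI hill climbing from a BIONJ start, first
  improvement, deterministic edge order. The balanced criterion is
  evaluated through Pauplin's closed form Σ 2^(1−p_ij) d_ij (p_ij =
  topological leaf distance); the OLS criterion sums least-squares branch
  lengths. Final branch lengths are OLS estimates under either scheme. The
  search is validated against exhaustive topology enumeration for n ≤ 6;
  NNI hill climbing is a heuristic and may in principle stop in a local
  optimum on larger, strongly non-additive matrices.
- Other linkage schemes and minimum-variance-reduction are deliberately
  not offered.

Exports: Phylip square matrix (labels padded to 10 characters; truncation
collisions are an error), TSV, R `dist`-style lower triangle; Newick and a
minimal Nexus TREES block. Dendrogram graphics are out of scope.

`cut_tree` cuts a rooted dendrogram into k clusters by removing the k−1
highest-joining internal nodes.

## Tree comparison

Both trees are read as unrooted; each internal edge contributes a
bipartition of the common leaf set. A pair of bipartitions is scored by the
better of the two side alignments of the mean Jaccard index, branch pairs
are matched by an optimal one-to-one assignment (Hungarian algorithm, not
greedy — optimality is cheap at these sizes), and the score is the mean
over max(#edges₁, #edges₂), in percent, so unmatched branches count zero.
The per-branch formula is this package's declared variant of published
branch-scoring schemes, validated against an exhaustive-assignment oracle;
it is 100 exactly when the bipartition sets coincide. Two star trees have
nothing to map and score a vacuous 100 with a warning.

## Synthetic collections

The generator plants `n_groups` phyla × `taxa_per_group` genera (one
species per genus) × `structures_per_taxon` linear oligomer structures.
Chain lengths are Poisson around `mean_structure_length` (default 6,
truncated at 2); each linkage is drawn from the group's dimer pool with
probability 1 − `noise_rate` (default 0.05) and from a group-unspecific
pool otherwise. Default pools are disjoint by construction: group g links
every ordered residue pair of a six-residue pyranose alphabet through
acceptor position 3+g, noise through position 2.

Defaults were chosen so that presence calling at θ = 2 is statistically
stable: a group pool holds 36 dimer types, a structure carries ~5 linkages,
and 15 structures per taxon (the default) put the expected per-type count
at ~2.1 — enough for within-group profiles to overlap reliably, which is
what makes the planted partition exactly recoverable by every hierarchical
method across seeds. With 10 structures per taxon the expected count drops
to ~1.4 and recovery becomes unstable.

What the generator does *not* emulate: branched or polymeric structures
(branches and repeating units are exercised by hand-written fixtures),
realistic residue frequency spectra, multi-organism structures, shared
publications, or correlated noise. Passing the planted-recovery tests
therefore demonstrates that the pipeline's bookkeeping, normalization and
tree construction are correct — not that real collections cluster cleanly.

## Numerical and degenerate-input choices

- Percentages: two decimals, half-up. Matrix exports: six decimals.
- UPGMA ultrametricity and NJ additivity are asserted to 1e-9.
- NNI accepts an improvement only beyond 1e-12, preventing tie cycling.
- Empty taxon or fragment pools raise a dedicated error (CLI exit code 3)
  advising lower thresholds; an all-identical profile set yields an
  unscaled zero matrix with a warning.
- `A_i = A_s` is accepted with a warning (the instance threshold is
  normally strictly higher).
- Every CLI run writes `parameters.txt` with all effective settings so the
  job can be reproduced bit-identically; the generator uses a single seeded
  RNG with a fixed generation order.

## Known limitations

- The notation grammar is the subset above; exotic database forms (e.g.
  phosphate-bridge shorthands like `Aep(1-P`) are rejected as unparseable
  rather than guessed.
- Tree search for minimum evolution is NNI-only (no SPR), adequate for the
  pool sizes this tool produces.
- "All biota" uniqueness is relative to the loaded collection, never to
  biology.
- No live taxonomy service, no NMR spectra beyond per-record counts, no
  dendrogram rendering.
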