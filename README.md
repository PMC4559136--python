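# glycostat

Statistical analysis of taxonomy-annotated glycan structure collections:
fragment abundance, database-coverage statistics, and glycome-based
clustering of taxa into phenetic trees.

The package is aimed at glycoscientists and microbiologists who want to ask,
over a collection of published carbohydrate structures annotated with source
organisms: *which monomeric and dimeric building blocks does a taxon use,
which of them are unique to it, how well is a taxonomic group covered, and
which taxa look alike by their glycomes?* Because each dimeric fragment
(donor residue, linkage, acceptor residue) is the product of one
glycosyltransferase activity, clustering taxa by their dimer repertoires
approximates clustering by carbohydrate-active enzyme repertoires.

## What it does

- **Linear-notation parsing** (`glycostat.notation`): glycans written in
  CSDB-style linear notation (`Gal(1-3)GlcNAc(1-2)Man`,
  `-4)[Ac(1-2)]aDGlcpN(1-`, `Subst1(1-3)aDGlcp(1-1)LIP // Subst1 = …`) are
  parsed into rooted residue/linkage graphs. Shortcut forms expand
  (`GlcNAc` → `Ac(1-2)GlcN`), branches, polymer repeating units with
  wrap-around linkages, alias declarations and aglycons are supported.
- **Fragment enumeration** (`glycostat.fragments`): monomers and dimers
  under configurable filters — combine anomeric forms, include/exclude
  monovalent residues, aglycons, aliases and superclasses, drop
  underdetermined residues, sugars-only mode, position-class (terminal /
  inline / reducing) and branching-degree annotation.
- **Collections** (`glycostat.datamodel`): TSV dumps of
  (structure, organism, publication) rows with rank-labelled lineages,
  merged into records indexed by a taxonomy tree.
- **Abundance & coverage** (`glycostat.abundance`, `glycostat.coverage`):
  per-taxon fragment tables with absolute/relative abundance and
  share-of-taxa, fragments unique to a taxon within its phylum / kingdom /
  all biota, per-domain fragment frequencies, and per-subtaxon coverage
  tables (structures, publications, organisms, NMR spectra) with year and
  structure-type filters.
- **Taxon clustering** (`glycostat.clustering`): binary fragment-occurrence
  profiles per taxon ("occurrence codes"), pairwise Hamming distances
  normalized by the summed structure counts of each taxon pair and rescaled
  to a matrix maximum of 100, then trees by UPGMA, complete linkage,
  Ward's D2, neighbor joining, BIONJ, or OLS/balanced minimum evolution;
  exports to Phylip/TSV/R matrices and Newick/Nexus trees.
- **Tree comparison** (`glycostat.treecmp`): mean topological score between
  the internal branches of two trees under an optimal one-to-one mapping.
- **Synthetic collections** (`glycostat.synthetic`): seeded generator with
  planted group-specific dimer preferences, so the whole pipeline is
  testable end to end without any database access.

## Model

For a taxon pool `T` (taxa of one rank passing population thresholds) and an
ordered fragment pool `F` (fragments with ≥ `A_s` containing structures and
≥ `A_i` instances collection-wide), each taxon `t` gets an occurrence code

    b_t[k] = 1  iff  fragment F[k] occurs ≥ θ times in the structures of t

(θ = 2 by default, to suppress one-off occurrences and analytical
artifacts). Taxa are compared by

    D_raw(i, j) = Hamming(b_i, b_j) / (N_i + N_j)

where `N_t` is the number of structures assigned to `t` — the division
corrects for unevenly studied taxa — and the whole matrix is rescaled so
its maximum equals 100. Trees are built directly from this dissimilarity
matrix.

## Worked example

```
$ glycostat simulate --seed 1 --n-groups 2 --taxa-per-group 3 \
      --structures-per-taxon 15 --noise-rate 0.0 -o out/sim
wrote 90 records to out/sim/dump.tsv

$ glycostat clusterize --dump out/sim/dump.tsv --rank genus --pop-abs 1 \
      --frag-min-structures 2 --frag-min-instances 3 --method upgma -o out/clu
taxon pool: 6 taxa
fragment pool: 68 fragments
results written to out/clu
```

The simulated collection plants two phyla with disjoint dimer pools
(group 1 links residues `(1-3)`, group 2 `(1-4)`). The clustering run pools
6 genera and 68 dimer fragments, encodes each genus as a 68-bit occurrence
code, and writes `matrix.tsv`, `tree.nwk`, `taxa_coverage.tsv` and
`parameters.txt` into `out/clu`. The tree separates the two planted phyla
into two clades:

```
$ cat out/clu/tree.nwk
((Genus01x02:18.085106382978722,(Genus01x01:14.893617021276597,
Genus01x03:14.893617021276597):3.191489361702125):26.595744680851062,
(Genus02x03:20.21276595744681,(Genus02x01:14.893617021276597,
Genus02x02:14.893617021276597):5.319148936170212):24.468085106382976);
```

Because the two groups share no planted dimers, the largest normalized
distances sit between cross-group pairs and reach exactly 100 after
rescaling (see `out/clu/matrix.tsv`).

In Python the same run is:

```python
from glycostat import SimulationSpec, generate_collection, PoolThresholds, run_clustering

col = generate_collection(SimulationSpec(n_groups=2, taxa_per_group=3, noise_rate=0.0, seed=1))
res = run_clustering(
    col, rank="genus",
    thresholds=PoolThresholds(population_abs_min=1, use_abs=True, use_rel=False,
                              fragment_min_structures=2, fragment_min_instances=3),
)
print(res.matrix.max_offdiag())   # 100.0
```

## Dump format

Tab-separated, UTF-8, header required; one row per
(structure, organism, publication):

```
structure_id  notation  lineage  year  nmr_count  structure_type  [publication_id]
```

`lineage` is a semicolon-separated list of `rank=name` pairs with ranks in
{domain, kingdom, phylum, class, genus, species, strain}, e.g.
`domain=Bacteria;phylum=Proteobacteria;genus=Escherichia;species=E. coli`.
Rows sharing a `structure_id` merge into one record. `structure_type` is
one of `mono_oligomer`, `polymer`, `mono_homopolymer`, `cyclic`,
`biological_repeat`.
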