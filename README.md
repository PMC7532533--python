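# phylodrivers

Cancer **driver mutations** — recurrent somatic missense changes that push
cells toward tumorigenesis — are expected to be deleterious at the organism
level and purged by purifying selection. When a driver's alternate residue
nevertheless shows up in the orthologs of other species, the natural
hypothesis is that other residues in the same protein **compensate** for it.
`phylodrivers` implements, as a reusable and tested pipeline, the
computational chain for detecting driver states in deep gene-family
phylogenies and inferring within-gene compensatory mutation ensembles. It is
aimed at molecular-evolution and cancer-genomics researchers who have, per
gene: a deep protein alignment with a human reference row, a rooted gene
tree, taxon annotations, a tumor mutation table, and (optionally) a tabular
structure-search result.

## What it computes

**Driver ranking and selection.** Every distinct non-SNP mutation of a gene
is ranked `1 + #{distinct mutations seen in strictly more tumors}`; driver
candidates are missense mutations with rank < 20, observed less frequently
than at most 5 distinct missense mutations, at most 9 per gene.

**Homogeneity.** Column conservation as a linearly rescaled sum-of-pairs
score, `H = (S − S_rand)/(S_hom − S_rand)`, where `S_hom` scores a
homogeneous column and `S_rand` is the analytic expectation under the
background amino-acid frequencies; neighborhood homogeneity averages `H`
over a site and its three flanking sites on each side. Sites are classified
*deep* when fungal or plant orthologs align there, *shallow* otherwise.

**Leaf weights.** The total tree weight `T` (sum of all branch lengths) is
apportioned root-to-tip: each node receives `A·B/C`, with `A` its incoming
branch plus subtree length, `B` the parent's weight and `C` the sum of the
`A` values over the parent's children. Leaf weights sum to `T` and
down-weight densely sampled clades.

**Weighted ancestral reconstruction.** Per site, a bottom-up pass sums
descendant leaf weights per residue (normalized); a top-down pass multiplies
each interior node's vector elementwise with its parent's bottom-up vector
and renormalizes; a node is assigned the arg-max residue when its weight
exceeds 0.5, else *undefined*. Residue changes are placed at branch
midpoints.

**Compensatory ensembles.** For a driver state present in ≥ 4 leaves, the
search looks for a minimal set of other residue states such that every
driver-bearing leaf carries a member whose transition precedes that
lineage's driver emergence, every member arises independently at ≥ 2 nodes,
each such node has ≥ 2 driver-bearing descendants, and the binomial tail

    p = Σ_{k=N_pair}^{N_total} C(N_total, k) F^k (1−F)^{N_total−k}

is below 1%, where `N_total` counts transitions to the driver state,
`N_pair` those strictly descendant of a member transition, and `F` is the
fraction of (applicable) branch length occupied by the member states. Each
state joins at most one ensemble per gene.

**Association scores.** For residue pairs involving a driver state, expected
and observed co-occurrence counts are computed both over tumors
(`exp = f₁·f₂·N`) and over the leaf-weighted alignment, and scored with a
signed Poisson tail, `Score = −ln(1 − PCDF(exp, obs))` for excess and
`ln PCDF(exp, obs)` for depletion, evaluated in log space so that tails
down to ~1e−300 and beyond score correctly; `|Score| ≤ 1` pairs are
discarded, the rest fall into (+/+, +/−, −/+, −/−) quadrants.

**Structure coverage.** Hits from a 12-column tabular search are scored
Global = bitscore / protein length and Local = bitscore / footprint length;
per site the `Global² + Local²` maximizer is chosen, and per
driver/compensator pair the highest-Local covering hit, flagged as passing
at Local ≥ 1.9.

A synthetic-data module generates Yule trees, alignments evolved under a
uniform 20-state process with *planted* driver/compensator events (ground
truth logged), taxon tables, tumor tables with configurable marginal
frequencies and pairwise odds multipliers, and hit tables — so the whole
pipeline is testable without external databases.

## Worked example

```bash
phylodrivers simulate --seed 3 --outdir fam
phylodrivers ensembles --msa fam/family.fasta --tree fam/family.nwk \
    --taxa fam/taxa.tsv --reference-id L0001 --drivers 1V
```

prints

```
driver 1V	members=2I	N_total=4	N_pair=4	F=0.1052	p=0.000122
```

i.e. for the driver state V at reference position 1 the search found a
single-member ensemble — residue I at position 2 — whose transitions precede
all four independent emergences of the driver (`N_pair = N_total = 4`) while
occupying only 10.5% of the tree, so the chance of that precedence pattern
under independent placement is 1.2e−4, well below the 1% acceptance bound.
This is exactly the compensator the simulator planted (`fam/truth.yaml`).
`phylodrivers run-all` executes every stage and writes TSV reports plus a
run manifest; reruns are byte-identical.

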