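# Methods

This note documents the models and procedures implemented in
`phylodrivers`, the choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Inputs and coordinates

A gene family consists of a protein multiple sequence alignment (FASTA)
with one designated human reference row, a rooted Newick tree whose
leaves are alignment rows, a taxon table (sequence → species, major
clade ∈ {vertebrate, invertebrate, protist, fungus, plant, prokaryote},
taxonomy path), a tumor mutation table keyed to 1-based reference
protein positions, and optionally a 12-column tabular structure-search
result. Alignment columns are 0-based internally; offset rules
(gene-specific interval shifts reconciling tumor-table coordinates with
the reference entry) use closed intervals and may be open-ended.
Alignment rows absent from the tree — e.g. a reference row added purely
for coordinate bookkeeping — participate only in the position↔column
map, never in weighting or frequency statistics. Residues outside the
20 canonical amino acids (B, Z, X, U, ...) map to an explicit unknown
code treated as a gap by every counting operation: conservative, and it
avoids phantom character states.

## Driver ranking

Tumor counts are numbers of distinct tumor samples (duplicate
mutation/sample rows collapse; whether the source table means samples
or entries is not generally resolvable, and distinct samples is the
conservative reading). The rank of a mutation is 1 plus the number of
distinct non-SNP mutations of the gene with strictly greater count;
ties share a rank. Selection keeps missense candidates with rank
strictly below 20 (the threshold is config-exposed because "rank below
20" and "rank threshold of 20" can be read either way) and with at most
5 distinct more-frequent missense mutations, sorted by count and
truncated to 9 per gene with a deterministic tie-break (count desc,
rank asc, position asc, residue). Nonsense and SNP-flagged records are
never selected.

## Homogeneity

For a column with n non-gap residues over a row subset,
`H = (S − S_rand)/(S_hom − S_rand)` where S is the sum-of-pairs
BLOSUM62 score, `S_hom = n(n−1)/2 · M(c,c)` for the column's consensus
residue c (most frequent, ties to the higher self-score), and
`S_rand = n(n−1)/2 · f M fᵀ` for background frequencies f, computed
analytically rather than by simulation so results are deterministic.
The consensus convention makes every uniform column score exactly 1;
an alternative convention filling the homogeneous column with the
highest-self-score residue (tryptophan under BLOSUM62) is available via
`hom_residue="max_self"`. Background frequencies default to the
empirical residue frequencies of the row subset over the whole
alignment. Columns with fewer than two residues are *undefined*,
signalled as `None` and never conflated with 0. H is not clamped; it
can be negative for anti-conserved columns and can marginally exceed 1
in pathological mixtures. Note that single-residue replacement toward
the majority can *decrease* S under BLOSUM62 (a mismatching tryptophan
may score better against the rest of the column than the majority
residue does), so no such monotonicity is asserted. The tree-building
site filter keeps columns with gap fraction ≤ 50% and H ≥ 0.1 over all
rows. A site is *deep* when at least one fungal or plant row aligns a
residue there.

## Leaf weights

The total tree weight T is the sum of all branch lengths. The root is
assigned T; every other node receives A·B/C, where A is its incoming
branch length plus the total branch length of its subtree, B the
parent's weight and C the sum of the A values over the parent's
children. Reading A as "incoming branch plus subtree" (rather than
immediate child branches only) makes children's weights sum exactly to
the parent's, hence leaf weights sum to T — the conservation law the
tests assert to 1e-9 over 1000 random trees. When all of a parent's
child A values are zero (an all-zero-length clade) the weight is split
equally. Scaling all branch lengths by k scales all weights by k and
leaves every normalized downstream quantity unchanged.

## Weighted ancestral reconstruction

Per alignment column: (i) bottom-up, each node's character vector is
the per-residue sum of descendant leaf weights (gap leaves carry no
character), normalized to 1; (ii) top-down in a single pass, each
interior non-root node's vector becomes the renormalized elementwise
product of its own bottom-up vector with its *parent's bottom-up*
vector — the root, having no ancestor, keeps its bottom-up vector, and
a product with empty support (disjoint residue sets) falls back to the
node's own vector; (iii) a node is assigned the arg-max residue if its
weight exceeds 0.5, else the undefined state. The threshold comparison
carries a 1e-12 guard so that mathematically exact 0.5/0.5 ties (which
must be undefined) are not flipped by float summation order. A single
top-down pass is used; iterating the product to a fixed point is
neither required nor implemented.

Transitions: every node with a defined residue is compared to its
nearest defined strict ancestor (bridging undefined spans); a differing
residue yields one transition at the midpoint of the branch entering
the node. This unified rule handles the plain parent/child case and
attributes a change across an undefined region to the branch entering
the first defined descendant — the conservative choice for compensator
precedence queries, since it makes the undefined span available as
"prior" tree.

## Compensatory ensembles

A driver state is an (alignment column, residue) pair; it must be
carried by ≥ 4 tree leaves. Candidate members are states of other
columns with a transition on the same branch as, or any ancestral
branch of, at least one driver transition. An ensemble must satisfy:

1. **Coverage with precedence** — every driver-bearing leaf carries at
   least one member residue *and* that member has a transition on the
   same or an ancestral branch of the driver emergence that leaf
   descends from. Presence acquired through an unrelated transition
   elsewhere in the tree does not compensate that lineage.
2. **Improbable co-occurrence** — the binomial upper tail
   Σ C(N_total,k) F^k (1−F)^(N_total−k), k = N_pair..N_total, is
   below 1%. N_total counts transition events to the driver state
   across the whole ancestral record (events, not leaves); N_pair
   counts those strictly *descendant* of a member transition. Two
   transitions at the midpoint of one branch have no resolvable order,
   so same-branch members contribute to construction and coverage but
   not to N_pair. F is the fraction of applicable branch length
   occupied by the member states: branches whose both endpoints carry
   the state count fully, transition branches count half, branches
   undefined at the member's site are excluded from the denominator,
   and for multi-member ensembles occupied branches are unioned
   (per-branch occupancy is the max over members) over branches
   applicable to at least one member.
3. **Independent appearances** — each member must transition at ≥ 2
   distinct nodes. This is enforced per member (the distributive
   reading of the criterion); a pooled-over-members variant is
   available behind `per_member_nodes=False`.
4. **Support** — every member transition node must have ≥ 2
   driver-bearing descendant leaves.
5. **Exclusivity** — each state joins at most one ensemble per gene;
   drivers are resolved in order of increasing ensemble probability
   and later drivers re-search with consumed states excluded.

Search: for candidate pools of ≤ 15 states, all subsets are evaluated
in increasing size (stopping once larger subsets can no longer beat
the smallest-plus-one size rule); larger pools use greedy growth that
at each step adds the coverage-increasing candidate minimizing the
partial ensemble's probability. Accepted ensembles larger than the
smallest accepted size plus one are not reported. The binomial tail is
computed by direct summation with exact integer coefficients.

The per-member and strict-descent readings are not cosmetic: with
presence-based coverage and pooled appearance counting, 53% of
independently placed drivers in the null study acquired a "significant"
ensemble; with the implemented criteria the spurious rate is 0/200
while 99/100 planted configurations are still recovered.

## Association scores

Tumor side: for states s₁, s₂ of one gene, obs is the number of tumor
samples carrying both, exp = f₁·f₂·N over the gene's N distinct
samples. Alignment side: over sequences non-gap at both columns, with
leaf weights renormalized to sum to 1, obs = (Σ weights carrying both
residues)·n_nz and exp = (Σ carrying s₁)(Σ carrying s₂)·n_nz, n_nz the
number of nonzero-weighted qualifying sequences; both may be
non-integer. The score is −ln(1 − PCDF(exp, obs)) when obs > exp,
ln PCDF(exp, obs) when obs < exp, 0 at equality (neither piecewise
branch applies; such pairs are discarded by the |Score| ≤ 1 rule
anyway). The Poisson CDF is evaluated at ⌊obs⌋ — the conservative,
monotone choice for non-integer observed counts, with `round` and a
continuous regularized-incomplete-gamma interpolation behind a flag.
Upper tails use the survival function in log space and switch to direct
log-space series summation past double underflow, so scores of many
hundreds remain accurate (verified against a 50-digit exact-rational
oracle to 1e-6 over exp ∈ [0.1, 50], obs ∈ [0, 200]); obs = 0 uses the
identity ln P(X=0) = −exp exactly. The pair universe is every residue
pair with at least one selected driver state co-occurring in ≥ 1 tumor
or ≥ 1 alignment row; pairs at the same site are excluded (one sequence
cannot carry both).

## Clade statistics

A species *harbors* a state when its mode residue (most frequent over
the species' rows, ties toward the human reference residue, then the
lowest code; gap can be the mode) equals the state's residue; an
any-sequence rule is available behind a flag. Per-clade driver
frequency is leaf-weighted: weight carrying the state over weight
non-gap at the column, among the clade's rows. Bootstrap summaries
resample the per-driver frequency set with replacement B = 1000 times
and report the 25/50/75th percentiles of the resample means, seeded.
The target clade is the larger-scope of two rules, whichever names
fewer species: the largest taxonomy node where harboring species are a
strict majority, or the smallest node containing > 90% of harboring
species (the fallback when no majority node exists); ties between
nested nodes with identical species counts resolve toward the shallower
node for the "largest" rule and the deeper node for the "smallest",
and equal-size cross-rule ties go to the 90%-cover rule.

## Structure coverage

Global Score = bitscore / reference protein length ("total protein
length" is read as the query reference length, not the structure chain
length); Local Score = bitscore / query footprint length (closed,
1-based). Per site the covering hit maximizing Global² + Local² wins,
ties toward higher Local then lexicographic structure id; per
driver/compensator pair the covering hit with the highest Local Score
is reported and flagged as passing at Local ≥ 1.9. Multiple hits to the
same structure are treated independently — no footprint merging.

## Synthetic data

Trees are ultrametric pure-birth (Yule) trees simulated forward:
lineages split at total rate k·λ and a final exponential waiting time
is drawn after the last split so every pendant branch is positive
(off-the-shelf simulators that stop at the n-th split leave two
zero-length pendant branches, i.e. zero-weight leaves). Sequences
evolve under a uniform 20-state process — substitution probability
1 − e^(−r·b) per site per branch, the new residue uniform over the
other 19 — with all events logged as ground truth. Defaults: 48
leaves, birth rate 1, 40 columns, rate r = 0.1 per site per unit
branch length, i.e. ≈ 5 substitutions per site across a tree of total
length ≈ 47 — the conserved-but-informative regime of deep ortholog
alignments of essential genes. Leaves are assigned to the six major
clades in contiguous preorder blocks (vertebrate 30%, invertebrate
25%, protist 15%, fungus 12.5%, plant 12.5%, prokaryote 5% — a
eukaryote-heavy mix with fungi/plants present so deep sites exist),
one species per leaf.

Planted configurations place the compensator state on two disjoint
branches (a single transition event could never satisfy the
two-independent-appearances criterion) whose subtrees each occupy at
most 15% of total branch length, with two driver events on leaf
branches inside each; placements where, at any node above a planted
event, the derived state's leaf weight exceeds 0.55 of the subtree
weight are rejected, because such nodes would themselves be assigned
the derived state and the reconstruction would flatten the clustered
events onto one ancestral branch. Null configurations plant only the
driver (three disjoint events with ≥ 2 leaves each, so the driver is
eligible) and leave every other site to evolve freely — candidate
"compensators" are then genuinely independent of the driver placement.

Tumor tables draw per-tumor Bernoulli presence; pairs with an odds
multiplier ω are drawn from the Plackett 2×2 with the configured
marginals (each mutation in at most one pair). The association null
study uses two mutations at 0.5% marginal frequency in 1000 tumors —
the rare-co-occurrence regime of somatic mutation tables, where the
expected pair count is ≈ 0.025 per table.

**What passing these studies shows — and does not.** Recovery (99/100)
and calibration (0/200 spurious, ≥ 95% of independent pairs within
|Score| ≤ 1) demonstrate internal correctness of the chain on data
matching its assumptions: a correct rooted tree, one-residue-per-site
histories, no alignment error, uniform substitution, clean planted
precedence. Real alignments add misalignment, paralog contamination,
rate heterogeneity, indels and tree error, none of which the generator
emulates; synthetic success therefore bounds implementation error, not
biological error.

## Numerical and degenerate-input conventions

Binomial tails by direct summation (exact integer coefficients,
far-tail-first accumulation); Poisson tails in log space with a series
fallback past underflow; undefined quantities (`H` with < 2 residues,
frequencies over all-gap clades, scores at exp = 0, F over zero defined
length) are `None`/skipped, never silently 0; multifurcating roots are
accepted and logged; negative branch lengths are fatal; zero-length
pendant branches give zero-weight leaves which contribute to no
character vector and are logged. All randomness flows through seeded
`numpy` generators; reruns of any stage, and of the whole pipeline,
are byte-identical.
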