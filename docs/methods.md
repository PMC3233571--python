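# Methods

This note documents the models and procedures `hapnet` implements, the
parameters that matter, the design choices made where the literature leaves
the procedure open, and what the synthetic-data tests do and do not
establish.

## Haplotype collapsing

Input is a pre-aligned FASTA (alignment construction is out of scope) plus a
TSV of per-sample region and domestic/wild status. Region codes come from a
closed 15-code vocabulary (Tibet, SA, Yunnan, SEA, ISEA, Pacific, URYZ,
MDYZ, SC, Taiwan, MUYR, DRYR, NEC, Japan, Korea).

Every alignment column containing a gap in *any* sequence is excluded from
all downstream analysis, so indels never contribute to distances. By
default, columns containing a non-ACGT character are excluded the same way
(the "complete deletion" convention); alternatively the offending
*sequences* can be dropped (`ambiguous_action="drop_sequences"`). Retained
columns keep their original 0-based indices in `source_columns`.

Samples with identical retained-column sequences form one haplotype.
Haplotype ids are assigned deterministically — samples sorted
lexicographically by id, haplotypes numbered `Hap1, Hap2, ...` by first
appearance — so output never depends on file order. How length variants
were trimmed before gap exclusion in any particular published dataset is
unknowable from the data alone; we document the masking rule rather than
guess.

## Median-joining network

Distances are Hamming counts over retained columns; a per-column positive
weight vector is accepted but defaults to uniform (no transition/
transversion weighting). The network is built by the classical three-stage
loop:

1. **ε-relaxed minimum spanning network.** An edge `{u, v}` of weight `w`
   is included iff `u` and `v` are in different connected components of the
   graph of all pairs at distance `< w − ε`. At ε = 0 (the default, and the
   sparsest choice) this is exactly the union of all minimum spanning
   trees; the edge set grows monotonically with ε.
2. **Quasi-median insertion.** For each *feasible triple* — three nodes
   mutually adjacent in the current MSN — the column-wise majority
   consensus is formed; columns where all three states differ contribute
   each observed state (Cartesian product), giving the quasi-median set.
   Every quasi-median of a triple has the same *connection cost* (one per
   two-agree column, two per all-different column), and per pass only
   medians from the cheapest cost level that yields a new sequence are
   added — the greedy criterion of the classical algorithm, and the reason
   the construction does not flood homoplasy-rich data with useless
   medians. The loop repeats to a fixpoint, guarded by a hard cap of
   10 × (observed count) median vectors; exceeding it raises a
   `ConvergenceError` rather than returning a dubious network.
3. **Pruning.** Median vectors are removed greedily, in creation order and
   iterated to a fixpoint, whenever removal (with the MSN recomputed on the
   remaining nodes) neither lengthens any observed–observed shortest path
   nor increases the total minimum-spanning-tree length. The MST condition
   is essential: path preservation alone would delete genuine Steiner
   points such as the centre of the (AAT, ATA, TAA) triple, whose removal
   leaves all pairwise path lengths at 2 but lengthens the network from 3
   to 4. Finally, any observed-only MSN edge whose endpoints ended up
   further apart than its weight (possible when medians mediate a detour on
   homoplasy-rich data) is restored, so the final network always contains
   every minimum spanning tree of the observed haplotypes.

Determinism: nodes are processed in fixed order (observed in table order,
then medians in creation order, named `mv<k>`), triples lexicographically,
and all tie-breaks are by (weight, smaller id, larger id). Identical input
yields a byte-identical network.

On low-homoplasy haplotype data surviving medians are branch points
(degree ≥ 3). On adversarial inputs — mutually unrelated random sequences —
degree-2 medians can legitimately survive because each carries the unique
shortest route between some observed pair; such inputs can also exhaust
the median cap. Both behaviours are by design: the tool targets
population-level haplotype data, where sequences are a few steps apart.

## Cores, subgroups, haplogroup components

A *core* is an observed haplotype with ≥ `min_freq` individuals occurring
in ≥ `min_regions` regions (defaults 10 and 3, chosen for datasets of
roughly a thousand samples over the 15-region frame; desk-scale synthetic
analyses use `min_regions = 1` because with 1% migration a core rarely
leaves its home region). Detection provenance is recorded; cores can also
be supplied explicitly. Cores within one mutational step of each other
merge into a *core cluster*, so e.g. four cores forming a one-mutation
parallelogram behave as a single centre; distance to a cluster is the
minimum over its members.

Each observed haplotype is assigned to the subgroup of its nearest core
cluster (ties to the lexicographically smallest label; haplotypes
unreachable from every core get the sentinel `unassigned` rather than a
forced label, surfacing data problems instead of hiding them). The
*star score* of a subgroup is the fraction of its haplotypes within one
step of the core cluster (1.0 = perfect star; an isolated core scores 1.0
by the single-node convention).

`haplogroup_components(graph, cut)` removes every edge longer than `cut`
mutations (default 5) and labels connected components by decreasing size.
It is a deliberately simple stand-in for tree-based haplogrouping: deeply
divergent lineages separate cleanly, but it makes no claim to reproduce
clade boundaries that a phylogenetic analysis would draw.

## Diversity gradient and centre ranking

Relative to a chosen core set, each haplotype is `core` (network distance
0), `N1` (distance 1) or `N2` (distance ≥ 2; unreachable haplotypes are
counted in N2 and flagged). `Nu` counts region-private haplotypes —
by default private over *all* individuals regardless of status, because
that is the only reading under which the same haplotype can appear in a
region's domestic and wild Nu cells; `--unique-scope=region-status`
implements the stricter per-cell alternative. Per (region, status) cell,
Nc + N1 + N2 haplotype counts always equal the number of distinct
haplotypes present, and individual counts sum to the cell's sample count;
cells with no samples are flagged (`-` in the text output). Cores are
global: a region where no core occurs simply has Nc = 0, and derived
classes are always computed against the global core set.

The centre ranking makes the narrative "most derived/unique haplotypes"
argument explicit: score(region) = Σ over statuses of
w₁·N1 + w₂·N2 + w₃·Nu (haplotype counts, default weights 1, 1, 1),
descending, ties broken alphabetically. In the pipeline the Table-2-style
output is restricted to the primary subgroup, but the ranking is computed
over *all* subgroup-assigned haplotypes against the union of core
clusters: with several well-separated centres each centre seeds its own
subgroup, and ranking within one subgroup would structurally blind the
analysis to the others. In the haplogroup sharing table a haplotype counts
toward a status column when at least one member has that status, so shared
haplotypes appear in both columns; this overlapping convention matches how
published mixed haplogroup rows add up, but exact reproduction of any
particular published table is not claimed.

## Synthetic data

The generator emulates the structure the analysis assumes, not a full
demographic history: a uniform root sequence (431 columns by default); one
wild founder per region at Poisson(θ_wild = 5) mutations from the root;
wild samples as Poisson(1)-mutation satellites of their founder (10 per
region); each centre's domestic founder drawn from its own region's wild
pool; domestic samples as Poisson(λ = 1) derivatives of the founder (60
per centre) — star-like by construction; each domestic sample relocated
with probability 0.01 to a random other region; optionally a divergent
lineage 8+ mutations deep (15 samples). Defaults were fixed once: three
centres (Tibet, SEA, MDYZ) among 10 regions, sample sizes scaled to desk
size at roughly the real data's domestic:wild ratio, θ chosen so regional
wild pools sit several steps apart, λ = 1 giving a realistic spread of
0–3-step derivatives.

Mutation is finite-sites (each of k distinct columns flips to a uniform
different base), so back-mutation and homoplasy are possible as on a real
431 bp fragment. The model deliberately omits coalescent genealogy within
pools, selection, rate heterogeneity across sites, and sequencing error;
a green recovery test therefore establishes that the analysis recovers
planted structure under star-plus-noise data, not that it would resolve
arbitrarily entangled real histories. Everything is driven by a single
seeded `numpy` generator; identical parameters give byte-identical files.

The expected star score of a simulated expansion is a property of λ, not a
free dial: at λ = 0.5 the expected fraction of *distinct* haplotypes
within one step of the core is ≈ 0.78 (haplotypes with ≥ 2 mutations are
over-represented among distinct sequences), which the tests pin against a
truth-derived oracle rather than a round number.

## Numerical and degenerate-input choices

* All distances are exact integer Hamming counts (floats only with custom
  weights); comparisons use a 1e-9 tolerance.
* A single haplotype yields an edgeless network; an empty table or an
  alignment whose columns are all masked is an error, not an empty result.
* Duplicate sequences in a haplotype table, duplicate FASTA ids, unequal
  aligned lengths, unknown region codes, and unannotated samples are all
  rejected with messages naming the offender.
* Pipeline exit codes: 0 success, 2 input/configuration error,
  3 convergence-cap error.

## Known limitations

* The ε and character weights used by any particular published
  Network-program analysis are generally unreported; exact topological
  agreement with published figures is therefore not claimed, only the
  algorithmic contract above.
* The distance-cut haplogroup partition is not a phylogeny; posterior
  support and clade structure are out of scope.
* The centre ranking is descriptive — no significance test is attached to
  rank differences.
* Runtime is comfortable to a few hundred haplotypes; the pruning stage is
  quadratic in the number of median vectors.
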