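# Methods

This note documents the models, parameter choices and numerical decisions
behind `phyloprof`, and what the synthetic-data experiments do and do not
demonstrate.

## The species panel and profiles

A profile is a 0/1 vector over an ordered panel of proteomes. The panel
order is the five nested taxonomic ranges around the focal species —
genus, family, class, phylum, kingdom — innermost first, with the focal
species at position 0. Within a range the order carries no phylogenetic
meaning, so the input file order is preserved; this makes every run
reproducible without imposing an arbitrary canonical sort. The focal bit
of every observed profile is 1 by construction (a protein is trivially
present in its own proteome), and the focal species is never removed by a
quality filter for the same reason — excluding it would change the
profile coordinate system mid-analysis.

Proteome quality is a disjunction of two independent signals: a BUSCO
completeness cutoff *or* membership of the CPD class in an accepted set.
The shipped levels are `all` (no filter), `HQ1` (BUSCO C ≥ 95% or CPD
Standard / Close to Standard / Close to Standard (High Value) / Outlier
(High Value)) and `HQ2` (BUSCO C ≥ 97% or CPD Standard / Close to
Standard (High Value)). The phrasing of the CPD acceptance sets is
ambiguous in common usage (whether "(High Value)" qualifies only the
Outlier class); the sets above are the package default and both the
cutoffs and sets are plain `QualityLevel` values that callers can replace.

## Distances, clustering, consensus

The profile distance is the raw mismatch (Hamming) count, PM, kept as an
integer internally and converted to a fraction of the profile length only
where the CA/CD statistics require proportions — integer arithmetic is
exact and avoids accumulating rounding error through the pipeline.

Trees are built with canonical Saitou–Nei neighbour joining, reimplemented
rather than delegated to an external binary so the pipeline is fully
testable and deterministic: ties in the Q-criterion are broken by the
smallest (row, column) index pair of the current matrix. Because PM
distances are integers, Q values are exactly representable in double
precision and the tie-break is platform-stable. Branch lengths follow the
standard limb-length formulas and may be negative, as NJ permits. The
implementation is O(n³) time / O(n²) memory and handles thousands of
leaves in batch use; the test suite exercises n ≤ 500. A PHYLIP-style
square-matrix writer is provided for cross-checking against external NJ
implementations.

How to read clusters off an unrooted profile tree is genuinely open.  The
package enumerates **both sides of every internal bipartition** (sizes in
[min_size, n − min_size], deduplicated) — a rooting-free superset of any
clade-based reading — and relies on the downstream redundancy removal to
resolve overlaps. The consensus of a cluster is the positionwise majority
bit of its stacked member profiles; exact ties resolve to 0 (absence),
which is conservative against inflating apparent conservation and keeps
the consensus deterministic. The majority consensus provably minimizes
the total PM to the members, which the tests verify against exhaustive
search over all 2^L binary strings for small L.

Consensus agreement is defined on an agreement scale,

    CA = 1 − mean over members of PM(member, consensus)/L ∈ [0, 1],

so CA = 1 means a perfectly coherent cluster. (Defining it as the raw
average PM would invert the scale and be inconsistent with thresholds
like "CA ≥ 0.9" meaning *strict*.)

## The consensus-distance null

Ideal epoch profiles have 1s exactly on the species of one nested clade:
Sc (focal species only, or the whole genus via `sc_scope="genus"` — the
narrow default makes the most recent epoch maximally specific), WGD
(flagged descendants of the whole-genome duplication, which must nest
between Sc and the family for the containment chain Sc ⊆ WGD ⊆ Sa ⊆ Se ⊆
A ⊆ F to hold; violations are an error, not a warning), Sa (family), Se
(class), A (phylum), F (everything).

Under the null that a profile is i.i.d. Bernoulli(q) — with q the global
fraction of 1s in the observed matrix — the mismatch count to an ideal
with k ones is the independent sum

    PM ~ Binomial(k, 1 − q) + Binomial(L − k, q),

computed exactly by convolving the two binomial pmfs. The significance
threshold for an epoch is the largest count c with P(PM ≤ c) ≤ α/m, where
m is the Bonferroni correction for the number of candidate clusters
scored (the default; configurable). A Monte Carlo mode draws seeded
random profiles instead and refuses per-test levels below its 1/n_draws
resolution; the exact mode is the default and the two agree to within one
count at the quantile boundary (tested at 10⁶ draws). The null simulates
single random profiles, not consensi of random clusters, matching the
view that a cluster consensus under the null is itself an arbitrary
profile; q ∈ {0, 1} degenerates to a point mass and is flagged with a
warning. Clusters whose CD at the closest ideal is at or below the
epoch's threshold are *kept* as significant — the keep/discard direction
follows from the fact that meaningful clusters sit far below any
plausible null quantile.

## Redundancy removal and epoch assignment

Significant clusters are sorted on increasing minimum CD over the six
ideals and greedily scanned; a cluster is kept only if it shares no
member with a previously kept cluster, so the selection is always
pairwise disjoint and, because the sort key ends with the cluster id, a
total order independent of input order.

The tie-break at equal CD matters more than it looks. With both-sides
bipartition candidates, a large *mixture* of adjacent epochs can reach
CD = 0 exactly — the majority consensus of (say) all Sc + WGD + Sa genes
lands on one of the ideals — and a size-descending tie-break would let
such a mixture absorb the members of every tight cluster inside it, only
to be discarded later by the CA filter, stranding its members
unassigned. The default tie-break therefore prefers **coherence**: higher
size-adjusted CA first (CA shrunk by 0.1/√size), then larger size. The
shrinkage term acknowledges that a 2-member cluster with CA = 1 carries
far less evidence than a 50-member cluster with CA = 0.98; its scale
(0.1) is of the order of the CA spread between coherent clusters and
mixtures. The literal size-descending ordering is available as
`tie_break="size"` for comparison.

Each selected cluster is assigned to its closest ideal profile, ties
resolving to the more recent epoch (the more specific hypothesis).
Strictness thresholds (CA ≥ ca_min, CD ≤ cd_max) filter the assignment;
the default grids are ca_min ∈ {0.99, 0.98, 0.95, 0.9, 0.8} and cd_max ∈
{0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2}, 35 cells. Because the disjoint
selection is computed once and only the filter varies, per-epoch
populations are monotone over the grid by construction. Population
tables, trait summaries and QLA reporting are restricted to clusters of
≥ 10 members (the `min_report_size` default), the size at which a
cluster's consensus is meaningfully attested; threshold comparisons use a
1e−12 tolerance so grid constants like 0.9 compare exactly against the
rational CA/CD values.

Quality-level agreement (QLA) for a cluster is the fraction of its
members assigned — significantly, via their cluster at the other quality
level — to the same closest ideal profile. Members unassigned at the
other level count as disagreement, since agreement requires a significant
same-epoch assignment, not merely the absence of contradiction.

## Annotation statistics

Hypergeometric tails are computed by exact integer summation
(`math.comb` + `Fraction`), so enrichment and depletion p-values are
exact to the last bit rather than log-space approximations; the tests
cross-check every configuration with N ≤ 25 against scipy. The term
universe is every term with at least one background annotation, and the
Bonferroni factor is the number of such terms; no ontology-graph
(ancestor-closure) propagation is performed — the test is flat, and
pre-propagated input tables are used as-is.

Prion-like calls follow PLAAC conventions: per ortholog, the PRD score is
used when present, failing that the LLR score; a protein is prion-like
when the fraction of its orthologs (the focal protein included — it is a
member of its own ortholog set) passing the score cutoff reaches the
fraction cutoff. Score thresholds are inclusive (≥ 15.0) except the
"> 0.0" variant, which is strict as conventionally written. Disorder and
uniqueness consume precomputed inputs (a per-protein disorder fraction;
per-threshold self-search flags); running the upstream predictors is out
of scope.

## The synthetic-data generator

The generator emulates the structure of a real ortholog presence/absence
matrix around a focal species: each gene is born at one epoch ancestor
(noiseless profile = that epoch's ideal), may lose one contiguous block
of 2–10 species inside its 1-region with probability 0.2 (clade-specific
loss without needing a full dated phylogeny; the block never touches the
focal bit), and then suffers i.i.d. bit flips — false negatives at
ε_fn = 0.02 (raised to 0.10 for the 10% of species marked low-quality,
emulating fragmentary assemblies) and false positives at ε_fp = 0.002.
The defaults give a 100-species panel (5 genus / 10 family / 15 class /
30 phylum / 40 kingdom, a 10-species WGD clade) with 50 genes per epoch;
ideal clades are contiguous panel prefixes by construction. Trait flags
are sampled per gene from per-epoch probabilities chosen to plant
qualitative trends worth recovering (prion-like and highly disordered
proteins peak among the most recent genes; mildly disordered and
"unique" proteins peak at the family epoch), and annotation tables carry
one term per epoch at 50% penetrance against a 2% background. All
randomness flows from a single seed through named substreams (species,
birth, loss, noise, traits, annotations) so each stage is independently
reproducible.

What the generator does **not** emulate: correlated loss across related
genes (losses are independent per gene), rate variation along the genome,
detection bias as a smooth function of evolutionary distance, and
paralog/ohnolog structure. Passing the planted-recovery tests therefore
shows the pipeline correctly inverts its own generative assumptions at
realistic noise, not that it resolves every failure mode of real
ortholog detection — in particular, WGD-epoch clusters are expected to be
hard in real data for reasons (asymmetric ohnolog divergence) the
generator does not model.

## Problem sizes and measured behaviour

The validation suite runs at sizes chosen to make each property sharply
testable: 200 random additive matrices of 5–8 leaves for NJ topology
recovery (exactness on additive inputs); 10⁶ Monte Carlo draws at L = 800,
k ∈ {1, 200, 800}, q = 0.25 for the null (Kolmogorov distance to the
exact cdf below 3·10⁻³); 100 random clusters with L ≤ 12 for consensus
optimality against all 2^L strings; all hypergeometric configurations
with N ≤ 25 against scipy; and five replicates of the default simulation
(6 epochs × 50 genes × 100 species) through the full pipeline, where
assignment at strictness (CA ≥ 0.9, CD ≤ 0.1) over clusters of ≥ 10
members recovers the planted epoch for ≥ 95% of assigned genes
(measured ≈ 99%, coverage ≈ 60%) and the noiseless limit is an exact
fixed point (accuracy and coverage 1.0). Unassigned genes at these
settings are dominated by heavy-loss profiles that are genuinely
ambiguous — a WGD-epoch gene that lost 9 of its 10 clade species is
bitwise identical to an Sc-epoch gene — which is an information limit of
the data, not of the clustering.

## Known limitations

* Cluster extraction from the NJ tree is a reconstruction; nothing
  guarantees the tree has a bipartition isolating each true epoch cohort,
  and under heavy noise cohorts fragment into several disjoint clusters
  (all typically assigned to the same epoch, lowering coverage, not
  accuracy).
* The null models profiles, not consensi of clusters of a given size;
  consensus nulls would be stricter for large clusters.
* A single global q ignores per-clade detection-rate differences.
* Greedy selection is order-optimal only locally; an optimal disjoint
  cover is NP-hard and not attempted.
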