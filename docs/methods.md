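# Methods

## The character model

Markers are binary presence/absence states of retrotransposon insertions
scored across a fixed taxon set, with `?` for unscorable loci. Polarity is
fixed: 0 is ancestral, established upstream by outgroups, and is never
re-inferred. Two assumptions carry the whole method and are inherited from
the biology of LTR retrotransposons: no precise excision (1 never reverts
to 0 by deletion of exactly the element plus one target-site copy) and no
independent insertion at the same orthologous site. Under these
assumptions every conflict between a marker and the species tree must be
hemiplasy: the insertion arose once, persisted as a presence/absence
polymorphism through one or more speciation events, and the two alleles
fixed discordantly in the descendant lineages.

## Polymorphism parsimony

A mapping of one character onto a rooted tree assigns each branch a state
in {0, 1, P}: a unique origin branch carries 0→1 or 0→P; branches in state
P form a connected region containing the origin; each branch leaving the P
region fixes an allele (P→1 or P→0); above the origin everything is 0.
The engine returns the mapping minimizing the number of retained-P
branches with:

* the origin on the branch above the MRCA of all presence tips (the lowest
  feasible position — ties in origin placement are resolved downward,
  which asserts the minimum polymorphism duration);
* below the origin, a branch is P iff its subtended tips (after `?`
  resolution) contain both states; pure subtrees fix;
* `?` tips resolved by dynamic programming over subtree classes
  (pure-absent / pure-present / mixed) minimizing retained-P branches
  first and the number of `?`→1 resolutions second, so ties resolve to
  absence and output is deterministic.

On strictly bifurcating trees a P region of k branches has exactly k+1
exits, so the two step conventions — `fixations` (count of allele
fixations, P→1 plus P→0 plus a direct 0→1) and `retentions` (1 + retained
P branches, the convention of classic polymorphism-parsimony programs) —
coincide; on polytomies they differ and both are selectable. The test
suite proves the engine exactly equal to an independent brute-force
minimum over all origins × all connected P regions for every rooted shape
with ≤ 8 leaves and every binary tip pattern, and verifies the `?` DP
against exhaustive resolution enumeration.

**ILS duration** of a marker is (number of fixations) − 1: the minimum
number of speciation events the polymorphism must have persisted across,
equivalently (independently sorting lineages) − 1. Conflict-free markers
(one fixation) are reported as the class "≤1" — a pattern that fits the
tree is indistinguishable from one that persisted across a single event —
alongside classes 2 (weak), 3 (moderate) and ≥4 (strong conflict).
Characters constant after `?` resolution are uninformative and contribute
zero steps; CI and RI are computed over informative characters with the
per-character minimum of 1 step and maximum equal to the number of
observed presence tips (under the fixations convention a character can
exceed that bound, so RI is a soft descriptive statistic here, not an
invariant).

**Dollo scoring** (single origin, losses counted) is provided as an
explicit comparison baseline for the same matrices; it is not used in the
ILS quantities.

**Tree search** is stepwise addition (one start tree per jumbled taxon
input order, default 7 jumbles, seeded) followed by nearest-neighbor
-interchange hill climbing on total steps. NNI keeps the neighborhood at
desk scale; the search is deterministic given the seed and is validated by
recovery of generating topologies from conflict-free matrices and by never
scoring worse than the generating tree on noisy ones.

## Per-branch, partition and radiation summaries

Every informative marker is attributed to its parsimony origin branch.
Per-internode summaries count conflict-free vs ILS-affected markers by
duration class; with a dated tree (branch lengths in MY, matched by clade)
the insertion rate is (markers on branch)/(branch length). Branches with
no attributed markers report an *undefined* %ILS rather than 0%.
Chromosome partitions (Z vs autosome; microchromosomes under the
conventional 20-Mb cutoff) report the ILS-affected fraction per partition,
with unassignable markers in an explicit "unknown" bucket. Radiation
summaries pool named internode sets (supplied as clade lists, since
radiation membership is a narrative choice, not an inferrable one) and
report full integer duration spectra. Spearman correlations (e.g. branch
length vs %ILS) use average-rank ties with the large-sample t
approximation by default and a seeded permutation p-value behind a flag.

## Hemiplasy combinatorics

A polymorphism persisting across n speciation events on a pectinate
species tree leaves L = n+1 lineages, each fixing one allele: 2^L equally
weighted fixation vectors. A vector is species-tree congruent iff it could
also have arisen with persistence across at most one event, which on the
caterpillar is exactly: the presence set is a clade (a leading block
l1..lk of the ladder or a single lineage), the full set, or empty. That
gives 2L congruent vectors (L leading blocks including the full set, L−1
non-initial singletons, plus the all-absent vector) and a hemiplasy
probability of (2^L − 2L)/2^L. The classification is *not* the
prefix-or-suffix rule one might guess from the ladder drawing: a trailing
block like (0,0,1,1,1) is not a clade and needs three fixations. The
clade rule is the one that agrees with the parsimony engine (hemiplasious
⇔ ILS duration ≥ 2), verified exhaustively for L ≤ 10, and reproduces
every closed-form checkpoint (22 discordant patterns of 32 at n = 4; 50%
at n = 3; >90% at n = 7; ≥99% at n = 11). Closed forms are exact to
n = 63; enumeration is capped at n = 20.

The model weights all fixation vectors uniformly — no drift or selection
asymmetry between alleles — which is what the closed form requires and
what the printed checkpoints imply.

## Placement support and the symmetry test

For a focal clade F and a backbone tree, one candidate topology is built
per attachment branch within a user-named region (2k − 1 positions for a
rooted binary region with k leaves; the region stem included by default).
Attaching F on the branch above clade e creates the path clades F∪e and e;
a candidate's *diagnostic* clades are its path clades not shared by every
candidate. A marker supports a candidate iff it is conflict-free on that
candidate with its origin subtending a diagnostic clade, and it could not
— under any resolution of its `?` entries — pin a diagnostic clade of a
different candidate; ambiguous markers count for nothing, so support sets
are disjoint and their sum is bounded by the marker count. This
"diagnostic, not merely compatible" restriction is this package's
formalization: compatibility alone would credit markers irrelevant to the
placement question.

The hybridization check formalizes the verbal ILS expectation of
near-symmetric support: the non-best counts are tested against a uniform
multinomial — exactly (summing the probability of all outcomes no more
probable than the observed one, enumerated over count multisets) when the
non-best total is ≤ 200 and the composition count is ≤ 2×10^6, by
chi-square otherwise — and the flag is raised only if uniformity is
rejected at alpha (default 0.05) with some alternative above expectation.
The exact-vs-chi-square switchover and alpha are reported with the
result; the test is labelled in CLI output as the package's own
formalization, since the underlying argument in the literature is verbal.

## Target-site motifs

Position-wise nucleotide counts of the 5-bp target-site duplications, with
`N` dropped per position (not per motif); information content
IC_j = 2 − H_j bits with no small-sample correction (negligible at
thousands of motifs, and simpler); per-position chi-square against uniform
1/4 frequencies (df 3, minimum 20 counted letters per position) combined
across the five positions by Fisher's method. "No target-site preference"
is operationalized as failure to reject this uniform null.

## The coalescent generator

The synthetic-data generator emulates the *output* of a genome-screening
pipeline — a marker matrix with metadata — under exactly the assumptions
the estimator makes, so that any estimator failure is attributable to the
estimator. Model: one haploid lineage per species; within each species
branch (lengths in coalescent units, ultrametric trees required) k
lineages coalesce at rate k(k−1)/2, survivors pass rootward, coalescence
completes above the root; one insertion per locus placed uniformly over
gene-tree branch length (infinite sites), with optional per-species-branch
rate multipliers; presence tips are the insertion edge's descendants.
Matrices can never contain an all-present pattern (the root stem is not an
insertable edge). Missing data is independent per entry; ascertainment
(min scored taxa — the screening default of 10, capped at the taxon count
for small validation trees — no plesiomorphies, no autapomorphies, no
all-absent) is enforced by rejection sampling so the retained locus count
is exact, with an explicit failure after a bounded number of attempts.
Defaults (2,000 loci, 20% missing entries, all filters on) represent a
realistic screening design; the missing rate is a package choice, as
deposited marker tables report the filter thresholds but not the achieved
missingness. A single seeded generator drives every draw, so identical
configs are byte-identical. N_e enters only through the helper
`to_coalescent_units(MY, N_e, generation time)`.

Two truths are recorded per locus. `duration_pattern` is the minimal ILS
duration implied by the complete, unmasked pattern — the estimand of any
pattern-based method, and what `recover_parameters` is primarily scored
against. `duration_true` is the genealogical persistence: the number of
speciation events more recent than the insertion at which the splitting
population contained both carrier and non-carrier sampled lineages. The
gap between them is the ILS that fixes into clade-like patterns and is
invisible to presence/absence data in principle; at tau = 0.5 internodes
on a 5-taxon ladder roughly 30% of loci carry such hidden persistence,
falling to ~0.1% at tau = 4 (see `examples/simulate_ils_gradient.py`).

What the generator does **not** emulate: real screening artifacts
(alignment errors, paralogy, non-independent missingness along lineages),
diploid allele-frequency dynamics, selection, gene flow. Passing recovery
tests on these simulations therefore demonstrates correctness of the
mapping machinery under the model's own assumptions, not robustness of
the biology.

Validation anchors: the 3-taxon gene-tree discordance probability
(2/3)e^(−T) (matched within 3 Monte-Carlo standard errors at 10,000 loci
for T ∈ {0, 0.5, 1, 2}), strict decrease of the ILS-affected fraction in
internode length over tau ∈ {0.1, 0.5, 1, 2, 4} (2,000 loci each, fixed
seeds), and per-locus duration recovery (exact against the pattern-implied
truth on fully scored data; ≥ 90% with one unscored taxon allowed per
locus at tau = 0.5).

## Numerical and interface choices

* Problem sizes in the test suite — ≤ 8-leaf oracle exhaustion, 10,000
  3-taxon loci, 2,000-locus ladders — were chosen as the smallest sizes at
  which the checks are statistically meaningful.
* Trees must be rooted (polarity!); a basal multifurcation is rejected as
  unrooted unless explicitly allowed. Branch lengths, when units are
  declared, must be nonnegative; coalescent simulation additionally
  requires ultrametricity (tolerance 1e-6 relative).
* `?` is the only internal missing symbol; `N` and `-` in inputs are
  mapped to `?` with a logged warning. PHYLIP taxon names are padded or
  truncated to 10 characters only in the PHYLIP writer.
* Marker coordinates in metadata are 1-based inclusive, matching
  spreadsheet-style deposited tables. PHYLIP and NEXUS dialects carry no
  marker ids or metadata; round-trips preserve taxa and states, and ids
  only through the CSV dialect.
* Empty internodes, all-absent patterns, constant characters and
  zero-marker partitions all report explicit undefined/uninformative
  statuses rather than zeros.
* The reproduction harness (`retroils reproduce`) tries both step
  conventions against a deposited tree-length value and reports which
  matched, because published polymorphism-parsimony tree lengths do not
  state their internal step definition.

## Known limitations

* The heuristic search explores NNI only; for matrices with severe
  conflict it can stop in local optima (mitigated by jumbled restarts).
* Polytomy scoring works but duration classes on polytomies conflate
  simultaneous divergence with unresolved order; the hemiplasy module is
  pectinate-only by design.
* The exact multinomial symmetry test falls back to chi-square above its
  enumeration bound even when the non-best total is ≤ 200.
* The uniform-support null of the hybridization check is an idealization:
  under pure ILS, conflicting markers still favor alternatives
  topologically close to the best placement, so pooling candidates at very
  different tree distances (e.g. every branch of a large region) can
  reject uniformity without any hybridization. The test is meant for a
  handful of comparably placed alternatives around one contentious node,
  the setting its verbal ancestor describes.
* CI/RI follow the conventions stated above and are descriptive; they are
  not comparable across programs that count steps differently.
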