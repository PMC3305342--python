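# Methods

## Scope and data model

`prmnet` analyses directed domain→target interaction networks predicted
from position weight matrices (PWMs) across multiple species, and
quantifies how those networks change over evolutionary time. All
coordinates are 0-based half-open internally; exported tables are
1-based inclusive and flagged as such in a header comment. Branch
lengths and divergence times are in millions of years (My); all rates
are per My.

## PWM scoring

Raw per-position amino-acid counts are converted to strictly positive
"adjusted counts" with Henikoff position-based pseudocounts:

    m(p, aa) = (n(p, aa) + B_p · b_aa) / (N_p + B_p),   B_p = 5 · R_p

where `R_p` is the number of distinct residues observed at position
`p`, `N_p` the total count there, and `b_aa = 1/20` a uniform
background. Each column of the adjusted matrix sums to 1. A candidate
peptide `x` of motif length `N_c` scores additively and is normalized
by the matrix optimum `S_opt = Σ_p max_aa m(p, aa)`:

    score(x) = Σ_p m(p, x_p) / S_opt ∈ (0, 1],

so the consensus scores exactly 1. The additive-then-normalize form is
this package's design choice for the published pipeline it models,
whose exact normalization is not printed; it preserves the two named
ingredients (position-wise adjusted counts, optimal-score
normalization) and gives scores a fixed, comparable scale. Larger is
better throughout.

Scanning slides the motif over every window of a protein and annotates
each window with the arithmetic mean of the per-residue disorder and
surface-accessibility tracks (mean rather than min/max because it is
stable under window clipping and track rescaling). Non-standard
residues raise an error by default; a skip-window mode is available.

PWM information content is the summed per-column Shannon entropy
(base 2). PWM dissimilarity pads both matrices with uniform ("X")
columns, evaluates every relative offset with at least one overlapping
real column, averages per-position L2 distances over the union span
(padding included), and returns the minimum over offsets. The measure
is symmetric and zero for identical matrices; the triangle inequality
is *not* guaranteed (minimum-over-offsets can break it). Offsets with
no real overlap are excluded — otherwise two sharp one-column matrices
could look more similar through pure padding than aligned head-on.

Background significance of a best score uses a location-scale Student's
t fit (df = n−1, sample mean and SD) to the per-protein best-score
distribution, reporting the upper-tail probability.

## Network assembly

Sites first pass strict feature gates (accessibility > threshold,
disorder > threshold), then per specificity class the top-N surviving
sites by score become edges. Ties break by (score desc, accessibility
desc, target id, start), making assembly deterministic and input-order
independent. Filters apply before the top-N cap; note the consequence
that tightening a filter can admit *different* edges (freed slots are
backfilled), so filter monotonicity holds only when the cap is not
binding. Each PWM class belongs to one domain protein; a protein owning
several classes contributes one potential edge per class, and target
in-degree counts distinct (domain protein, class) partners.

Prediction evaluation subsamples the negative set to a configurable
ratio (default 5:1 negatives:positives, seeded), computes AUROC with
midrank tie handling, and reports MCC plus the confusion matrix at the
network's accept/reject decision.

## Orthology

Orthogroups arrive as membership tables plus reconstructed gene trees
(newick, leaves `species|protein`). For rate calculations the mapping
is constrained to one-to-one/many-to-one against the reference species:
for each reference protein and each other species, the member with the
smallest patristic distance (path length on the gene tree) is chosen,
ties broken lexicographically. A reference protein missing from its own
gene tree is an error; members missing from the tree are skipped with a
logged warning. "Global" comparisons instead use unconstrained
one-to-many ortholog sets. Domain-presence filtering consumes a
precomputed annotation table (domain detection itself is out of scope);
proteins absent from the table are kept, mirroring a removal list.

Family alignments (reference protein + constrained orthologs, one row
per species) transfer residue windows between species by column
interval: the source window ± flank (default 10 residues, clipped at
sequence ends) maps to an alignment column span, and each species
receives the ungapped subsequence and residue coordinates under that
span.

## Interaction change counting and rates

Two conservation criteria:

* **Global** (no positional information): a reference edge (d, c, t) is
  conserved iff some ortholog of t is a target of (some ortholog of d,
  class c) in the other network. Gains are other-network edges whose
  endpoints both have reference orthologs but no reference counterpart;
  restricting the gain universe to proteins with orthologs keeps the
  count consistent with the rate denominator ("all possible
  interactions amongst proteins with orthologs").
* **Local** (positional): conserved iff the other network holds an
  accepted same-class site on the constrained target ortholog whose
  start falls inside the alignment-mapped window of a reference site
  ± 10 residues. Window membership is start-based, which is stable
  under clipping at sequence ends. Gains are counted symmetrically by
  mapping the other species' site windows back to the reference row.
  Edges whose target lacks a family alignment are skipped and counted.

Protein change uses ortholog existence only: an edge changes iff either
endpoint has no ortholog in the compared species.

Rates normalize the change count:

    rate = intChanges / (orthDomainProteins · orthProteins · divergenceTime)

with `orthDomainProteins` the reference domain proteins having a
(domain-positive) ortholog in the partner species and `orthProteins`
all reference proteins with an ortholog. The error bound assumes the
partner network harbors as many wrong interactions as the reference, so
the maximum spurious change count is twice the reference's false calls,
normalized like the rate.

Randomization nulls use degree-preserving double-edge swaps on the
bipartite (domain, class)→target multigraph (default 100·|E| attempts,
swaps creating duplicate edges rejected; randomized networks carry no
site annotations, so null testing uses the global criterion). The
one-sided "slower than random" test reports the add-one empirical
p-value `(1 + #{null ≤ observed}) / (1 + n_reps)`, which never returns
zero at finite replicate counts. Note that a network with a single
specificity class is *frozen* under degree-preserving swaps (the
bipartite degree sequence determines it completely); meaningful nulls
need ≥2 classes.

## Network phylogenies

Each orthology-mapped interaction identity (reference domain protein,
class, reference target) is a binary character; species distance is the
normalized Hamming distance between character rows; trees come from
neighbor joining (scikit-bio's Saitou–Nei implementation, standard
branch-length formulas), which recovers additive matrices exactly.
Species lacking an orthologous pair are coded 0 (absence), consistent
with presence/absence character coding. Topological agreement is the
unrooted Robinson–Foulds distance.

## Clusters and conservation metrics

A binding-site cluster is a set of sites on one target in which every
pair overlaps by more than 50% of the *shorter* site's length (for the
equal-length sites of one domain family the two readings coincide; the
shorter-site reading keeps the predicate symmetric for mixed lengths).
Clustering is a greedy single pass over sites sorted by (start asc,
length desc, class id): a site joins the current cluster iff it
overlaps every member, else it seeds a new cluster; the result
partitions the input.

Gap-weighted column conservation scores each alignment column as the
normalized inverse entropy of its non-gap residues, `1 − H/log2(20)`,
multiplied by `max(0, 1 − gaps/non-gaps)`; columns with at least as
many gaps as residues score 0. This emulates an unweighted-frequency
conservation score with gap down-weighting; it is an emulation of that
scheme, not a re-implementation of any external tool.

The divergence-weighted binding-site conservation metric proceeds in
three steps for a reference site: (1) the best window score per
ortholog (site ± 10 residues through the family alignment); (2)
gene-tree divergence distances to the reference protein; (3) the
weighted mean of score differences `δ_o = score_o − score_ref` with
weights `1/distance_o`. Differences below `−τ`, with `τ` twice the
worst accepted score in the reference network, are floored at `−τ`
rather than excluded: flooring saturates "site absent" signals without
silently dropping species (the published description of this threshold
is ambiguous; flooring is this package's reading). An ortholog whose
mapped window is shorter than the motif contributes the floor value.
Zero distances are floored at 1e-6 before taking reciprocals. The
metric is 0 iff all included differences are 0, is invariant to
rescaling all distances by a constant, and is undefined (flagged, not
zero) when no ortholog can be evaluated.

## Forward simulator

The simulator is an explicit modeling choice — a generator of
ground-truthed test beds, not a reconstruction of any inferred
evolutionary process. A dated, rooted, binary species tree is traversed
in preorder with a single seeded RNG stream, so a configuration is
fully reproducible (identical seeds give byte-identical fixture sets).

* **Proteins.** The first `n_pwm_classes` proteins are domain proteins
  (one PWM class each, exempt from gene events); the rest are targets.
  Every target carries one reserved, disordered, surface-accessible
  "slot" per class at a fixed position, spaced so slots never overlap;
  tracks are 0.9/5.0 (disorder/accessibility) in a slot ± 3 residues
  and 0.05/1.0 elsewhere. Protein length is uniform at
  `protein_length`, which keeps family alignments exact when indels are
  off.
* **PWMs** are sharp random matrices (18 observations of a random
  consensus plus two single alternative observations per position), so
  consensus sites score 1.0 and each anchor substitution costs roughly
  `1/N_c` of the normalized score.
* **Direct mode.** The potential edge set is classes × targets.
  Ancestral edges are sampled at `ancestral_density`. Along each branch
  every potential edge follows a two-state Poisson process (loss hazard
  per existing edge, gain hazard per absent edge), simulated by
  exponential waiting times; every toggle is logged. Target genes can
  be lost or duplicated (per-gene hazards); a duplicate copies its
  parent's branch-start edge states and then experiences the edge
  process over the whole branch (a branch-granularity approximation:
  gene and edge processes do not interleave in time within one
  branch). Replaying the event log in recorded order — gene events
  first, then edge toggles, per branch — reproduces every leaf network
  exactly, and the test suite asserts this.
* **Mechanistic mode.** No edge process runs; planted consensus sites
  simply evolve. Sequences accumulate Poisson(μ·t·L) substitutions per
  branch (uniform replacement over the 19 other residues); networks are
  *not* emitted and must re-emerge by scanning the evolved proteomes.
  With `indegree_coupling` on, targets are planted with 1..k_max class
  sites and substitutions inside any site slot are accepted with
  probability 1/k — a crude purifying-selection proxy that couples site
  retention to in-degree. An optional deletion-only indel process
  (geometric lengths, mean ≈ 2.5 residues) produces genuinely gapped
  family alignments; insertions are not modeled.
* **Gene trees** are grown alongside the species-tree traversal
  (bifurcating at duplications, truncating at losses, splitting at
  speciations), pruned of extinct lineages, and emitted per orthogroup
  with branch lengths in My, so patristic distances are directly
  comparable to divergence times.

The closed-form companion `expected_observed_changes` gives the
expected number of *observed* edge differences between an ancestor and
a descendant time t apart under the two-state process — loss followed
by regain looks conserved, which is exactly the saturation phenomenon:
the expectation is linear in t for `t·λ ≪ 1` and plateaus at the
stationary mixture. For the symmetric case (equal gain and loss
hazards) the same formula applies to a leaf–leaf comparison with t the
path length, because the two-state flip probability composes along the
path independently of the state at the common ancestor.

## What the simulator does and does not show

Passing tests on simulated data demonstrate internal consistency of the
pipeline: scanning recovers exactly the planted sites, change counting
matches the generating process's closed form, profile trees recover the
generating topology, and the conservation metric responds to planted
site decay. Real proteomes differ in ways the generator deliberately
ignores: amino-acid composition and substitution biases, indel-rich
disordered regions, motif-like background matches, overlapping
multi-class sites sharing a PxxP-style core, gene conversion, and
incomplete or erroneous orthology. Quantities that depend on real
specificity data (published AUROC/MCC values, absolute interaction
counts, real correlation coefficients) are therefore out of reach by
design; the package reproduces the *arithmetic* of the published rate
table exactly and the *qualitative phenomena* (saturation within ~200
My at the simulated hazards, reference-species bias, slower-than-random
rewiring, in-degree/conservation correlation) at desk scale.

## Problem sizes and defaults

Simulation scenarios in the tests and the acceptance script use 1040
potential edges (8 classes × 130 targets) for direct-mode rate
properties, 5 (A,B,C,D,E) or 8 (A..H) species dated up to 300 My deep,
edge hazards of 0.002–0.005 per edge per My so that `t·λ` spans the
linear (0.02) through saturated (3) regimes, substitution rates of
5e-4–2e-3 per residue per My in mechanistic mode, 200 randomization
replicates for null tests, and 500 random instances for the cluster
predicate check. These sizes were chosen so every property has clear
statistical resolution (3-SD binomial bands, p < 0.01 correlations)
while the whole suite stays interactive.

## Known limitations

* Direct-mode sequences are static (ancestral); only coordinates, not
  sequence content, are meaningful for edges gained after the root.
* Gene duplication applies to targets only; domain proteins are fixed
  across species, so `orthDomainProteins` variation must come from the
  domain-annotation filter rather than the simulator.
* The local (windowed) gain count maps windows back through the same
  family alignment; families are keyed by reference protein, so gains
  on other-species proteins without a mapped reference target are not
  counted in local mode (they are in global mode).
* The null model randomizes network topology but keeps site annotations
  out of the replicates; positional null tests are not supported.
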