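# Methods

This note records the models implemented in `foldspace`, the defaults
and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions.

## Age model

A unit (superfamily or fold) is described by a binary occurrence
profile over the leaves of a rooted species tree.  A *scenario* is an
assignment of presence/absence to every node; its events are gains
(absent parent, present child) and losses (present parent, absent
child).  The lineage above the root is taken to be absent, so a
present root contributes one gain at the root.  This prior makes
"age 1 = gained at the root" well defined and gives the all-present
profile the finite cost `g`.

* **Maximum parsimony** minimizes `S = L + g·G` over scenarios, where
  `L` and `G` count losses and gains and `g` is the gain weight.  The
  default `g = 1` penalizes both event types equally; sweeps default to
  {0.1, 0.2, 0.5, 1, 2, 5, 10} (up to ten-fold asymmetry either way).
  The optimum is found by a Sankoff-style dynamic program over states
  {absent, present} with transition costs absent→present `g`,
  present→absent 1.
* **Dollo parsimony** allows exactly one gain, placed at the most
  recent common ancestor of the present leaves; the losses are the
  maximal all-absent subtrees below it.
* **Fusion parsimony** is maximum parsimony with at most one gain
  inside the Eukaryotic subtree (the subtree rooted at the MRCA of the
  Eukaryotic leaves); gains at the root or in the Archaeal/Bacterial
  subtrees are unconstrained.  Implemented by augmenting the DP state
  with the count of Eukaryotic gains used (0 or 1); child contributions
  combine by a capped convolution over that count.

**Age** = normalized age of the earliest (oldest) gain node, i.e. the
max over gains.  **Co-optimal tie-break**: minimum-cost scenarios are
not unique; the DP optimizes lexicographically (cost, then
earliest-gain age), by default *maximizing* the age, with
`prefer_old=False` to minimize instead so the tie-break's effect is
measurable.  The max-age objective combines across subtrees as a
maximum, which is monotone in each child's contribution, so the
per-child lexicographic optimum is globally optimal; the implementation
is checked against exhaustive enumeration over all internal-state
assignments (including the constrained fusion variant and both
tie-break directions).

Degenerate input: an all-absent profile has no defined age and is
rejected; the simulator re-draws such units rather than emitting them.

**Age groups.** Ancient means age = 1 within an absolute tolerance of
1e-9 on normalized ages; new-born means age ≤ cutoff.  The cutoff is a
parameter (default 0.1); `auto_cutoff` instead scans the observed ages
for the value that most nearly equalizes the new-born and ancient group
sizes, which is the criterion the analysis design calls for when a
fixed value is not given.

A known model relation used in the tests: MP age ≤ Dollo age always (a
gain strictly above the presence MRCA forces at least one extra loss,
so it is never co-optimal), and MP collapses exactly to the Dollo
scenario once `g` exceeds any achievable loss count.  The tests use
`g = n_leaves + 1`: the often-quoted threshold "g > number of present
leaves" is not sufficient (two present leaves at the ends of a
caterpillar need arbitrarily many losses under a single gain), whereas
the leaf count bounds the Dollo loss set.

## Trees

Eight tree configurations per genome set: {backbone topology with
Wagner-parsimony branch lengths, NJ-jackknife consensus under Jaccard,
the same under Bray-Curtis, provided topology with Wagner-parsimony
branch lengths} × {superfamily, fold}.  Full parsimony topology
*search* is intentionally out of scope — any externally supplied Newick
can stand in as the backbone/provided topology; in the synthetic
pipeline both default to the simulation tree's topology.

* **Distances.**  For genomes i, j, count units on both (`a`), only on
  i (`b`), only on j (`c`); units on neither are ignored.  Jaccard
  `(b+c)/(a+b+c)`; Bray-Curtis on presence/absence `(b+c)/(2a+b+c)`.
  Pairs with an empty union have no defined distance and are an error.
* **Neighbour joining** delegates to scikit-bio with negative branch
  length estimates clamped to zero (the behaviour of the classic
  PHYLIP pipeline this reproduces).
* **Jackknife.**  100 delete-half resamples of the *units* (columns of
  the profile are genomes; resampling is over the characters, not the
  taxa), each keeping `floor(U/2)` units without replacement, seeded.
* **Consensus.**  Extended majority rule: splits above 50% frequency
  always enter; remaining splits are added greedily by decreasing
  frequency (ties broken by bitmask for determinism) when compatible
  with everything accepted.
* **Branch lengths.**  On consensus topologies: weighted least squares
  with Fitch-Margoliash weights `1/d²` (zero distances fall back to
  the largest finite weight), non-negativity enforced by bounded least
  squares.  On backbone topologies: Wagner parsimony — each branch gets
  the expected number of 0↔1 transitions averaged uniformly over *all*
  most-parsimonious reconstructions, summed over units, computed
  exactly by an inside-outside DP that counts optimal assignments
  (verified against exhaustive MPR enumeration).
* **Rooting.**  Either at the node whose removal separates the three
  superkingdom leaf sets (root acquires exactly three children), or on
  the midpoint of an outgroup's pendant edge.  Non-monophyletic
  superkingdoms are an error listing the offending leaves; the
  pipeline falls back to archaeal-outgroup rooting with a recorded
  warning, mirroring the use of an archaeal outgroup when a
  trifurcation is unavailable.
* **Height normalization.**  age(v) = (max path length from v to a
  descendant leaf) / (max root-to-leaf path length).  This forces every
  leaf to 0 and the root to 1 exactly, even on non-ultrametric trees,
  and is invariant to uniform branch-length scaling; ages are
  non-increasing from root to leaf.  The alternative reading
  (normalized depth from the root) disagrees with leaf-age-0 on
  non-ultrametric trees, which is why the max-descendant-path
  convention was adopted.  An all-zero-length tree yields ages 1 for
  internal nodes and 0 for leaves, with a warning.

## Descriptors

Computed per representative domain, averaged per superfamily:

* radius of gyration `Rg` — RMS distance of Cα atoms from their
  centroid (Å);
* contacts — Cα pairs within 8 Å; non-local if ≥ 5 residues apart in
  sequence; the non-local count is divided by `Rg` (contacts/Å).  Both
  thresholds are configurable; the defaults follow the conventional Cα
  contact-order definitions;
* buried fraction — residues with relative solvent exposure < 7% (the
  JOY-style convention) as a proportion of length, divided by `Rg`;
  a flag divides the raw count instead, since either reading of the
  normalization is defensible;
* hydrophobicity — mean of per-residue values on the optimal matching
  hydrophobicity (OMH) scale of Sweet & Eisenberg, shipped as a data
  file and replaceable by any complete residue→value table;
* strand direction — a domain with ≥ 15% strand residues is labelled
  parallel (or antiparallel) when ≥ 70% of its strand-residue pairing
  votes point that way, else mixed; each strand residue inherits the
  orientations of its strand's sheet pairings, counting strands paired
  both ways once per pairing;
* disulphides — a superfamily is *with* disulphides when more than half
  its domains have a bond, *without* only when none do; the remaining
  *ambiguous* middle class is excluded from contrasts;
* amino-acid propensities — `P(aa, g) = (n_aa,g / N_g) / (n_aa / N)`;
  expectation 1 under no preference; the conservation identity
  `Σ_g (N_g/N)·P(aa,g) = 1` holds for any partition and is asserted in
  tests; significance is a 1-df Pearson chi-square on the 2×2 table
  (this amino acid vs others × this group vs rest), flagged when any
  expected cell is below 1.

Secondary structure, exposure and disulphide annotations are inputs
(the DSSP/JOY/PROMOTIF boundary); the package never computes them from
coordinates.

## Motifs

Sheet topologies record each strand's chain rank and integer sheet
slot, plus pairing orientations between adjacent slots.  A **greek
key** is a window of four chain-consecutive strands in one sheet whose
slot deltas match a signature — default {(+3,−1,−1), (−3,+1,+1)},
mirror-closed so spatial renumbering cannot change calls — with every
adjacent-slot pairing in the window antiparallel.  A **jelly roll** is
a greek key wrapped by the strands immediately before and after it in
the chain, sitting on the two slots just outside the key's span and
pairing antiparallel with the outer key strands.  Signatures are data
and can be replaced; the defaults are deliberately conservative (no
5-strand keys, no mixed sheets).  At superfamily level, any domain
with a jelly roll puts the superfamily in the jelly-roll set;
remaining superfamilies with any greek key form the greek-key set, so
the sets are disjoint by construction.

## Statistics

* **Mann-Whitney U** from midranks with the tie-corrected variance
  `(n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))]` and a 0.5 continuity
  correction on z; for pooled N ≤ 12 an exact permutation path
  enumerates all assignments (one-sided upper tail on U; two-sided by
  the deviation rule).  At these sample sizes the normal approximation
  can differ from the exact p by ~0.1 or more when ties make the
  permutation distribution lumpy — the exact path exists precisely for
  that regime, and the reported `method` field says which was used.
* **Enrichment**: one-sided hypergeometric upper tail P(X ≥ k) per
  (term, group), Bonferroni over all tests performed.  The universe
  defaults to superfamilies with at least one annotation
  (`annotated_only=False` widens it), since whether unannotated
  superfamilies belong in N is genuinely ambiguous; terms annotating
  nothing are skipped.  No ontology-graph propagation is performed —
  annotations are consumed as provided, with pre-propagated input
  accepted as-is.
* **Structure vs function**: three parallel-vs-antiparallel age
  contrasts — by structural label; by annotation with terms enriched in
  either directional subset (overlapping superfamilies counted on both
  sides, overlap reported); and restricted to superfamilies unique to
  one side.  Degenerate sides are reported, not errors.
* **Percentile curves**: quantiles at integer percentiles 0–100 with
  linear interpolation, for plotting age distributions.

## Synthetic data

The generator produces every pipeline input with known ground truth.
Default conditions: 12 genomes (4 per superkingdom), 500 units, 10%
per-branch loss, 1% per-branch lateral transfer, 1% per-leaf
false-positive/false-negative annotation noise, uniform birth-node
distribution, seed mandatory.  Loss is absorbing — a lineage that
loses a unit regains it only through an explicit transfer event —
matching the gain/loss event vocabulary of the parsimony models.
Births at leaves are allowed (true age 0).  Units that end all-absent
are re-drawn and the re-draw count logged, keeping matrices aligned
with the truth table.  Under the branch-length-weighted birth option
the root, which has no parent edge, receives the mean edge length as
its weight.

Toy domains chain ideal secondary-structure segments (α-helical
spirals: 2.3 Å radius, 1.5 Å rise, 100°/residue; near-extended strand
zigzags; random-walk coils) with 3.8 Å virtual bonds and clash
avoidance (≥ 3.5 Å between non-consecutive Cα), centroid-biased for
compactness; exposures are sampled to hit a target buried fraction
with burial biased toward the core, and disulphide pairs link
spatially close residues rewritten to cysteine.

What this does *not* emulate: real SCOP class frequencies, sequence
evolution, genome-size heterogeneity, phylogenetic signal in the
annotation noise, or realistic secondary-structure packing.  Passing
tests therefore demonstrate the correctness of the algorithms and the
qualitative behaviour of the statistics under known ground truth — not
that real protein data would yield any particular effect size.

## Pipeline scale and determinism

The end-to-end run uses 12 genomes × 500 units × 8 trees, 100
jackknife replicates per distance tree, 60 structure-bearing
superfamilies and ~16 functional terms; these sizes keep a full run in
the tens of seconds while leaving every stage non-trivially populated.
All randomness flows from one config seed through fixed offsets (and a
character-sum of the recipe name for jackknife sub-seeds, since
Python's salted string hash is not reproducible across processes);
reports are byte-identical across reruns.  In the synthetic full run
the structural stage plants age-covarying effects (older superfamilies
longer, more buried, more often parallel; younger ones more
disulphide-bonded, more often greek key/jelly roll) so the downstream
contrasts have signal to find; the statistics modules are tested
separately under null and planted alternatives.

## Known limitations

* No likelihood-based (ML/Bayesian) gain-loss models, and no
  per-superfamily evolutionary models.
* Parsimony topology search is out of scope; only branch-length
  assignment on fixed topologies is implemented.
* The consensus tree builder assumes a shared taxon namespace and
  re-binds trees when needed; supports are reported per split, not
  written into Newick node labels.
* Exact Mann-Whitney enumeration is exponential and restricted to
  pooled N ≤ 12 by default.
* The fusion DP caps Eukaryotic gains at one; generalizing the cap is
  straightforward but unneeded here.
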