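# Methods

## The model

RNA secondary structure can be treated as phylogenetic data in its own
right.  A molecule is deconstructed into *substructures* — double-helical
stems, hairpin loops, bulges and internal loops, multiloop segments,
joints, and free ends — and the geometry of each substructure (its length
in base pairs for stems, in nucleotides otherwise, optionally the number of
G:U pairs per stem) becomes an ordered multistate character.  Homology is
positional: only substructures of the same kind and the same canonical
label (the P-numbering of RNase P helices, for instance) are compared
column-wise, because stems and loops respond to different evolutionary
models.  A substructure absent from a molecule is coded with the minimum
state 0, not dropped.

Characters are *polarized* by an evolutionary tendency toward conformational
order: base-paired, stabilizing elements are assumed ancestrally maximal
and erode, while unpaired, de-stabilizing elements are assumed ancestrally
absent and grow.  Operationally a hypothetical ancestor is added to the
matrix — the column maximum for every stabilizing character, 0 for every
de-stabilizing one — and included in the parsimony search as an ordinary
terminal.  The resulting trees are *intrinsically rooted*: after the
search, each minimal tree is rooted on the branch where the ancestor
attaches and the ancestor leaf is pruned.  No outgroup is needed.  Reported
tree lengths are those of the search trees, i.e. they include the steps on
the ancestor's terminal branch.

Because the matrix can be transposed, the same machinery yields two kinds
of trees: trees of molecules (rows are molecules) and trees of
substructures (rows are substructures of one kind).  On a rooted tree of
substructures, basal leaves are the oldest structural components; the
relative age of each leaf is its node distance

    nd = (d − d_min) / (d_max − d_min),

where d counts internal nodes on the root-to-leaf path.  The basal-most
leaf scores exactly 0 and the deepest exactly 1; a star tree carries no
chronology and scores 0 everywhere.  On trees whose basal leaf attaches at
the root (d_min = 1, as in the published RNase P stems chronology) this
reduces to (d − 1)/(d_max − 1); the d_min normalization is our choice so
the 0–1 endpoint contract holds on every rooted tree, including consensus
trees whose root has only internal children.  Polytomies count once, so
leaves tied at a consensus polytomy share an nd value.  By default nd is
computed on the strict consensus of all minimal trees (a flag selects
single-tree mode); values are divided into 10 equal classes for heat-map
coloring (configurable).

## Parsimony engine

Ordered characters cost |i − j| per step (Wagner parsimony); unordered
characters (aligned sequence columns in total-evidence matrices) use Fitch
costs, with alignment gaps treated as missing rather than a fifth state.
All searches are equally weighted.

The engine exploits an exact identity: for two trees joined by a new branch
between subdivision points on edges e1 and e2,

    len(join) = len(T1) + len(T2) + Σ_c gap(I1(e1,c), I2(e2,c)),

where I(e,c) is the Farris state interval (or Fitch state set) of the tree
rooted at edge e.  This follows from the rooting-invariance of parsimony
length, and makes the incremental cost of every stepwise addition,
branch-and-bound expansion, and TBR reconnection exact at O(taxa ×
characters).  The per-tree down-pass/up-pass kernel is JIT-compiled with
numba when available, with an identical pure-Python fallback.  A full
Sankoff dynamic program over the complete 62-state space (min-plus with a
distance transform for the linear costs) is kept as an independent slow
path; it handles arbitrary multifurcating trees and is cross-checked
against the interval engine, against brute-force enumeration of internal
state assignments, and against phangorn's Sankoff implementation in the
test suite.

Search strategies follow standard cladistic practice:

* **exhaustive** (≤ 10 taxa): complete enumeration by stepwise insertion;
  every unrooted topology is generated exactly once, so all minimal trees
  are collected.
* **branch and bound**: the same enumeration with pruning; the incremental
  length of a partial tree never decreases on completion, so pruning
  against an initial greedy-addition upper bound is admissible and the
  result is exact.
* **heuristic**: random-addition replicates, each followed by TBR branch
  swapping with first-improvement moves.  At a local optimum, up to
  `plateau_cap` distinct equally parsimonious neighbors are also swapped
  (MULTREES-style), which lets small searches cross TBR islands; on larger
  problems the replicate diversity does that work and the plateau can be
  disabled.  One shortest tree (plus its plateau) is kept per replicate and
  distinct minima are pooled, deduplicated by a canonical (sorted-children,
  leaf-0-rooted) form, up to a `max_trees` cap (default 10,000) with a
  saturation flag.

All tie-breaks — addition order, edge choice, bisection order — are
first-found under a generator seeded from a single integer, so every search
is reproducible.

Statistics: CI = m/s (m = Σ per-character minimal steps, s = tree length),
with a second value excluding parsimony-uninformative characters (those
whose star-tree maximum g_i equals m_i, i.e. constant or autapomorphic
patterns); RI = (g − s)/(g − m); RC = CI × RI.  g1 is the Fisher skewness of
the length distribution over uniformly sampled unrooted topologies
(uniformity by sequential insertion on a uniformly chosen edge); it errors
on zero-variance distributions.  Bootstrap support resamples characters
with replacement and builds one tree per replicate by greedy stepwise
addition with a random taxon order and no swapping ("fast" semantics);
support is the percentage of replicates containing each rooted clade of
the reporting tree.

## Synthetic data

The generator produces matrices with known ground truth under the same
polarization model the coding assumes.  A Yule tree is simulated
(`n_taxa` = 20 by default); characters evolve along branches by a reflected
random walk on {0..max_state} with Poisson(`change_rate` = 0.2) steps per
branch and probability `drift` = 0.8 of moving in the derived direction
(down for stems, up for loops).  `max_state` defaults to 12, a realistic
ceiling for helix lengths in base pairs.  Two further processes shape the
matrix:

* **accretion**: each character is born at a position on the trunk (the
  root-to-deepest-leaf path); lineages diverging before the birth code 0.
  By default stem births are spread evenly along the trunk in character
  order, giving a known accretion rank per character; a hairpin-loop
  character is born with (and lost with) its host stem, so every simulated
  matrix is realisable as actual molecules.
* **lineage loss**: each active substructure is lost outright with
  probability `loss_prob` = 0.02 per branch, mimicking lineage-specific
  substructure loss.

`simulate_molecules` realises a matrix as dot-bracket records (G:C stems
with A-loops) plus a homology annotation, and the round trip
decompose → label → code reproduces the matrix bit for bit — the
end-to-end correctness check for the whole structural front end.

Two model predictions are checked on replicates.  (1) *Polarity*: with
every substructure ancestrally present (all births at the root), reversing
the ancestor (minimum for stems, maximum for loops) produces equally or
less parsimonious trees; this is the regime in which the polarization
assumption is meaningful, and the check passes in 100/100 replicates.
Under heavy accretion the reversed ancestor can be cheaper — characters
born mid-tree genuinely have root state 0 — so the polarity check is run
under the erosion model, not the accretion one.  (2) *Chronology
recovery*: with accretion on, the Spearman correlation between true
accretion ranks and nd read off the tree of substructures exceeds 0.9 in
the median at the default noise level, degrading as `change_rate` grows.

What the generator does not emulate: base-pairing covariation and
compensatory substitutions, non-canonical pairs, rate heterogeneity across
lineages, coaxial-tract annotation ambiguity, and alignment error in
total-evidence data.  Passing tests therefore demonstrate the correctness
and internal consistency of the pipeline under its own model, not the
historical accuracy of any chronology inferred from real molecules.

## Numerical and design choices

* States are written in the alphanumeric alphabet 0–9, A–Z, a–z (0..61);
  larger lengths clamp to 'z' with a warning, keeping the alphabet closed.
* Coordinates are 0-based closed intervals internally; CT, bpseq and
  annotation files are 1-based on disk.
* Stems are maximal stacked runs of pairs; a single unpaired nucleotide
  terminates a run.  Coaxial composite tracts (P10-11 and the like) are
  created only through explicit annotation: stems sharing a label merge,
  absorbing unannotated bulges/internal loops strictly inside the tract.
  Lone pairs are stems.  Pseudoknot stems are ordinary stems for coding;
  crossing affects only loop classification, which uses the non-crossing
  nesting skeleton (greedy 5'-first layer assignment).
* NEXUS output carries DATA, ASSUMPTIONS (ordered/unordered TYPESET) and
  PAUP (ANCSTATES vector) blocks; character kind/domain/metric metadata
  ride in bracketed comments so a round trip is lossless.  The SYMBOLS list
  declares only the prefix in use, which keeps small-state files readable
  by parsers with case-insensitive alphabets.
* Heat maps are SVG 1.1 authored directly (a layout is a trivial list of
  labelled shapes); templates are either label/x/y/shape TSV or an SVG
  whose elements carry substructure ids.  Unscored elements render grey and
  are listed in a warning comment.
* The packaged table of the 26 RNase P helical substructures (their nd
  chronology and taxonomic distribution over structural types A/M/A/B/C/E)
  is printed reference data; `published.chronology_tree()` rebuilds the
  ladder tree it implies (21 depth levels, one unary level with no terminal)
  so the ancestry code can be validated against printed values.

## Problem sizes

Tests and the acceptance script run the study at reduced but representative
sizes chosen to keep a complete replication on one CPU within minutes:
1,000 (300 in the script) random matrices of up to 8 taxa for the
search-equivalence check, 100 polarity replicates at 20 taxa × 30
characters, and 20 chronology-recovery replicates at the default
conditions.  g1 uses 2,000 random trees and bootstrap 2,000 replicates in
the analysis scripts (the statistics stabilise well below the 10^4–10^5
used in large production runs).

## Known limitations

* Heuristic searches are not guaranteed to find all minimal trees (or, on
  adversarial data, the minimum itself); branch and bound is exact but
  exponential.  The `>10,000`-tree saturation cap mirrors a MAXTREES limit
  and is reported, not silently truncated.
* The reproduction of the published RNase P tree statistics requires the
  original study's supplementary 133 × 129 structural matrix, which is not
  redistributed here; the pipeline (TSV ingest → partition → search → stats → nd)
  is implemented and tested on synthetic data of the same shape, and the
  corresponding acceptance test fails with a clear message until the matrix
  is supplied at `data/rpr_structural_matrix_s2.tsv`.
* Secondary-structure layout is not computed; heat maps need a template.
* No sequence alignment and no automatic P-number inference: structures
  and homology annotations are inputs.
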