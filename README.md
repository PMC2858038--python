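# rnaclad — structural cladistics of RNA molecules

`rnaclad` reconstructs evolutionary history directly from RNA secondary
structure.  It was built around the classic structural-cladistic analysis of
ribonuclease P RNA (RPR), in which the shape of a molecule — the lengths of
its stems, loops and unpaired segments — is coded as phylogenetic characters
and used to infer both *trees of molecules* (which lineages are ancient) and
*trees of substructures* (which parts of the molecule are ancient).  It is
aimed at molecular evolutionists who want intrinsically rooted phylogenies
from structure without external outgroups.

The pipeline:

1. **Decompose** secondary structures (dot-bracket with pseudoknot layers,
   CT, bpseq) into typed substructures — stems, hairpins, bulges/internal
   loops, multiloop segments, joints, free ends — and attach canonical
   homology labels (P-numbering) from an annotation.
2. **Code** a taxa × characters matrix of lengths in the alphanumeric state
   alphabet `0-9 A-Z a-z`, with missing substructures as state 0.
3. **Polarize** with a hypothetical ancestor: stabilizing characters
   (stem lengths, G:U pairs) take the column maximum ancestrally and erode;
   de-stabilizing characters (loops, unpaired segments) start at 0 and
   grow.  The ancestor joins the search as a terminal and roots the tree.
4. **Search** under equally weighted Wagner parsimony, cost |i − j| per
   ordered character (Fitch for sequence columns in total-evidence
   matrices): exhaustive, branch-and-bound, or heuristic
   (random-addition + TBR with MULTREES-style pooling), with CI/RI/RC,
   g1 skewness, and fast stepwise-addition bootstrap.
5. **Transpose** the matrix to build trees of substructures, convert them
   into node-distance chronologies

       nd = (d − d_min) / (d_max − d_min) ∈ [0, 1]

   (d = internal nodes from root to leaf; basal = oldest = 0), and render
   evolutionary heat maps (SVG) of substructure ancestry.

A synthetic-data generator with known ground truth (true tree, true
substructure accretion order) makes the whole pipeline testable end to end,
and the printed chronology of the 26 RPR helical substructures ships with
the package (`rnaclad.published`) for validation against published values.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
dataset of 20 molecules × 48 characters (30 stems + 18 hairpin loops):

```bash
python analysis/01_simulate_dataset.py      # molecules.dbn, annotation, truth
python analysis/02_code_characters.py       # decompose -> label -> code -> NEXUS
python analysis/03_tree_of_molecules.py     # rooted MP tree + statistics
python analysis/04_tree_of_substructures.py # transpose -> chronology (nd)
python analysis/05_ancestry_heatmap.py      # SVG heat maps, accretion curves
python analysis/06_polarization_and_recovery.py  # replicated model checks
```

`03_tree_of_molecules.py` prints (seed 2010):

```
{
  "ci_with": 0.753,
  "ci_without": 0.752,
  "g1": -0.843,
  "n_min_trees": 8,
  "rc": 0.695,
  "reversed_polarity_length": 509,
  "ri": 0.923,
  "tree_length": 494
}
clades with bootstrap support > 50%: 14/16
reversed polarization is less parsimonious, as the model predicts
```

— eight minimal trees of 494 steps with moderate homoplasy (CI 0.75,
RI 0.92), strongly left-skewed tree-length distribution (g1 = −0.84,
i.e. hierarchical signal), and a longer tree (509 steps) when the
polarization is reversed.  `04_tree_of_substructures.py` then reports

```
"spearman_nd_vs_true_rank": 0.98
```

— the node-distance chronology read off the tree of substructures ranks the
48 substructures almost exactly in their true accretion order, with the
oldest simulated stem basal (nd = 0) and the youngest at nd = 1.
`05_ancestry_heatmap.py` recomputes the published RPR helical chronology
from the packaged table: stem P12 basal at nd = 0.00, the coaxial P10-11
tract at 0.25, and P10.1 most derived at 1.00.

The same steps are available as a CLI (`rnaclad decompose | code | nexus |
analyze | nd | heatmap | simulate`); `rnaclad analyze` writes trees, a
consensus, statistics, an nd table and a reproducibility manifest into a
run directory.

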