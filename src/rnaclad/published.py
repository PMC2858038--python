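"""The published chronology of RNase P helical substructures.

Ships the printed table of the 26 helical substructures of the RPR
molecule: their node-distance (nd) ancestry values from the tree of stem
substructures and their taxonomic distribution over the structural types
(Archaea A/M, Bacteria A/B/C, Eukarya E).  The chronology tree implied by
the nd column can be reconstructed to exercise the ancestry machinery
against the printed values: nd steps on a 0.05 grid imply 21 depth levels,
with stem P12 basal (nd = 0.00) and P10.1 / P15.1 deepest (nd = 1.00).
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

__all__ = [
    "helical_chronology",
    "chronology_tree",
    "type_groups",
]

_TYPE_COLUMNS = [
    "archaea_A",
    "archaea_M",
    "bacteria_A",
    "bacteria_B",
    "bacteria_C",
    "eukarya_E",
]


def helical_chronology() -> pd.DataFrame:
    """Printed helical-substructure chronology as a data frame.

    Columns: ``label``, ``nd`` and one +/- presence column per structural
    type.
    """
    ref = resources.files("rnaclad.data").joinpath("helical_chronology.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def chronology_tree(df: pd.DataFrame | None = None) -> dendropy.Tree:
    """Reconstruct the chronology (ladder) tree implied by the nd column.

    Leaves attach along an internal chain at the depth their nd value
    implies (d = nd * (d_max - 1) + 1); depth levels without a terminal
    substructure remain as unary chain nodes so every printed nd value is
    reproduced exactly by :func:`rnaclad.ancestry.node_distance`.
    """
    if df is None:
        df = helical_chronology()
    step = min(b - a for a, b in zip(sorted(set(df["nd"])), sorted(set(df["nd"]))[1:]))
    d_max = round(1.0 / step) + 1
    depth_of = {
        row.label: round(row.nd * (d_max - 1)) + 1 for row in df.itertuples()
    }

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    chain = [tree.seed_node]
    for _ in range(2, d_max + 1):
        node = dendropy.Node()
        chain[-1].add_child(node)
        chain.append(node)
    for label, d in depth_of.items():
        leaf = dendropy.Node()
        leaf.taxon = tns.new_taxon(label)
        chain[d - 1].add_child(leaf)
    return tree


def type_groups(df: pd.DataFrame | None = None) -> dict[str, dict[str, str]]:
    """Presence map per structural type: type -> {label: '+'/'-'}."""
    if df is None:
        df = helical_chronology()
    out: dict[str, dict[str, str]] = {}
    for col in _TYPE_COLUMNS:
        out[col] = dict(zip(df["label"], df[col]))
    return out
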