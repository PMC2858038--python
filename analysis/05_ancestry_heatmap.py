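"""Evolutionary heat maps of substructure ancestry.

Colors a secondary-structure layout by nd class, for two chronologies: the
synthetic stems chronology inferred in 04, and the published chronology of
the 26 RNase P helical substructures shipped with the package (stem P12
basal at nd = 0.00, P10.1/P15.1 most derived at nd = 1.00).

Writes results/heatmaps/: synthetic.svg, rnasep_helices.svg and the
published chronology's cumulative accretion per structural type.
"""

from pathlib import Path

from rnaclad import AncestryMap, cumulative_accretion, node_distance, render_heatmap
from rnaclad.published import chronology_tree, helical_chronology, type_groups

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "heatmaps"


def grid_layout(labels, per_row=6):
    rows = []
    for k, lab in enumerate(labels):
        x, y = k % per_row, k // per_row
        rows.append(f"{lab}\t{x}\t{y}\tcircle")
    return "\n".join(rows) + "\n"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # synthetic chronology from 04
    nd = {}
    for ln in (BASE / "substructures" / "nd.tsv").read_text().splitlines()[1:]:
        label, v = ln.split("\t")
        nd[label] = float(v)
    amap = AncestryMap(nd)
    (OUT / "synthetic.svg").write_text(
        render_heatmap(amap, grid_layout(sorted(nd, key=nd.get)))
    )

    # published helical chronology
    df = helical_chronology()
    amap_pub = node_distance(chronology_tree(df))
    order = sorted(amap_pub.nd, key=amap_pub.nd.get)
    (OUT / "rnasep_helices.svg").write_text(
        render_heatmap(amap_pub, grid_layout(order))
    )

    # accretion of substructures per structural type (presence-weighted)
    presence = type_groups(df)
    for type_name, has in presence.items():
        sub = {l: v for l, v in amap_pub.nd.items() if has[l] == "+"}
        curve = cumulative_accretion(AncestryMap(sub))
        curve.columns = [type_name]
        curve.to_csv(OUT / f"accretion_{type_name}.tsv", sep="\t")
    print(f"wrote heat maps and {len(presence)} accretion curves -> {OUT}")
    print(
        "published chronology extremes:",
        {l: amap_pub.nd[l] for l in ("P12", "P10-11", "P10.1")},
    )


if __name__ == "__main__":
    main()
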