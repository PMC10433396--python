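#!/usr/bin/env python
"""Alpha diversity (reads, OTUs, coverage, Chao1, ACE, Shannon, Simpson),
beta diversity (Bray-Curtis and unweighted UniFrac), and PCoA for the
selection-regime dataset.

Reads the files written by 01_simulate_datasets.py back through the
package's own readers, so this script also exercises the full file
round-trip.  Outputs land in results/diversity/.
"""

from pathlib import Path

from commeco import diversity as dv
from commeco.io import read_count_table, read_metadata, read_newick, write_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "selection"
OUT = ROOT / "results" / "diversity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(DATA / "counts.tsv")
    tree = read_newick(DATA / "tree.nwk")
    groups = read_metadata(DATA / "metadata.tsv")
    groups.check_counts(counts)

    alpha = dv.alpha_table(counts)
    write_table(alpha, OUT / "alpha.tsv", index_label="sample_id")
    summary = dv.alpha_group_summary(alpha, groups)
    write_table(summary, OUT / "alpha_groups.tsv", index_label="group")
    print("alpha diversity (group means):")
    print(summary[["shannon_mean", "simpson_mean", "chao1_mean"]].round(3))

    for name, dm in [("braycurtis", dv.bray_curtis(counts)),
                     ("unifrac", dv.unweighted_unifrac(counts, tree))]:
        write_table(dm.to_data_frame(), OUT / f"dm_{name}.tsv",
                    index_label="sample_id")
        ordination = dv.pcoa(dm, k=2)
        write_table(ordination.coordinates, OUT / f"pcoa_{name}.tsv",
                    index_label="sample_id")
        pct = 100 * ordination.proportion_explained
        print(f"{name} PCoA: axis1 {pct[0]:.1f}%, axis2 {pct[1]:.1f}% "
              "of (positive-eigenvalue) variance")


if __name__ == "__main__":
    main()
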