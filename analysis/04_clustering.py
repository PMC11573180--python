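#!/usr/bin/env python
"""Clusters of orthologous huge proteins.

Greedy set-cover clustering of the HP set at identity >= 0.3 and
bidirectional coverage >= 0.8, with composition and functional-category
tables; checks recovery against the planted families.
"""

import argparse
from pathlib import Path

from hugeprot.clustering import cluster_summary, greedy_cluster, membership_table
from hugeprot.io_formats import read_annotations, read_fasta, read_metadata
from hugeprot.prevalence import extract_hps


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    proteins = list(read_fasta(args.data / "proteins.fasta"))
    metas = read_metadata(args.data / "metadata.tsv")
    annotations = read_annotations(args.data / "annotations.tsv")
    hp_ids = extract_hps(proteins).all_ids
    hp_records = [p for p in proteins if p.protein_id in hp_ids]

    clusters = greedy_cluster(hp_records)
    membership_table(clusters).to_csv(args.out / "clusters.tsv", sep="\t", index=False)
    summary = cluster_summary(clusters, hp_records, metas, annotations)
    summary["clusters"].to_csv(
        args.out / "cluster_composition.tsv", sep="\t", index=False
    )
    summary["categories"].to_csv(
        args.out / "cluster_categories.tsv", sep="\t", index=False
    )

    multi = [c for c in clusters if c.size >= 2]
    print(
        f"{len(hp_records)} HPs -> {len(clusters)} clusters "
        f"({len(multi)} with >= 2 members, sizes {sorted(c.size for c in multi)})"
    )
    if not summary["categories"].empty:
        print("top functional categories in multi-member clusters:")
        top = summary["categories"].query("cluster_type == 'multi'").head(5)
        for row in top.itertuples(index=False):
            print(
                f"  {row.superkingdom:<10} {row.functional_category}: "
                f"{row.n_proteins} proteins"
            )


if __name__ == "__main__":
    main()
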