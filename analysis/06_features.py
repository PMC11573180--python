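#!/usr/bin/env python
"""Protein features, localization hints and potential artifacts.

Aggregates disorder/signal-peptide/TMH annotations for the HP set,
flags potential gene-model artifacts, and rolls GO terms up the
ontology per superkingdom.
"""

import argparse
from pathlib import Path

import pandas as pd

from hugeprot.architecture import architectures_from_hits
from hugeprot.clustering import greedy_cluster
from hugeprot.features import GO_NAMESPACES, go_rollup, profile_features
from hugeprot.io_formats import (
    read_annotations,
    read_domtblout,
    read_fasta,
    read_metadata,
    read_obo,
)
from hugeprot.pipeline import _profile_table
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

    archs = architectures_from_hits(
        read_domtblout(args.data / "hits.domtblout"), protein_ids=sorted(hp_ids)
    )
    clusters = greedy_cluster(hp_records)
    cluster_sizes = {pid: c.size for c in clusters for pid in c.member_ids}
    profiles = profile_features(
        annotations,
        patterns={pid: a.pattern for pid, a in archs.items()},
        cluster_sizes=cluster_sizes,
        protein_ids=sorted(hp_ids),
    )
    _profile_table(profiles).to_csv(args.out / "features.tsv", sep="\t", index=False)

    ontology = read_obo(args.data / "go_mini.obo")
    sk_of_proteome = {m.proteome_id: m.superkingdom for m in metas}
    sk_of = {
        p.protein_id: sk_of_proteome.get(p.proteome_id or "", "unknown")
        for p in proteins
    }
    hp_ann = {pid: annotations[pid] for pid in sorted(hp_ids) if pid in annotations}
    frames = []
    for ns in GO_NAMESPACES:
        df = go_rollup(hp_ann, ontology, ns, superkingdom_of=sk_of)
        df.insert(0, "namespace", ns)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        args.out / "go_rollup.tsv", sep="\t", index=False
    )

    flagged = {pid: p for pid, p in profiles.items() if p.artifact_flags}
    print(f"{len(profiles)} HP feature profiles; {len(flagged)} flagged as potential artifacts:")
    tally: dict[str, int] = {}
    for p in flagged.values():
        for f in p.artifact_flags:
            tally[f] = tally.get(f, 0) + 1
    for flag, n in sorted(tally.items()):
        print(f"  {flag}: {n}")


if __name__ == "__main__":
    main()
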