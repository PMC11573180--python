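#!/usr/bin/env python
"""Where do huge proteins occur?

Extracts HPs (length >= 5000), applies the proteome filters, and
computes the per-phylum likelihood statistic L = 100 * h / s.
"""

import argparse
from pathlib import Path

from hugeprot.io_formats import read_fasta, read_metadata
from hugeprot.prevalence import (
    extract_hps,
    filter_proteomes,
    likelihood_table,
    phylum_likelihood,
    proteome_size_vs_hp_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    proteins = list(read_fasta(args.data / "proteins.fasta"))
    metas = read_metadata(args.data / "metadata.tsv")
    hp_set = extract_hps(proteins)
    kept, removal_log = filter_proteomes(metas)
    summaries = phylum_likelihood(hp_set, kept)

    likelihood_table(summaries).to_csv(
        args.out / "phylum_likelihood.tsv", sep="\t", index=False
    )
    proteome_size_vs_hp_table(hp_set, kept).to_csv(
        args.out / "size_vs_hp.tsv", sep="\t", index=False
    )
    removal_log.to_csv(args.out / "removal_log.tsv", sep="\t", index=False)

    print(f"{len(hp_set.all_ids)} HPs across {len(metas)} proteomes "
          f"({len(kept)} kept after filtering, {len(removal_log)} removed)")
    for s in summaries:
        print(
            f"  {s.superkingdom:<10} {s.phylum:<18} median likelihood "
            f"{s.median_likelihood_pct:.3f}% over {len(s.likelihood_pct)} proteomes"
        )


if __name__ == "__main__":
    main()
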