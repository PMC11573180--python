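#!/usr/bin/env python
"""Do huge proteins exist?

Compares existence-evidence tiers between HPs and non-HPs (raw
proportions, fixed-size resampling at 5/10/100 replicates,
Kruskal-Wallis + ANOVA) and correlates HP content with BUSCO
completeness and assembly level.
"""

import argparse
from pathlib import Path

from hugeprot.existence_stats import (
    assembly_level_summary,
    full_comparison,
    quality_correlations,
)
from hugeprot.io_formats import (
    attach_annotations,
    read_annotations,
    read_fasta,
    read_metadata,
)
from hugeprot.pipeline import _existence_table
from hugeprot.prevalence import extract_hps, filter_proteomes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    proteins = list(read_fasta(args.data / "proteins.fasta"))
    annotations = read_annotations(args.data / "annotations.tsv")
    proteins = attach_annotations(proteins, annotations)
    metas = read_metadata(args.data / "metadata.tsv")
    hp_set = extract_hps(proteins)
    kept, _ = filter_proteomes(metas)

    cmp = full_comparison(proteins, hp_set.all_ids, (5, 10, 100), args.seed)
    _existence_table(cmp).to_csv(args.out / "existence.tsv", sep="\t", index=False)
    quality_correlations(kept, hp_set, proteins).to_csv(
        args.out / "quality_correlations.tsv", sep="\t", index=False
    )
    assembly_level_summary(kept, hp_set).to_csv(
        args.out / "assembly_levels.tsv", sep="\t", index=False
    )

    print("existence-tier percentages (HP vs non-HP):")
    for lvl in (1, 2, 3, 4):
        print(f"  level {lvl}: {cmp.hp_pct[lvl]:6.2f}% vs {cmp.nonhp_pct[lvl]:6.2f}%")
    print(
        f"Kruskal-Wallis H={cmp.kruskal_h:.3f} (p={cmp.kruskal_p:.3g}); "
        f"ANOVA F={cmp.anova_f:.3f} (p={cmp.anova_p:.3g})"
    )


if __name__ == "__main__":
    main()
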