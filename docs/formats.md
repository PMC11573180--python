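# File formats

All files are UTF-8 with LF line endings. Coordinates are 1-based
inclusive everywhere (the HMMER convention); nothing in the package
converts them.

## FASTA (`proteins.fasta`)

Multi-FASTA wrapped at 60 columns. Headers are either
`>proteome_id|protein_id` or a plain `>protein_id` (in which case a
separate id→proteome mapping may be supplied to the reader). Sequences
are upper-cased on read; a single terminal `*` stop is stripped.
Allowed residues: the 20 standard amino acids plus `X B Z U O`.

## Proteome metadata TSV (`metadata.tsv`)

Tab-separated with a mandatory header. Columns:

| column | type | notes |
|---|---|---|
| `proteome_id` | string | unique; duplicates are an error |
| `taxid` | int | NCBI taxon id (opaque to the pipeline) |
| `superkingdom` | string | one of `archaea`, `bacteria`, `eukaryota` (case-insensitive); anything else — e.g. viruses — is rejected |
| `phylum` | string | taken verbatim; no taxonomy resolution |
| `proteome_size` | int | protein count, >= 1 |
| `assembly_level` | string | free categorical, e.g. `Complete genome`, `Contig` |
| `busco_completeness` | float | percentage in [0, 100]; empty = absent |
| `is_plasmid` | bool | `true`/`false`/`1`/`0` |

## Per-protein annotation TSV (`annotations.tsv`)

This is a package-defined schema carrying only the semantic content the
survey uses, not a byte-level clone of any predictor's output.

| column | type | notes |
|---|---|---|
| `protein_id` | string | key |
| `existence_level` | int | 1–4 (UniProt-style evidence tiers); a value of 5 ("Uncertain") drops the record with a warning |
| `disorder_scores` | packed floats | comma-separated per-residue scores in [0, 1]; length must equal the protein length; empty = absent |
| `has_signal_peptide` | bool | empty = absent |
| `n_tmh` | int | number of predicted transmembrane helices; empty = absent |
| `go_terms` | string | `;`-separated GO ids |
| `functional_category` | string | one-or-two-letter COG-style category; empty = absent |

Absent optional fields stay absent; nothing is imputed.

## HMMER3 domtblout (`hits.domtblout`, read-only)

Standard `hmmscan --domtblout` layout: `#` comment lines, then data
lines with >= 23 whitespace-separated columns. Columns consumed
(1-based): 1 target name, 2 target accession, 4 query (protein) name,
7 full-sequence E-value, 13 domain i-Evalue, 14 domain bit score,
20–21 envelope from/to. Any HMMER3.x minor-version layout with at
least 23 columns parses.

## OBO 1.2 (read-only)

Only `[Term]` stanzas with `id`, `name`, `namespace`, `is_a` and
`is_obsolete` are consumed. Obsolete terms are excluded; the `is_a`
graph must be acyclic.

## Pipeline outputs

Every stage writes TSV: `likelihood.tsv`, `size_vs_hp.tsv`,
`removal_log.tsv`, `existence.tsv`, `quality_correlations.tsv`,
`assembly_levels.tsv`, `clusters.tsv` (cluster_id, representative,
member, identity_to_rep, cov_rep, cov_member),
`cluster_composition.tsv`, `cluster_categories.tsv`,
`architectures.tsv`, `architecture_groups.tsv` (group_code, pattern,
n_proteins), `domain_distribution.tsv`, `features.tsv`,
`go_rollup.tsv`, `feature_length_profile.tsv`, plus `config.yaml` and
`manifest.json` (config hash, seed, row counts; no timestamps, so
re-runs are byte-identical).
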