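# Methods

## The survey

Huge proteins (HPs) are the extreme right tail of the protein length
distribution: sequences of at least 5000 amino acids. They are rare
(on the order of one to a few per thousand proteins in the most
HP-prone phyla, essentially absent in many prokaryotic lineages) and
disproportionately poorly annotated, which raises two linked
questions: where do they occur, and are they real proteins rather than
gene-model artifacts? This package implements the computational
survey that addresses both on any proteome collection expressed in its
input schemas, and ships a synthetic-data generator so that every
stage can be validated against planted ground truth.

The stages, in dependency order:

1. **Extraction and prevalence.** A protein is an HP iff its length is
   >= 5000 (boundary inclusive, configurable). Proteomes are filtered
   before any prevalence statistic: phyla with fewer than 5 proteomes
   are dropped; within each surviving phylum, proteomes whose size is
   strictly below `mean - SD` of the phylum's sizes are dropped (the
   statistics are computed once, before any size-based removal, and
   not re-applied); plasmid proteomes are dropped. The per-proteome
   likelihood of carrying HPs is `L = 100 * h / s` (HP count over
   proteome size); phyla are summarised by the median L and reported
   sorted by superkingdom, then median descending.
2. **Existence evidence.** Evidence tiers (1 protein level … 4
   predicted; tier 5 "uncertain" excluded at ingest) are compared
   between HPs and non-HPs by raw proportions, by fixed-size
   resampling of the non-HP cohort (without replacement, sample size
   equal to the HP cohort, 5/10/100 replicates, reporting per-tier
   count means and SDs), and by Kruskal-Wallis and one-way ANOVA.
   BUSCO completeness is correlated (Pearson, per superkingdom)
   against HP count per proteome and against HP length; HP counts are
   summarised per assembly level.
3. **Homology clusters.** HPs are clustered by greedy set cover at
   minimum identity 0.3 and bidirectional coverage 0.8 (both sequences
   must have >= 80% of their length inside the alignment envelope).
   Cluster composition is tallied by phylum and by supplied functional
   category labels; multi-member clusters and singletons are reported
   separately and cross-superkingdom clusters flagged.
4. **Domain architectures.** hmmscan domtblout hits are filtered at
   sequence E-value <= 0.001 AND domain i-Evalue <= 0.001, overlaps
   resolved, and each protein reduced to its ordered accession string
   (the architecture pattern). Identical patterns form groups with
   stable 6-character codes. Domain content is tabulated per phylum on
   a balanced subsample (<= 50 proteomes per phylum, top 15 phyla per
   superkingdom), and proteins carrying repeat-class domains are
   censused presence-wise.
5. **Features and artifacts.** Per-residue disorder scores collapse to
   the percentage of residues with score >= 0.5; signal peptides and
   TMH counts are consumed as annotations. A protein is flagged as a
   potential artifact when it has no domain, when it is a singleton
   with no functional category, or when its disorder is >= 99% (with
   exact 100% flagged separately). GO terms are propagated along
   `is_a` to all ancestors before counting distinct proteins per term.

## The aligner

Pairwise comparison uses an affine-gap Smith-Waterman (Gotoh) under
BLOSUM62 with gap open 11 / extend 1, where a gap of length k costs
`11 + k` (the BLAST protein convention: the first gap column costs
12). Identity is identical aligned columns divided by *all* alignment
columns, gaps included in the denominator — the conservative reading
of identity under coverage-mode-0 clustering — and coverage of each
sequence is its aligned envelope length over its full length.
Selenocysteine and pyrrolysine are retained in sequences but scored as
X, since standard matrices lack them; two X columns count as identical.

The aligner is written in-package (a numba-compiled kernel) rather
than delegated to an alignment library for one reason: the clustering
contract requires bit-for-bit reproducible alignments, including which
co-optimal alignment is traced. Tie-breaks are therefore fixed and
documented — diagonal over vertical gap over horizontal gap, gap
extension over re-opening, and among equal-scoring cells the smallest
row then column — and the test suite holds the implementation to
*exact* score and identity equality against an independently written
quadratic-space textbook Smith-Waterman on random pairs. All
arithmetic is integral-valued in double precision, so exactness is
well-defined.

For long, nearly collinear pairs (HP homologues under the no-indel
generator) an optional diagonal band of half-width `max(200,
0.1 * length)` accelerates the fill; full dynamic programming is used
for short sequences and whenever the oracle comparison runs. Greedy
clustering orders candidates by length descending (ties by id
ascending), so results are independent of input file order; a
brute-force implementation that computes the full pairwise matrix
first and applies the same greedy rule is kept in the tests as an
oracle for small n.

## The generator

`synthetic_data` emulates the statistical structure the survey
assumes, with defaults chosen as the package's study conditions:

* **Bulk lengths** are log-normal with ln-scale mu 5.8, sigma 0.9
  (median ~330 aa, a typical proteome-wide length law); the
  parameters are conventional rather than fitted to any particular
  dataset. Bulk lengths are capped at 4999 so the ground-truth HP set
  is exactly the planted set.
* **Background HPs** per proteome are Poisson with mean
  `hp_rate * size / 1000`; default rates per phylum span the observed
  range, from 0.05 per 1000 in archaea to 4 per 1000 in the most
  HP-prone eukaryotic phyla, so the per-proteome likelihood statistic
  spans roughly 0–0.4%.
* **Homologous HP families** (default 5 families of 6 members, lengths
  5000–6000) descend from one random ancestor each by i.i.d. per-site
  substitution, uniform over the 19 alternative residues, with no
  indels. The substitution probability p is the closed-form inverse of
  the expected pairwise member identity `(1-p)^2 + p^2/19`; the
  default target is 0.6, comfortably above the 0.3 clustering
  threshold, while unrelated sequences sit near the 1/20 random
  background. No indels means within-family coverage is exactly 100%,
  keeping the identity/coverage ground truth analytic. Families are
  planted *on top of* the Poisson background so neither process
  distorts the other's calibration.
* **Architectures** come from a small library that includes a
  multi-domain pattern with a repeated accession, a long repeat block
  and single-domain patterns; each HP's architecture is emitted as
  domtblout lines with envelope coordinates in order, >= 5-residue
  gaps, E-values well below the 0.001 thresholds for true hits and
  above them for decoys.
* **Annotations** use separate evidence-tier laws for HPs
  (0.8% / 0.06% / 22% / 77% across tiers 1–4) and non-HPs; planted
  family members draw COG-style category labels at proportions
  0.5/0.3/0.2; a fixed number of HPs is planted at >= 99% (and exactly
  100%) disorder to exercise the artifact flags.

Default problem sizes (30 proteomes of 150–300 proteins) are the
package's desk-scale study conditions: large enough that every
distributional check has power, small enough that the whole survey,
run twice for the determinism check, completes in minutes on one core.

What the generator does **not** emulate: indel evolution and domain
shuffling within families, genuine correlation structure between
quality covariates and HP content, realistic GO depth, or
database-scale cohort sizes. Passing tests therefore demonstrate that
the pipeline's logic is correct and calibrated on data satisfying its
stated model — not that any particular biological collection will
reproduce specific published counts, which depend on the underlying
sequence database release.

## Numerical and design choices

* The filtering SD is the sample SD (n−1); the cutoff comparison is
  strict (`<`), so a phylum of identical sizes loses nothing.
* Medians are plain order statistics (`numpy.median`, midpoint rule on
  even counts) everywhere, so summaries are comparable across stages.
* The unit of observation for the Kruskal-Wallis/ANOVA comparison is
  the per-protein ordinal evidence tier, two groups (HP vs non-HP) —
  the one reading under which both tests are well-defined on these
  data. Identical multisets short-circuit to H = 0, p = 1 (their exact
  value, which also avoids the degenerate all-tied case).
* Resampling is without replacement: the non-HP cohort is a finite set
  of distinct proteins, so the hypergeometric, not the binomial, is
  the reference law (and the calibration tests use hypergeometric
  standard errors).
* Overlap policy for domain hits: two envelopes conflict when their
  overlap exceeds 50% of the shorter; conflicts are settled by
  bitscore, then smaller i-Evalue, then accession. The threshold is a
  parameter; 0 reproduces strict non-overlap.
* Repeated domains are never collapsed in the primary pattern (repeat
  counts are part of the architecture); a collapsed view (`ACC*`) is
  emitted alongside for reporting.
* Group codes are the first 48 bits of SHA-256 of the pattern rendered
  in base-36 (6 characters); truncation collisions re-hash with an
  appended counter, so codes are stable across runs and injective
  within one.
* All randomness flows from one root seed; substreams use fixed
  `SeedSequence` spawn keys, so adding a stream never perturbs earlier
  draws, and identical config + seed yields byte-identical files.

## Known limitations

* The greedy clusterer is all-vs-representative with no k-mer
  prefilter: O(n·k) alignments for n sequences and k representatives.
  Fine at desk scale; a prefilter would be an optimisation, not a
  semantic change.
* The banded aligner can underestimate alignments whose optimal path
  leaves the band; it is used only where near-collinearity is
  expected, and every oracle comparison runs full DP.
* Functional categories and all predictor-derived annotations are
  inputs, not computed: the package deliberately contains no
  orthology, signal-peptide, TMH or disorder predictor.
* Published database-scale counts (total HPs, cluster counts,
  artifact counts, test p-values) are functions of a specific sequence
  database release and are out of scope for the synthetic validation.
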