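"""Existence-level evidence comparison between HPs and non-HPs.

UniProt assigns each protein an existence level: 1 (evidence at protein
level), 2 (transcript level), 3 (inferred from homology), 4 (predicted).
Level 5 ("uncertain") is excluded at ingest.  This module compares the
level distributions of the HP and non-HP cohorts three ways:

* raw per-level proportions,
* fixed-size resampling of the non-HP cohort (without replacement, the
  sample matching the HP cohort size, repeated 5/10/100 times) yielding
  per-level count means and SDs,
* Kruskal-Wallis and one-way ANOVA on the per-protein ordinal scores of
  the two cohorts (smaller level = stronger evidence).

It also computes per-superkingdom Pearson correlations of BUSCO
completeness against HP count and HP length, and assembly-level
summaries of HP counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EXISTENCE_LEVELS, ProteinRecord, ProteomeMeta
from .prevalence import HPSet


@dataclass
class ExistenceComparison:
    """Per-level counts/percentages for both cohorts plus test statistics."""

    hp_counts: dict[int, int] = field(default_factory=dict)
    nonhp_counts: dict[int, int] = field(default_factory=dict)
    hp_pct: dict[int, float] = field(default_factory=dict)
    nonhp_pct: dict[int, float] = field(default_factory=dict)
    resample_mean: dict[int, dict[int, float]] = field(default_factory=dict)
    resample_sd: dict[int, dict[int, float]] = field(default_factory=dict)
    kruskal_h: float | None = None
    kruskal_p: float | None = None
    anova_f: float | None = None
    anova_p: float | None = None


def _level_counts(levels: Sequence[int]) -> dict[int, int]:
    counts = {lvl: 0 for lvl in EXISTENCE_LEVELS}
    for lvl in levels:
        if lvl not in counts:
            raise ValueError(f"existence level {lvl} outside 1-4 (exclude at ingest)")
        counts[lvl] += 1
    return counts


def existence_proportions(
    proteins: Iterable[ProteinRecord], hp_ids: set[str]
) -> ExistenceComparison:
    """Per-level counts and percentages for the HP and non-HP cohorts.

    Every protein must carry a level in 1-4; pct = 100 * count / cohort
    size.
    """
    hp_levels, nonhp_levels = [], []
    for p in proteins:
        if p.existence_level is None:
            raise ValueError(f"protein {p.protein_id} has no existence level")
        (hp_levels if p.protein_id in hp_ids else nonhp_levels).append(p.existence_level)
    cmp = ExistenceComparison(
        hp_counts=_level_counts(hp_levels), nonhp_counts=_level_counts(nonhp_levels)
    )
    for counts, pcts in (
        (cmp.hp_counts, cmp.hp_pct),
        (cmp.nonhp_counts, cmp.nonhp_pct),
    ):
        total = sum(counts.values())
        for lvl in EXISTENCE_LEVELS:
            pcts[lvl] = 100.0 * counts[lvl] / total if total else 0.0
    return cmp


def resample_nonhp(
    nonhp_levels: Sequence[int],
    sample_size: int,
    n_reps: int,
    rng: np.random.Generator | int,
) -> tuple[dict[int, float], dict[int, float]]:
    """Mean and SD of per-level counts over fixed-size resamples.

    Each replicate draws ``sample_size`` proteins from the non-HP cohort
    without replacement and counts per level.  Deterministic for a given
    generator/seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    levels = np.asarray(nonhp_levels)
    if sample_size > len(levels):
        raise ValueError(
            f"sample_size {sample_size} exceeds population {len(levels)}"
        )
    counts = np.zeros((n_reps, len(EXISTENCE_LEVELS)))
    for r in range(n_reps):
        sample = rng.choice(levels, size=sample_size, replace=False)
        for j, lvl in enumerate(EXISTENCE_LEVELS):
            counts[r, j] = int((sample == lvl).sum())
    means = {lvl: float(counts[:, j].mean()) for j, lvl in enumerate(EXISTENCE_LEVELS)}
    sds = {lvl: float(counts[:, j].std(ddof=0)) for j, lvl in enumerate(EXISTENCE_LEVELS)}
    return means, sds


def compare_distributions(
    hp_levels: Sequence[int], nonhp_levels: Sequence[int]
) -> tuple[float, float, float, float]:
    """Two-group Kruskal-Wallis (tie-corrected H) and one-way ANOVA F on
    the per-protein ordinal existence scores."""
    if len(hp_levels) < 2 or len(nonhp_levels) < 2:
        raise ValueError("each cohort needs at least 2 proteins for the tests")
    hp = np.asarray(hp_levels, float)
    nonhp = np.asarray(nonhp_levels, float)
    if np.array_equal(np.sort(hp), np.sort(nonhp)):
        # identical multisets: no group effect by construction
        h, hp_p = 0.0, 1.0
    else:
        h, hp_p = stats.kruskal(hp, nonhp)
    f, f_p = stats.f_oneway(hp, nonhp)
    return float(h), float(hp_p), float(f), float(f_p)


def full_comparison(
    proteins: Sequence[ProteinRecord],
    hp_ids: set[str],
    rep_counts: Sequence[int] = (5, 10, 100),
    seed: int = 0,
) -> ExistenceComparison:
    """Proportions + resampling (sample size = HP cohort) + both tests."""
    cmp = existence_proportions(proteins, hp_ids)
    hp_levels = [p.existence_level for p in proteins if p.protein_id in hp_ids]
    nonhp_levels = [p.existence_level for p in proteins if p.protein_id not in hp_ids]
    sample_size = min(len(hp_levels), len(nonhp_levels))
    rng = np.random.default_rng(seed)
    for n_reps in rep_counts:
        means, sds = resample_nonhp(nonhp_levels, sample_size, n_reps, rng)
        cmp.resample_mean[n_reps] = means
        cmp.resample_sd[n_reps] = sds
    if len(hp_levels) >= 2 and len(nonhp_levels) >= 2:
        cmp.kruskal_h, cmp.kruskal_p, cmp.anova_f, cmp.anova_p = compare_distributions(
            hp_levels, nonhp_levels
        )
    return cmp


def quality_correlations(
    metas: Iterable[ProteomeMeta],
    hp_set: HPSet,
    proteins: Iterable[ProteinRecord],
) -> pd.DataFrame:
    """Per-superkingdom Pearson r of BUSCO completeness vs HP count (one
    point per proteome) and vs HP length (one point per HP).

    Proteomes without a completeness value are excluded and counted;
    fewer than 3 points leaves r absent (NaN).
    """
    metas = list(metas)
    length_by_id = {p.protein_id: p.length for p in proteins}
    rows = []
    for sk in sorted({m.superkingdom for m in metas}):
        sk_metas = [m for m in metas if m.superkingdom == sk]
        with_busco = [m for m in sk_metas if m.busco_completeness is not None]
        n_excluded = len(sk_metas) - len(with_busco)

        x_count = [m.busco_completeness for m in with_busco]
        y_count = [hp_set.count(m.proteome_id) for m in with_busco]
        r_count = _pearson(x_count, y_count)

        x_len, y_len = [], []
        for m in with_busco:
            for hp_id in sorted(hp_set.hp_ids.get(m.proteome_id, ())):
                if hp_id in length_by_id:
                    x_len.append(m.busco_completeness)
                    y_len.append(length_by_id[hp_id])
        r_len = _pearson(x_len, y_len)
        rows.append(
            {
                "superkingdom": sk,
                "r_completeness_vs_hp_count": r_count,
                "n_proteomes": len(with_busco),
                "r_completeness_vs_hp_length": r_len,
                "n_hps": len(x_len),
                "n_excluded_no_busco": n_excluded,
            }
        )
    return pd.DataFrame(rows)


def _pearson(x: Sequence[float], y: Sequence[float]) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def assembly_level_summary(
    metas: Iterable[ProteomeMeta], hp_set: HPSet
) -> pd.DataFrame:
    """HP-count distribution (median, quartiles) per superkingdom and
    assembly level; empty groups are simply absent."""
    rows = [
        {
            "superkingdom": m.superkingdom,
            "assembly_level": m.assembly_level,
            "hp_count": hp_set.count(m.proteome_id),
        }
        for m in metas
    ]
    df = pd.DataFrame(rows, columns=["superkingdom", "assembly_level", "hp_count"])
    if df.empty:
        return pd.DataFrame(
            columns=["superkingdom", "assembly_level", "n_proteomes", "q1", "median", "q3"]
        )
    out = (
        df.groupby(["superkingdom", "assembly_level"])["hp_count"]
        .agg(
            n_proteomes="count",
            q1=lambda s: float(np.percentile(s, 25)),
            median="median",
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    return out
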