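"""HP extraction, proteome filtering and the per-phylum likelihood statistic.

A huge protein (HP) is any protein of length >= 5000 aa (threshold
inclusive and configurable).  The per-proteome *likelihood* of carrying
HPs is ``L = 100 * h / s`` with h the HP count and s the proteome size;
phyla are summarised by the median L over their proteomes.

Proteome filtering applies three rules in a fixed order:

1. drop every phylum represented by fewer than 5 proteomes;
2. within each surviving phylum, drop proteomes whose size is strictly
   smaller than ``mean(s) - sd(s)`` (sample SD, n-1 denominator),
   computed over the phylum before any size-based removal;
3. drop plasmid proteomes.

Rules 1 and 3 are idempotent subset operations; rule 2 is applied once
by contract (re-applying it would shift the cutoff and could cascade).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ProteinRecord, ProteomeMeta

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 5000
MIN_PROTEOMES_PER_PHYLUM = 5


@dataclass
class HPSet:
    """The HP ids of a collection, grouped by proteome."""

    min_length: int = DEFAULT_MIN_LENGTH
    hp_ids: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.hp_ids.values():
            out |= ids
        return out

    def count(self, proteome_id: str) -> int:
        return len(self.hp_ids.get(proteome_id, ()))


@dataclass
class PhylumLikelihoodSummary:
    """Distribution of the HP likelihood statistic within one phylum."""

    phylum: str
    superkingdom: str
    likelihood_pct: list[float]
    median_likelihood_pct: float


def extract_hps(
    proteins: Iterable[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> HPSet:
    """Classify proteins: HP iff length >= min_length (boundary inclusive)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    hp = HPSet(min_length=min_length)
    for p in proteins:
        if p.length >= min_length:
            hp.hp_ids.setdefault(p.proteome_id or "", set()).add(p.protein_id)
    return hp


def filter_proteomes(
    metas: Iterable[ProteomeMeta],
) -> tuple[list[ProteomeMeta], pd.DataFrame]:
    """Apply the three removal rules in order; returns (kept, removal log).

    The log has one row per dropped proteome with the rule that removed
    it ("phylum_lt_5", "size_below_mean_minus_sd", "plasmid").
    """
    metas = list(metas)
    log_rows: list[dict] = []

    # rule 1: phyla with < 5 proteomes
    by_phylum: dict[str, list[ProteomeMeta]] = {}
    for m in metas:
        by_phylum.setdefault(m.phylum, []).append(m)
    kept: list[ProteomeMeta] = []
    for m in metas:
        if len(by_phylum[m.phylum]) < MIN_PROTEOMES_PER_PHYLUM:
            log_rows.append({"proteome_id": m.proteome_id, "rule": "phylum_lt_5"})
        else:
            kept.append(m)

    # rule 2: size < mean - sd within phylum (stats computed pre-removal)
    cutoffs: dict[str, float] = {}
    for phylum in {m.phylum for m in kept}:
        sizes = np.array([m.proteome_size for m in kept if m.phylum == phylum], float)
        cutoffs[phylum] = float(sizes.mean() - sizes.std(ddof=1))
    survivors = []
    for m in kept:
        if m.proteome_size < cutoffs[m.phylum]:
            log_rows.append(
                {"proteome_id": m.proteome_id, "rule": "size_below_mean_minus_sd"}
            )
        else:
            survivors.append(m)

    # rule 3: plasmid proteomes
    final = []
    for m in survivors:
        if m.is_plasmid:
            log_rows.append({"proteome_id": m.proteome_id, "rule": "plasmid"})
        else:
            final.append(m)

    log = pd.DataFrame(log_rows, columns=["proteome_id", "rule"])
    return final, log


def phylum_likelihood(
    hp_set: HPSet, kept_metas: Iterable[ProteomeMeta]
) -> list[PhylumLikelihoodSummary]:
    """Per-phylum HP likelihoods, sorted by superkingdom then median desc.

    One ``L = 100 * h / s`` value per kept proteome; proteomes present in
    the HP set but absent from the kept metadata are excluded with a
    warning.
    """
    metas = list(kept_metas)
    known = {m.proteome_id for m in metas}
    for pid in hp_set.hp_ids:
        if pid not in known:
            logger.warning("proteome %s has HPs but is not in kept metadata", pid)

    groups: dict[tuple[str, str], list[float]] = {}
    for m in metas:
        L = 100.0 * hp_set.count(m.proteome_id) / m.proteome_size
        groups.setdefault((m.superkingdom, m.phylum), []).append(L)
    summaries = [
        PhylumLikelihoodSummary(
            phylum=phylum,
            superkingdom=sk,
            likelihood_pct=vals,
            median_likelihood_pct=float(np.median(vals)),
        )
        for (sk, phylum), vals in groups.items()
    ]
    summaries.sort(key=lambda s: (s.superkingdom, -s.median_likelihood_pct, s.phylum))
    return summaries


def proteome_size_vs_hp_table(
    hp_set: HPSet, kept_metas: Iterable[ProteomeMeta]
) -> pd.DataFrame:
    """Per-proteome (log10 size, HP count) table for the size scatter."""
    rows = [
        {
            "proteome_id": m.proteome_id,
            "superkingdom": m.superkingdom,
            "phylum": m.phylum,
            "log10_size": float(np.log10(m.proteome_size)),
            "hp_count": hp_set.count(m.proteome_id),
        }
        for m in kept_metas
    ]
    return pd.DataFrame(
        rows, columns=["proteome_id", "superkingdom", "phylum", "log10_size", "hp_count"]
    )


def likelihood_table(summaries: list[PhylumLikelihoodSummary]) -> pd.DataFrame:
    """Flatten summaries to a tidy per-phylum table (report shape)."""
    return pd.DataFrame(
        [
            {
                "superkingdom": s.superkingdom,
                "phylum": s.phylum,
                "n_proteomes": len(s.likelihood_pct),
                "median_likelihood_pct": s.median_likelihood_pct,
            }
            for s in summaries
        ],
        columns=["superkingdom", "phylum", "n_proteomes", "median_likelihood_pct"],
    )
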