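"""Pfam domain-architecture fingerprinting.

From raw hmmscan hits to canonical per-protein architectures:

1. keep hits with full-sequence E-value <= 0.001 AND domain i-Evalue
   <= 0.001;
2. resolve overlaps — two envelopes conflict when their overlap exceeds
   50% of the shorter one; conflicts are settled greedily in descending
   bitscore order (ties: smaller i-Evalue, then lexicographic
   accession);
3. the architecture is the surviving accessions (version suffix
   stripped) ordered by envelope start, joined with ``|``; consecutive
   repeats are NOT collapsed (repeat counts carry signal), though a
   collapsed view (runs -> ``ACC*``) is also available for reporting;
4. identical patterns form architecture groups, each assigned a stable
   6-character base-36 code derived from a SHA-256 of the pattern
   (collisions re-hashed with a counter until unique).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import DomainHitRaw, ProteomeMeta

DEFAULT_SEQ_EVALUE = 0.001
DEFAULT_DOM_EVALUE = 0.001
#: two envelopes conflict when overlap > this fraction of the shorter one
OVERLAP_TOLERANCE = 0.5


@dataclass
class Architecture:
    """Ordered domain content of one protein."""

    protein_id: str
    ordered_hits: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def pattern(self) -> str:
        return "|".join(acc for acc, _, _ in self.ordered_hits)

    @property
    def collapsed_pattern(self) -> str:
        """Runs of the same accession collapsed to ``ACC*``."""
        out: list[str] = []
        run_acc, run_len = None, 0
        for acc, _, _ in self.ordered_hits + [("", 0, 0)]:
            if acc == run_acc:
                run_len += 1
                continue
            if run_acc is not None:
                out.append(run_acc + "*" if run_len > 1 else run_acc)
            run_acc, run_len = acc, 1
        return "|".join(out)

    @property
    def accessions(self) -> set[str]:
        return {acc for acc, _, _ in self.ordered_hits}


def strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def filter_hits(
    raw_hits: Iterable[DomainHitRaw],
    seq_e: float = DEFAULT_SEQ_EVALUE,
    dom_e: float = DEFAULT_DOM_EVALUE,
) -> list[DomainHitRaw]:
    """Keep hits passing both E-value thresholds (monotone in either)."""
    return [h for h in raw_hits if h.seq_evalue <= seq_e and h.dom_ievalue <= dom_e]


def resolve_overlaps(
    hits: Sequence[DomainHitRaw], tolerance: float = OVERLAP_TOLERANCE
) -> list[DomainHitRaw]:
    """Greedy overlap resolution for the hits of one protein.

    Hits are admitted in descending bitscore (ties: smaller i-Evalue,
    then accession); a candidate conflicting with an already-admitted
    hit (overlap > ``tolerance`` of the shorter envelope) is dropped.
    ``tolerance=0`` reproduces strict non-overlap.  Result sorted by
    envelope start.
    """
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.dom_ievalue, h.pfam_accession))
    kept: list[DomainHitRaw] = []
    for cand in ranked:
        ok = True
        for other in kept:
            overlap = min(cand.env_to, other.env_to) - max(cand.env_from, other.env_from) + 1
            if overlap <= 0:
                continue
            shorter = min(
                cand.env_to - cand.env_from + 1, other.env_to - other.env_from + 1
            )
            if overlap > tolerance * shorter:
                ok = False
                break
        if ok:
            kept.append(cand)
    return sorted(kept, key=lambda h: (h.env_from, h.env_to, h.pfam_accession))


def deduce_architecture(
    protein_id: str, resolved_hits: Sequence[DomainHitRaw]
) -> Architecture:
    """Canonical architecture: accessions (version stripped) by envelope
    start; consecutive repeats preserved."""
    ordered = sorted(resolved_hits, key=lambda h: (h.env_from, h.env_to, h.pfam_accession))
    return Architecture(
        protein_id=protein_id,
        ordered_hits=[
            (strip_version(h.pfam_accession), h.env_from, h.env_to) for h in ordered
        ],
    )


def architectures_from_hits(
    raw_hits: Iterable[DomainHitRaw],
    protein_ids: Iterable[str] | None = None,
    seq_e: float = DEFAULT_SEQ_EVALUE,
    dom_e: float = DEFAULT_DOM_EVALUE,
) -> dict[str, Architecture]:
    """Full per-protein pipeline: filter -> resolve -> deduce.

    ``protein_ids``, when given, guarantees an (empty) architecture for
    proteins with no surviving hit — the no-domain set.
    """
    by_protein: dict[str, list[DomainHitRaw]] = {}
    for h in filter_hits(raw_hits, seq_e, dom_e):
        by_protein.setdefault(h.protein_id, []).append(h)
    out = {
        pid: deduce_architecture(pid, resolve_overlaps(hits))
        for pid, hits in by_protein.items()
    }
    if protein_ids is not None:
        for pid in protein_ids:
            out.setdefault(pid, Architecture(protein_id=pid))
    return out


_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _hash_code(text: str) -> str:
    digest = int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:8], "big")
    chars = []
    for _ in range(6):
        digest, r = divmod(digest, 36)
        chars.append(_B36[r])
    return "".join(chars)


def group_architectures(
    architectures: Iterable[Architecture],
    hash_fn: Callable[[str], str] = _hash_code,
) -> dict[str, tuple[str, list[str]]]:
    """Group proteins by exact pattern equality.

    Returns ``pattern -> (6-character code, sorted protein ids)``.
    Codes come from a cryptographic hash of the pattern so they are
    stable across runs; truncation collisions are resolved by
    re-hashing with an appended counter.  Proteins with an empty
    pattern (no domains) are excluded — they form the no-domain set.
    """
    members: dict[str, list[str]] = {}
    for arch in architectures:
        if arch.pattern:
            members.setdefault(arch.pattern, []).append(arch.protein_id)
    code_of: dict[str, str] = {}
    taken: dict[str, str] = {}
    for pattern in sorted(members):
        code = hash_fn(pattern)
        bump = 0
        while code in taken and taken[code] != pattern:
            bump += 1
            code = hash_fn(f"{pattern}#{bump}")
        taken[code] = pattern
        code_of[pattern] = code
    return {p: (code_of[p], sorted(ids)) for p, ids in members.items()}


def no_domain_ids(architectures: Iterable[Architecture]) -> set[str]:
    return {a.protein_id for a in architectures if not a.pattern}


def domain_distribution(
    architectures: Iterable[Architecture],
    records_proteome: dict[str, str],
    metas: Iterable[ProteomeMeta],
    max_proteomes_per_phylum: int = 50,
    top_phyla: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-domain, per-phylum counts on a phylum-balanced subsample.

    Each phylum is deterministically subsampled to at most
    ``max_proteomes_per_phylum`` proteomes (so large phyla do not skew
    the picture) and only the ``top_phyla`` per superkingdom by total
    contribution are retained.  Emits both presence counts (a protein
    counts once per domain) and occurrence counts (every copy counts).
    """
    rng = np.random.default_rng(seed)
    meta_of = {m.proteome_id: m for m in metas}
    by_phylum: dict[str, list[str]] = {}
    for m in meta_of.values():
        by_phylum.setdefault(m.phylum, []).append(m.proteome_id)
    chosen: set[str] = set()
    for phylum in sorted(by_phylum):
        ids = sorted(by_phylum[phylum])
        if len(ids) > max_proteomes_per_phylum:
            picked = rng.choice(ids, size=max_proteomes_per_phylum, replace=False)
            chosen.update(str(p) for p in picked)
        else:
            chosen.update(ids)

    tallies: dict[tuple[str, str, str], list[int]] = {}
    for arch in architectures:
        proteome = records_proteome.get(arch.protein_id)
        meta = meta_of.get(proteome or "")
        if meta is None or meta.proteome_id not in chosen:
            continue
        occurrences: dict[str, int] = {}
        for acc, _, _ in arch.ordered_hits:
            occurrences[acc] = occurrences.get(acc, 0) + 1
        for acc, n in occurrences.items():
            key = (meta.superkingdom, meta.phylum, acc)
            entry = tallies.setdefault(key, [0, 0])
            entry[0] += 1  # presence
            entry[1] += n  # occurrences

    df = pd.DataFrame(
        [
            {
                "superkingdom": sk,
                "phylum": phylum,
                "pfam_accession": acc,
                "n_proteins": pres,
                "n_occurrences": occ,
            }
            for (sk, phylum, acc), (pres, occ) in tallies.items()
        ],
        columns=["superkingdom", "phylum", "pfam_accession", "n_proteins", "n_occurrences"],
    )
    if df.empty:
        return df
    phylum_totals = (
        df.groupby(["superkingdom", "phylum"])["n_proteins"].sum().reset_index()
    )
    keep_phyla = set()
    for sk, grp in phylum_totals.groupby("superkingdom"):
        top = grp.sort_values(["n_proteins", "phylum"], ascending=[False, True]).head(
            top_phyla
        )
        keep_phyla.update((sk, p) for p in top["phylum"])
    mask = df.apply(lambda r: (r["superkingdom"], r["phylum"]) in keep_phyla, axis=1)
    return df[mask].sort_values(
        ["superkingdom", "phylum", "pfam_accession"], ignore_index=True
    )


def repeat_census(
    architectures: Iterable[Architecture], pfam_types: dict[str, str]
) -> int:
    """Number of proteins carrying >= 1 repeat-class domain.

    ``pfam_types`` maps every accession appearing in the architectures
    to its Pfam type string; unmapped accessions are an error.
    Presence-based: a protein with thirty copies counts once.
    """
    archs = list(architectures)
    unmapped = sorted(
        {acc for a in archs for acc in a.accessions if acc not in pfam_types}
    )
    if unmapped:
        raise KeyError(f"accessions missing from the Pfam type mapping: {unmapped}")
    return sum(
        1
        for a in archs
        if any(pfam_types[acc] == "Repeat" for acc in a.accessions)
    )
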