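"""Non-domain feature aggregation, artifact flagging and GO roll-up.

Per-residue disorder scores collapse to a percentage (residues with
score >= 0.5 — the IUPred-style convention); signal peptides and TMH
counts are consumed as annotations.  Suspicious HPs are flagged when
they have no domain, no homologue in the dataset and no functional
category, or near-total (>= 99%, and exactly 100%) predicted disorder.
GO terms are propagated along ``is_a`` to all ancestors before
counting, each protein counting once per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationRecord, Ontology, ProteinRecord

DISORDER_RESIDUE_THRESHOLD = 0.5

ARTIFACT_FLAGS = ("no_domain", "no_homology_no_cog", "disorder_ge_99", "disorder_eq_100")

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class FeatureProfile:
    """Aggregated features and artifact flags for one protein.

    ``unknown_flags`` lists flags whose inputs were absent (three-valued
    logic: set / unset / unknown).
    """

    protein_id: str
    disorder_pct: float | None = None
    has_signal_peptide: bool | None = None
    n_tmh: int | None = None
    artifact_flags: set[str] = field(default_factory=set)
    unknown_flags: set[str] = field(default_factory=set)


def disorder_percent(
    scores: Sequence[float], threshold: float = DISORDER_RESIDUE_THRESHOLD
) -> float:
    """Percentage of residues at or above the disorder score threshold."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty disorder score vector")
    return 100.0 * float((arr >= threshold).sum()) / arr.size


def flag_artifacts(
    protein_id: str,
    pattern: str | None,
    cluster_size: int | None,
    cog_assigned: bool | None,
    disorder_pct: float | None,
) -> FeatureProfile:
    """Evaluate the artifact flags for one protein.

    * ``no_domain`` — the architecture pattern is empty;
    * ``no_homology_no_cog`` — singleton cluster AND no category label;
    * ``disorder_ge_99`` / ``disorder_eq_100`` — disorder thresholds
      (100% implies >= 99%).

    ``None`` inputs leave the corresponding flag unknown.
    """
    profile = FeatureProfile(protein_id=protein_id, disorder_pct=disorder_pct)
    if pattern is None:
        profile.unknown_flags.add("no_domain")
    elif pattern == "":
        profile.artifact_flags.add("no_domain")
    if cluster_size is None or cog_assigned is None:
        profile.unknown_flags.add("no_homology_no_cog")
    elif cluster_size == 1 and not cog_assigned:
        profile.artifact_flags.add("no_homology_no_cog")
    if disorder_pct is None:
        profile.unknown_flags.update({"disorder_ge_99", "disorder_eq_100"})
    else:
        if disorder_pct >= 99.0:
            profile.artifact_flags.add("disorder_ge_99")
        if disorder_pct == 100.0:
            profile.artifact_flags.add("disorder_eq_100")
    return profile


def profile_features(
    annotations: dict[str, AnnotationRecord],
    patterns: dict[str, str] | None = None,
    cluster_sizes: dict[str, int] | None = None,
    protein_ids: Iterable[str] | None = None,
) -> dict[str, FeatureProfile]:
    """Build feature profiles (disorder %, signal peptide, TMH, flags)
    for a set of proteins, joining architecture and clustering context
    when available."""
    ids = list(protein_ids) if protein_ids is not None else sorted(annotations)
    out: dict[str, FeatureProfile] = {}
    for pid in ids:
        ann = annotations.get(pid)
        pct = None
        if ann is not None and ann.disorder_scores:
            pct = disorder_percent(ann.disorder_scores)
        pattern = patterns.get(pid) if patterns is not None else None
        size = cluster_sizes.get(pid) if cluster_sizes is not None else None
        cog = (ann.functional_category is not None) if ann is not None else None
        profile = flag_artifacts(pid, pattern, size, cog, pct)
        if ann is not None:
            profile.has_signal_peptide = ann.has_signal_peptide
            profile.n_tmh = ann.n_tmh
        out[pid] = profile
    return out


def go_rollup(
    annotations: dict[str, AnnotationRecord],
    ontology: Ontology,
    namespace: str,
    superkingdom_of: dict[str, str] | None = None,
    slim: set[str] | None = None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Distinct-protein counts per GO term after ancestor propagation.

    Each protein's terms are propagated to every ``is_a`` ancestor; a
    protein counts once per term however many of its annotations roll
    up to it (counts are therefore monotone along ``is_a``).  Terms
    missing from the ontology are skipped with a warning.  The report
    restricts to ``slim`` when given, else the ``top_n`` by count.
    """
    import logging

    logger = logging.getLogger(__name__)
    if namespace not in GO_NAMESPACES:
        raise ValueError(f"namespace must be one of {GO_NAMESPACES}")
    counts: dict[tuple[str, str], set[str]] = {}
    for pid, ann in annotations.items():
        sk = (superkingdom_of or {}).get(pid, "all")
        propagated: set[str] = set()
        for term in ann.go_terms:
            if term not in ontology:
                logger.warning("GO term %s not in ontology; skipped", term)
                continue
            propagated |= ontology.ancestors(term)
        for term in propagated:
            if ontology.namespace(term) != namespace:
                continue
            if slim is not None and term not in slim:
                continue
            counts.setdefault((sk, term), set()).add(pid)
    df = pd.DataFrame(
        [
            {
                "superkingdom": sk,
                "go_id": term,
                "go_name": ontology.name(term),
                "n_proteins": len(pids),
            }
            for (sk, term), pids in counts.items()
        ],
        columns=["superkingdom", "go_id", "go_name", "n_proteins"],
    ).sort_values(
        ["superkingdom", "n_proteins", "go_id"],
        ascending=[True, False, True],
        ignore_index=True,
    )
    if top_n is not None and not df.empty:
        df = (
            df.groupby("superkingdom", group_keys=False)
            .head(top_n)
            .reset_index(drop=True)
        )
    return df


def feature_length_profile(
    profiles: dict[str, FeatureProfile],
    proteins: Sequence[ProteinRecord],
    hp_ids: set[str],
    sample_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Joined feature-vs-length table for HPs and an equal-size non-HP
    sample (without replacement, seeded); binning is left to plotting."""
    rng = np.random.default_rng(seed)
    hp = [p for p in proteins if p.protein_id in hp_ids]
    nonhp = sorted(
        (p for p in proteins if p.protein_id not in hp_ids),
        key=lambda p: p.protein_id,
    )
    size = sample_size if sample_size is not None else len(hp)
    if size > len(nonhp):
        raise ValueError(f"sample size {size} exceeds non-HP population {len(nonhp)}")
    sampled_idx = rng.choice(len(nonhp), size=size, replace=False) if size else []
    cohort = [(p, True) for p in hp] + [(nonhp[i], False) for i in sorted(sampled_idx)]
    rows = []
    for p, is_hp in cohort:
        prof = profiles.get(p.protein_id)
        rows.append(
            {
                "protein_id": p.protein_id,
                "length": p.length,
                "is_hp": is_hp,
                "disorder_pct": prof.disorder_pct if prof else None,
                "has_signal_peptide": prof.has_signal_peptide if prof else None,
                "n_tmh": prof.n_tmh if prof else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "length", "is_hp", "disorder_pct", "has_signal_peptide", "n_tmh"],
    )
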