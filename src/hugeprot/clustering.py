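"""Greedy set-cover clustering of HPs by local pairwise alignment.

Reproduces the semantics of identity/coverage clustering at the survey's
thresholds (minimal identity 0.3, bidirectional coverage 0.8) with a
native implementation:

* :func:`align_pair` — affine-gap Smith-Waterman (Gotoh) under BLOSUM62
  with gap open 11 / extend 1 (a gap of length k costs ``11 + k``).
  Identity is identical aligned columns over *all* alignment columns,
  gap columns included in the denominator; coverage of each sequence is
  the aligned envelope length over its full length.  Selenocysteine (U)
  and pyrrolysine (O) are scored as X.
* :func:`greedy_cluster` — deterministic greedy set cover: candidates
  ordered by length descending (ties by id ascending); the first
  unassigned sequence becomes a representative and captures every
  unassigned sequence meeting BOTH thresholds against it.

Traceback tie-breaks are fixed (diagonal > gap-in-target > gap-in-query;
gap extension preferred over re-opening; the maximal cell with smallest
row then column wins), so results are reproducible and comparable
against an independent dynamic-programming oracle to exact equality.

An optional diagonal band (width ``max(200, 0.1 * len)``) accelerates
the long, near-collinear comparisons typical of HP homologues; full
dynamic programming is the default for short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io_formats import AMINO_ALPHABET, ProteinRecord

_NEG = -1.0e30

_BLOSUM = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = str(_BLOSUM.alphabet)  # "ARNDCQEGHILKMFPSTWYVBZX*"
_SUB = np.asarray(_BLOSUM, dtype=np.float64)

_ENCODE = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(_MATRIX_ALPHABET):
    _ENCODE[ord(_ch)] = _i
# U/O are absent from BLOSUM62: score them as X
_ENCODE[ord("U")] = _MATRIX_ALPHABET.index("X")
_ENCODE[ord("O")] = _MATRIX_ALPHABET.index("X")


@dataclass(frozen=True)
class AlignParams:
    gap_open: float = 11.0
    gap_extend: float = 1.0
    band: int | None = None  # half-width of the diagonal band; None = full DP


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    identity: float
    coverage_query: float
    coverage_target: float
    score: float
    n_columns: int = 0
    n_identical: int = 0


def encode_sequence(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(seq) - AMINO_ALPHABET)
        raise ValueError(f"sequence contains unsupported characters {bad}")
    return codes


@njit(cache=False)
def _sw_fill(a, b, sub, go, ge, band):  # pragma: no cover - exercised via align_pair
    """Gotoh fill; returns (best score, best i, best j, Hp, Ep, Fp).

    Pointer codes: Hp 0=stop 1=diag 2=up(F) 3=left(E); Ep/Fp 0=open
    1=extend.  Cells outside the band are treated as minus infinity.
    """
    m = a.shape[0]
    n = b.shape[0]
    Hp = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Ep = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Fp = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Hprev = np.zeros(n + 1, dtype=np.float64)
    Hcur = np.zeros(n + 1, dtype=np.float64)
    Fprev = np.full(n + 1, _NEG, dtype=np.float64)
    Fcur = np.full(n + 1, _NEG, dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        if band > 0:
            center = int(round(i * n / m))
            lo = max(1, center - band)
            hi = min(n, center + band)
        else:
            lo = 1
            hi = n
        for j in range(0, n + 1):
            Hcur[j] = _NEG
            Fcur[j] = _NEG
        Hcur[lo - 1] = 0.0  # local alignment may start at the band edge
        e = _NEG
        for j in range(lo, hi + 1):
            e_open = Hcur[j - 1] - go
            e_ext = e - ge
            if e_ext >= e_open:
                e = e_ext
                Ep[i, j] = 1
            else:
                e = e_open
                Ep[i, j] = 0
            f_open = Hprev[j] - go
            f_ext = Fprev[j] - ge
            if f_ext >= f_open:
                f = f_ext
                Fp[i, j] = 1
            else:
                f = f_open
                Fp[i, j] = 0
            Fcur[j] = f
            diag = Hprev[j - 1] + sub[a[i - 1], b[j - 1]]
            h = diag
            ptr = 1
            if f > h:
                h = f
                ptr = 2
            if e > h:
                h = e
                ptr = 3
            if h <= 0.0:
                h = 0.0
                ptr = 0
            Hcur[j] = h
            Hp[i, j] = ptr
            if h > best:
                best = h
                bi = i
                bj = j
        for j in range(0, n + 1):
            Hprev[j] = Hcur[j]
            Fprev[j] = Fcur[j]
    return best, bi, bj, Hp, Ep, Fp


def _traceback(a, b, bi, bj, Hp, Ep, Fp):
    """Walk pointers from the best cell; returns
    (n_columns, n_identical, a_start, b_start) with 1-based starts."""
    i, j = bi, bj
    ncols = 0
    nident = 0
    state = 0  # 0=H, 1=E (gap in a / consumes b), 2=F (gap in b / consumes a)
    while True:
        if state == 0:
            p = Hp[i, j]
            if p == 0:
                break
            if p == 1:
                ncols += 1
                if a[i - 1] == b[j - 1]:
                    nident += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 2:  # vertical gap: consumes a[i-1]
            p = Fp[i, j]
            ncols += 1
            i -= 1
            state = 0 if p == 0 else 2
        else:  # horizontal gap: consumes b[j-1]
            p = Ep[i, j]
            ncols += 1
            j -= 1
            state = 0 if p == 0 else 1
    return ncols, nident, i + 1, j + 1


def align_pair(
    a: ProteinRecord | tuple[str, str],
    b: ProteinRecord | tuple[str, str],
    params: AlignParams = AlignParams(),
) -> AlignmentResult:
    """Local alignment of two sequences; symmetric in identity and score.

    Accepts :class:`ProteinRecord` or ``(id, sequence)`` pairs.  The gap
    model charges ``gap_open + gap_extend`` for the first gap column and
    ``gap_extend`` for each further column.
    """
    qid, qseq = (a.protein_id, a.sequence) if isinstance(a, ProteinRecord) else a
    tid, tseq = (b.protein_id, b.sequence) if isinstance(b, ProteinRecord) else b
    if not qseq or not tseq:
        raise ValueError("cannot align empty sequences")
    ca, cb = encode_sequence(qseq), encode_sequence(tseq)
    band = params.band if params.band is not None else 0
    go = params.gap_open + params.gap_extend
    score, bi, bj, Hp, Ep, Fp = _sw_fill(ca, cb, _SUB, go, params.gap_extend, band)
    if score <= 0.0:
        return AlignmentResult(qid, tid, 0.0, 0.0, 0.0, 0.0)
    ncols, nident, a_start, b_start = _traceback(ca, cb, bi, bj, Hp, Ep, Fp)
    return AlignmentResult(
        query_id=qid,
        target_id=tid,
        identity=nident / ncols if ncols else 0.0,
        coverage_query=(bi - a_start + 1) / len(qseq),
        coverage_target=(bj - b_start + 1) / len(tseq),
        score=float(score),
        n_columns=ncols,
        n_identical=nident,
    )


@dataclass
class Cluster:
    """One greedy cluster: representative plus all captured members."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    phylum_counts: dict[str, int] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    member_stats: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _auto_band(len_a: int, len_b: int) -> int | None:
    longest = max(len_a, len_b)
    if min(len_a, len_b) <= 2000:
        return None
    return max(200, int(0.1 * longest))


def greedy_cluster(
    hp_records: Sequence[ProteinRecord],
    min_identity: float = 0.3,
    min_coverage: float = 0.8,
    params: AlignParams = AlignParams(),
    band: str | int | None = "auto",
) -> list[Cluster]:
    """Deterministic greedy set-cover clustering at joint thresholds.

    Candidates are ordered by length descending, ties by id ascending;
    repeatedly the first unassigned sequence becomes a representative
    and every unassigned sequence with identity >= ``min_identity`` AND
    both coverages >= ``min_coverage`` against it joins its cluster.
    ``band="auto"`` switches to banded alignment for long pairs.
    """
    if not (0.0 < min_identity <= 1.0 and 0.0 < min_coverage <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    order = sorted(hp_records, key=lambda r: (-r.length, r.protein_id))
    unassigned = list(order)
    clusters: list[Cluster] = []
    while unassigned:
        rep = unassigned.pop(0)
        cluster = Cluster(representative_id=rep.protein_id, member_ids=[rep.protein_id])
        cluster.member_stats[rep.protein_id] = (1.0, 1.0, 1.0)
        remaining = []
        for cand in unassigned:
            if band == "auto":
                use_band = _auto_band(rep.length, cand.length)
            elif band is None:
                use_band = None
            else:
                use_band = int(band)
            p = AlignParams(params.gap_open, params.gap_extend, use_band)
            res = align_pair(rep, cand, p)
            if (
                res.identity >= min_identity
                and res.coverage_query >= min_coverage
                and res.coverage_target >= min_coverage
            ):
                cluster.member_ids.append(cand.protein_id)
                cluster.member_stats[cand.protein_id] = (
                    res.identity,
                    res.coverage_query,
                    res.coverage_target,
                )
            else:
                remaining.append(cand)
        unassigned = remaining
        clusters.append(cluster)
    return clusters


def cluster_summary(
    clusters: Sequence[Cluster],
    records: Iterable[ProteinRecord],
    metas: Iterable,
    annotations: dict | None = None,
) -> dict:
    """Per-cluster composition and per-superkingdom functional tables.

    Fills each cluster's phylum and category tallies (proteins without a
    category count as "unassigned" and are excluded from the category
    rows), flags cross-superkingdom clusters, and builds the functional
    table: (superkingdom, category) protein counts sorted descending,
    multi-member clusters separated from singletons.
    """
    import pandas as pd

    proteome_of = {r.protein_id: r.proteome_id for r in records}
    meta_of = {m.proteome_id: m for m in metas}
    annotations = annotations or {}

    cluster_rows = []
    cat_tally: dict[tuple[str, str, str], int] = {}
    n_unassigned = 0
    for idx, cl in enumerate(clusters):
        cl.phylum_counts = {}
        cl.category_counts = {}
        sks = set()
        ctype = "multi" if cl.size >= 2 else "singleton"
        for pid in cl.member_ids:
            meta = meta_of.get(proteome_of.get(pid, ""), None)
            phylum = meta.phylum if meta else "unknown"
            sk = meta.superkingdom if meta else "unknown"
            sks.add(sk)
            cl.phylum_counts[phylum] = cl.phylum_counts.get(phylum, 0) + 1
            ann = annotations.get(pid)
            cat = ann.functional_category if ann is not None else None
            if cat is None:
                n_unassigned += 1
                cl.category_counts["unassigned"] = (
                    cl.category_counts.get("unassigned", 0) + 1
                )
            else:
                cl.category_counts[cat] = cl.category_counts.get(cat, 0) + 1
                cat_tally[(sk, cat, ctype)] = cat_tally.get((sk, cat, ctype), 0) + 1
        cluster_rows.append(
            {
                "cluster_id": f"C{idx:05d}",
                "representative": cl.representative_id,
                "size": cl.size,
                "phyla": ";".join(f"{k}:{v}" for k, v in sorted(cl.phylum_counts.items())),
                "superkingdoms": ";".join(sorted(sks)),
                "cross_superkingdom": len(sks) > 1,
            }
        )
    categories = pd.DataFrame(
        [
            {
                "superkingdom": sk,
                "functional_category": cat,
                "cluster_type": ctype,
                "n_proteins": n,
            }
            for (sk, cat, ctype), n in cat_tally.items()
        ],
        columns=["superkingdom", "functional_category", "cluster_type", "n_proteins"],
    ).sort_values(
        ["superkingdom", "n_proteins", "functional_category", "cluster_type"],
        ascending=[True, False, True, True],
        ignore_index=True,
    )
    return {
        "clusters": pd.DataFrame(cluster_rows),
        "categories": categories,
        "n_unassigned": n_unassigned,
    }


def membership_table(clusters: Sequence[Cluster]):
    """Tidy member-level table: cluster, representative, member, identity
    and coverages against the representative."""
    import pandas as pd

    rows = []
    for idx, cl in enumerate(clusters):
        for pid in cl.member_ids:
            ident, cov_q, cov_t = cl.member_stats.get(pid, (float("nan"),) * 3)
            rows.append(
                {
                    "cluster_id": f"C{idx:05d}",
                    "representative": cl.representative_id,
                    "member": pid,
                    "identity_to_rep": round(ident, 6),
                    "cov_rep": round(cov_q, 6),
                    "cov_member": round(cov_t, 6),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "representative",
            "member",
            "identity_to_rep",
            "cov_rep",
            "cov_member",
        ],
    )
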