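"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`ProteomeMeta`, :class:`DomainHitRaw` and
:class:`AnnotationRecord`.  Formats handled:

* multi-FASTA (headers ``proteome_id|protein_id`` or plain ids),
* HMMER3 ``--domtblout`` tables (read-only),
* OBO 1.2 ontology flat files (read-only, ``is_a`` edges only),
* package-defined TSV schemas for proteome metadata and per-protein
  annotations (see ``docs/formats.md``).

Coordinates are 1-based inclusive throughout, as in HMMER output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues plus ambiguity codes and the rare translated
#: residues selenocysteine (U) and pyrrolysine (O)
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO")

SUPERKINGDOMS = ("archaea", "bacteria", "eukaryota")

#: UniProt protein-existence tiers; level 5 ("Uncertain") is rejected on ingest
EXISTENCE_LEVELS = (1, 2, 3, 4)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    """One protein sequence with its proteome linkage and evidence tier."""

    protein_id: str
    sequence: str
    proteome_id: str | None = None
    existence_level: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().rstrip("*")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residue(s) {sorted(bad)}"
            )
        if self.existence_level is not None and self.existence_level not in EXISTENCE_LEVELS:
            raise ValueError(
                f"protein {self.protein_id}: existence level must be in 1-4, "
                f"got {self.existence_level}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeMeta:
    """Per-proteome taxonomy, size and quality metadata."""

    proteome_id: str
    taxid: int
    superkingdom: str
    phylum: str
    proteome_size: int
    assembly_level: str = "Unknown"
    busco_completeness: float | None = None
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        self.superkingdom = self.superkingdom.lower()
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"proteome {self.proteome_id}: unknown superkingdom "
                f"{self.superkingdom!r} (expected one of {SUPERKINGDOMS})"
            )
        if self.proteome_size < 1:
            raise ValueError(f"proteome {self.proteome_id}: proteome_size must be >= 1")
        if self.busco_completeness is not None and not (
            0.0 <= self.busco_completeness <= 100.0
        ):
            raise ValueError(
                f"proteome {self.proteome_id}: BUSCO completeness outside [0, 100]"
            )


@dataclass
class DomainHitRaw:
    """One unfiltered hmmscan domain hit with envelope coordinates."""

    protein_id: str
    pfam_accession: str
    domain_name: str
    seq_evalue: float
    dom_ievalue: float
    bitscore: float
    env_from: int
    env_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.env_from <= self.env_to):
            raise ValueError(
                f"hit {self.domain_name} on {self.protein_id}: envelope "
                f"{self.env_from}..{self.env_to} is not 1-based increasing"
            )


@dataclass
class AnnotationRecord:
    """Non-domain annotations for one protein.

    Absent fields stay ``None`` and are never imputed.  ``existence_level``
    rides along here because the annotation table is where evidence tiers
    are supplied; it is joined onto :class:`ProteinRecord` on ingest.
    """

    protein_id: str
    disorder_scores: list[float] | None = None
    has_signal_peptide: bool | None = None
    n_tmh: int | None = None
    go_terms: set[str] = field(default_factory=set)
    functional_category: str | None = None
    existence_level: int | None = None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _split_header(header: str) -> tuple[str | None, str]:
    """Split ``proteome|protein`` headers; plain ids have no proteome part."""
    if "|" in header:
        parts = header.split("|")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(f"malformed FASTA header {header!r}")
        return parts[0], parts[1]
    if not header:
        raise ParseError("empty FASTA header")
    return None, header


def read_fasta(
    path: str | Path, proteome_map: dict[str, str] | None = None
) -> Iterator[ProteinRecord]:
    """Stream :class:`ProteinRecord` objects from a FASTA file.

    Sequences are upper-cased and a terminal ``*`` stop is stripped.
    Empty-sequence entries are rejected with a warning; file order is
    preserved.  ``proteome_map`` resolves plain protein ids to proteomes
    when headers carry no ``proteome|`` prefix.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome_id, protein_id = _split_header(rec.id)
        seq = str(rec.seq)
        if not seq.rstrip("*"):
            logger.warning("skipping %s: empty sequence", protein_id)
            continue
        if proteome_id is None and proteome_map is not None:
            proteome_id = proteome_map.get(protein_id)
        yield ProteinRecord(protein_id=protein_id, sequence=seq, proteome_id=proteome_id)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> int:
    """Write records as wrapped FASTA (UTF-8, LF); returns record count."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = (
                f"{rec.proteome_id}|{rec.protein_id}" if rec.proteome_id else rec.protein_id
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path) -> Iterator[DomainHitRaw]:
    """Stream domain hits from an hmmscan ``--domtblout`` table.

    Column layout (1-based): 1 target name, 2 target accession, 4 query
    name, 7 full-sequence E-value, 13 i-Evalue, 14 domain score, 20-21
    envelope from/to.  Any HMMER3.x layout with >= 23 whitespace-separated
    columns is accepted; ``#`` lines are comments.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 23:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 23 columns, found {len(cols)}"
                )
            try:
                hit = DomainHitRaw(
                    protein_id=cols[3],
                    pfam_accession=cols[1],
                    domain_name=cols[0],
                    seq_evalue=float(cols[6]),
                    dom_ievalue=float(cols[12]),
                    bitscore=float(cols[13]),
                    env_from=int(cols[19]),
                    env_to=int(cols[20]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            yield hit


# ---------------------------------------------------------------------------
# metadata / annotation TSVs
# ---------------------------------------------------------------------------

_META_REQUIRED = ("proteome_id", "taxid", "superkingdom", "phylum", "proteome_size")


def read_metadata(path: str | Path) -> list[ProteomeMeta]:
    """Load the proteome metadata TSV; duplicate proteome ids are an error."""
    df = pd.read_csv(path, sep="\t", dtype={"proteome_id": str})
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")
    dupes = df["proteome_id"][df["proteome_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate proteome_id {sorted(set(dupes))}")
    metas = []
    for row in df.itertuples(index=False):
        busco = getattr(row, "busco_completeness", None)
        if busco is not None and (isinstance(busco, float) and math.isnan(busco)):
            busco = None
        metas.append(
            ProteomeMeta(
                proteome_id=row.proteome_id,
                taxid=int(row.taxid),
                superkingdom=str(row.superkingdom),
                phylum=str(row.phylum),
                proteome_size=int(row.proteome_size),
                assembly_level=str(getattr(row, "assembly_level", "Unknown")),
                busco_completeness=None if busco is None else float(busco),
                is_plasmid=_parse_bool(getattr(row, "is_plasmid", False)),
            )
        )
    return metas


def write_metadata(metas: Iterable[ProteomeMeta], path: str | Path) -> None:
    rows = [
        {
            "proteome_id": m.proteome_id,
            "taxid": m.taxid,
            "superkingdom": m.superkingdom,
            "phylum": m.phylum,
            "proteome_size": m.proteome_size,
            "assembly_level": m.assembly_level,
            "busco_completeness": m.busco_completeness,
            "is_plasmid": m.is_plasmid,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def read_annotations(
    path: str | Path, known_proteins: set[str] | dict[str, int] | None = None
) -> dict[str, AnnotationRecord]:
    """Load the per-protein annotation TSV into a protein_id keyed map.

    Disorder scores are a single comma-packed column of per-residue values
    in [0, 1].  Annotations for unknown proteins (when ``known_proteins``
    is given) are kept for a later join but logged as warnings; when
    ``known_proteins`` maps ids to lengths, a disorder vector whose
    length differs from the protein length is an error.  Records with
    existence level 5 ("Uncertain") are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise ParseError(f"{path}: missing mandatory column 'protein_id'")
    out: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if known_proteins is not None and pid not in known_proteins:
            logger.warning("annotation for unknown protein %s (kept)", pid)
        level = _opt_int(getattr(row, "existence_level", None))
        if level == 5:
            logger.warning("dropping protein %s: 'Uncertain' existence level", pid)
            continue
        scores_raw = getattr(row, "disorder_scores", None)
        scores = None
        if isinstance(scores_raw, str) and scores_raw:
            scores = [float(x) for x in scores_raw.split(",")]
            if any(not (0.0 <= s <= 1.0) for s in scores):
                raise ParseError(f"{path}: disorder score outside [0,1] for {pid}")
            if isinstance(known_proteins, dict) and pid in known_proteins:
                if len(scores) != known_proteins[pid]:
                    raise ParseError(
                        f"{path}: disorder vector length {len(scores)} != protein "
                        f"length {known_proteins[pid]} for {pid}"
                    )
        go_raw = getattr(row, "go_terms", None)
        go = set(go_raw.split(";")) if isinstance(go_raw, str) and go_raw else set()
        cat = getattr(row, "functional_category", None)
        out[pid] = AnnotationRecord(
            protein_id=pid,
            disorder_scores=scores,
            has_signal_peptide=_opt_bool(getattr(row, "has_signal_peptide", None)),
            n_tmh=_opt_int(getattr(row, "n_tmh", None)),
            go_terms=go,
            functional_category=None if _is_na(cat) else str(cat),
            existence_level=level,
        )
    return out


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "existence_level": r.existence_level,
                "disorder_scores": (
                    ",".join(f"{s:.3f}" for s in r.disorder_scores)
                    if r.disorder_scores is not None
                    else None
                ),
                "has_signal_peptide": r.has_signal_peptide,
                "n_tmh": r.n_tmh,
                "go_terms": ";".join(sorted(r.go_terms)) if r.go_terms else None,
                "functional_category": r.functional_category,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _opt_int(value) -> int | None:
    return None if _is_na(value) else int(value)


def _opt_bool(value) -> bool | None:
    return None if _is_na(value) else _parse_bool(value)


def attach_annotations(
    proteins: Iterable[ProteinRecord], annotations: dict[str, AnnotationRecord]
) -> list[ProteinRecord]:
    """Join existence levels from annotation records onto protein records."""
    out = []
    for p in proteins:
        ann = annotations.get(p.protein_id)
        if ann is not None and ann.existence_level is not None:
            p.existence_level = ann.existence_level
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------

class Ontology:
    """Directed acyclic ``is_a`` graph over ontology terms.

    Edges point child -> parent.  Obsolete terms are excluded at load.
    ``ancestors`` is the reflexive transitive closure, so every term has
    at least itself as an ancestor.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [u for u, _ in nx.find_cycle(graph)]
            raise ParseError(f"is_a cycle involving terms {cycle}")
        self.graph = graph

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """Reflexive transitive closure of ``is_a`` parents."""
        return {term} | nx.descendants(self.graph, term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))


def read_obo(path: str | Path) -> Ontology:
    """Load an OBO 1.2 file, keeping only ``is_a`` edges between live terms."""
    raw = obonet.read_obo(str(path))  # skips is_obsolete terms
    g = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        g.add_node(node, name=data.get("name"), namespace=data.get("namespace"))
    for child, parent, key in raw.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return Ontology(g)
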