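"""Synthetic proteome collections with known ground truth.

The generator emulates the statistical structure a huge-protein (HP,
length >= 5000 aa) survey assumes:

* bulk protein lengths are log-normal, capped below the HP threshold so
  the ground-truth HP set is exactly the planted set;
* each proteome receives a Poisson number of background HPs with mean
  ``hp_rate x proteome_size / 1000``;
* K homologous HP families of m members each are planted on top, derived
  from a common random ancestor by i.i.d. per-site substitution (no
  indels), with the substitution probability chosen so that the expected
  pairwise identity between two members hits a target;
* every HP carries a planted multi-domain architecture emitted as an
  HMMER3 domtblout table (true hits below the E-value thresholds, decoy
  hits above);
* per-protein annotations (existence level, per-residue disorder, signal
  peptide, TMH count, GO terms, functional category) follow configurable
  categorical distributions.

For two family members mutated independently from the ancestor with
per-site probability p (uniform replacement over the 19 alternatives),
the expected column identity is ``(1-p)^2 + p^2/19``; the generator
inverts this closed form.

All randomness flows from one root seed; per-stream generators are
derived with fixed ``SeedSequence`` spawn keys so adding a stream never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AnnotationRecord,
    ProteinRecord,
    ProteomeMeta,
    write_annotations,
    write_fasta,
    write_metadata,
)

_AA20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: spawn keys for the independent random substreams
_STREAMS = {"layout": 0, "bulk": 1, "families": 2, "annotations": 3, "domtblout": 4}

DEFAULT_ARCHITECTURE_LIBRARY: list[list[str]] = [
    ["PF00001", "PF00002", "PF00001"],
    ["PF07690", "PF00083"],
    ["PF00400"] * 6,                                # WD40-like repeat block
    ["PF00069", "PF00400", "PF00400", "PF00400", "PF12345"],
    ["PF02463"],
]

#: Pfam type labels for the default library (repeat census input)
DEFAULT_PFAM_TYPES: dict[str, str] = {
    "PF00001": "Family",
    "PF00002": "Family",
    "PF00083": "Family",
    "PF00069": "Domain",
    "PF00400": "Repeat",
    "PF02463": "Domain",
    "PF07690": "Family",
    "PF12345": "Domain",
}

_ASSEMBLY_LEVELS = ("Complete genome", "Chromosome", "Scaffold", "Contig")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic proteome collection.

    Defaults describe a desk-scale collection spanning the three
    superkingdoms, with HP rates per 1000 proteins spanning the range
    seen across phyla (near zero in archaea up to ~4 in the most
    HP-prone eukaryotic phyla).
    """

    n_proteomes: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("eukaryota", "Apicomplexa"): 6,
            ("eukaryota", "Chordata"): 6,
            ("bacteria", "Planctomycetota"): 6,
            ("bacteria", "Pseudomonadota"): 6,
            ("archaea", "Euryarchaeota"): 6,
        }
    )
    proteome_size_range: tuple[int, int] = (150, 300)
    length_lognormal_mu: float = 5.8
    length_lognormal_sigma: float = 0.9
    hp_rate: dict[str, float] = field(
        default_factory=lambda: {
            "Apicomplexa": 4.0,
            "Chordata": 0.4,
            "Planctomycetota": 0.8,
            "Pseudomonadota": 0.1,
            "Euryarchaeota": 0.05,
        }
    )
    n_hp_families: int = 5
    family_size: int = 6
    within_family_target_identity: float = 0.6
    hp_length_range: tuple[int, int] = (5000, 6000)
    architecture_library: list[list[str]] = field(
        default_factory=lambda: [list(a) for a in DEFAULT_ARCHITECTURE_LIBRARY]
    )
    seed: int = 0
    # annotation distributions
    hp_existence_probs: tuple[float, ...] = (0.008, 0.0006, 0.2214, 0.7700)
    nonhp_existence_probs: tuple[float, ...] = (0.003, 0.01, 0.40, 0.587)
    family_category_probs: dict[str, float] = field(
        default_factory=lambda: {"Q": 0.5, "M": 0.3, "T": 0.2}
    )
    mean_disorder_pct: float = 15.0
    n_disorder_ge99: int = 3
    n_disorder_eq100: int = 2
    signal_peptide_prob: float = 0.1
    tmh_mean: float = 0.5
    go_pool: tuple[str, ...] = tuple(f"GO:000000{i}" for i in range(1, 10))
    plasmid_prob: float = 0.05
    decoy_prob: float = 0.5
    min_bulk_length: int = 50

    def __post_init__(self) -> None:
        if self.hp_length_range[0] < 5000:
            raise ValueError("hp_length_range lower bound must be >= 5000")
        if not (0.0 < self.within_family_target_identity <= 1.0):
            raise ValueError("within_family_target_identity must be in (0, 1]")
        if any(r < 0 for r in self.hp_rate.values()):
            raise ValueError("hp_rate values must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    hp_ids_per_family: dict[int, set[str]] = field(default_factory=dict)
    architecture_per_hp: dict[str, list[str]] = field(default_factory=dict)
    category_per_hp: dict[str, str] = field(default_factory=dict)
    disorder_pct_per_hp: dict[str, float] = field(default_factory=dict)
    hp_proteome: dict[str, str] = field(default_factory=dict)
    background_hp_ids: set[str] = field(default_factory=set)

    @property
    def all_hp_ids(self) -> set[str]:
        ids = set(self.background_hp_ids)
        for members in self.hp_ids_per_family.values():
            ids |= members
        return ids


def substitution_probability(target_identity: float) -> float:
    """Per-site substitution probability achieving an expected identity.

    Inverts ``I(p) = (1-p)^2 + p^2 / 19`` on [0, 1].
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target identity must be in (0, 1]")
    a = 20.0 / 19.0
    disc = 1.0 - a * (1.0 - target_identity)
    if disc < 0:
        raise ValueError(f"target identity {target_identity} unreachable")
    return (1.0 - math.sqrt(disc)) / a


def expected_pairwise_identity(p: float) -> float:
    """Expected column identity of two members at substitution rate p."""
    return (1.0 - p) ** 2 + p * p / 19.0


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA20[rng.integers(0, 20, size=length)]


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_hp_family(
    ancestor_length: int,
    m: int,
    target_identity: float,
    rng: np.random.Generator | int,
) -> list[str]:
    """Derive ``m`` sequences from a common random ancestor (no indels).

    Each member mutates every site independently with probability p
    (uniform replacement over the 19 other residues), where p is chosen
    so that the expected pairwise identity between two members equals
    ``target_identity``.
    """
    if m < 2:
        raise ValueError("family size must be >= 2")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = substitution_probability(target_identity)
    ancestor = _random_sequence(rng, ancestor_length)
    idx = np.searchsorted(np.sort(_AA20), ancestor)  # _AA20 is sorted already
    members = []
    for _ in range(m):
        member_idx = idx.copy()
        mask = rng.random(ancestor_length) < p
        shift = rng.integers(1, 20, size=int(mask.sum()))
        member_idx[mask] = (member_idx[mask] + shift) % 20
        members.append(_decode(_AA20[member_idx]))
    return members


def planted_clustering_scenario(
    seed: int,
    n_families: int = 5,
    family_size: int = 6,
    target_identity: float = 0.6,
    length_range: tuple[int, int] = (5000, 6000),
    n_singletons: int = 10,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """HP records for a clustering-recovery experiment with known labels.

    ``n_families`` planted families (one common ancestor each, no
    indels) plus unrelated random singletons; returns the records and a
    ground-truth label per protein id (families 0..K-1, singletons get
    unique labels >= 100).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    lo, hi = length_range
    for k in range(n_families):
        length = int(rng.integers(lo, hi + 1))
        for j, seq in enumerate(
            simulate_hp_family(length, family_size, target_identity, rng)
        ):
            pid = f"FAM{k:02d}_M{j:02d}"
            records.append(ProteinRecord(protein_id=pid, sequence=seq, proteome_id="PX"))
            labels[pid] = k
    for s in range(n_singletons):
        length = int(rng.integers(lo, hi + 1))
        pid = f"SING{s:02d}"
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=_decode(_random_sequence(rng, length)),
                proteome_id="PX",
            )
        )
        labels[pid] = 100 + s
    return records, labels


def simulate_proteomes(
    config: SimulationConfig,
) -> tuple[dict[str, list[ProteinRecord]], list[ProteomeMeta], GroundTruth]:
    """Generate a proteome collection and its ground truth (in memory).

    Bulk lengths are log-normal, capped at 4999 so that the planted HPs
    are exactly the proteins of length >= 5000.  Background HP counts
    per proteome are Poisson with mean ``hp_rate x size / 1000``; family
    members are planted on top of the Poisson background.
    """
    layout = _stream(config.seed, "layout")
    bulk = _stream(config.seed, "bulk")
    fam_rng = _stream(config.seed, "families")

    truth = GroundTruth()
    proteomes: dict[str, list[ProteinRecord]] = {}
    metas: list[ProteomeMeta] = []
    lo, hi = config.proteome_size_range
    hlo, hhi = config.hp_length_range

    taxid = 1000
    pidx = 0
    for (superkingdom, phylum), count in sorted(config.n_proteomes.items()):
        rate = config.hp_rate.get(phylum, 0.0)
        for _ in range(count):
            pidx += 1
            taxid += 1
            proteome_id = f"SYN{pidx:04d}"
            size = int(layout.integers(lo, hi + 1))
            n_bg_hp = min(int(layout.poisson(rate * size / 1000.0)), size)
            records: list[ProteinRecord] = []
            # bulk (non-HP) proteins
            lengths = bulk.lognormal(
                config.length_lognormal_mu, config.length_lognormal_sigma, size - n_bg_hp
            )
            lengths = np.clip(np.rint(lengths).astype(int), config.min_bulk_length, 4999)
            for j, ln in enumerate(lengths, start=1):
                records.append(
                    ProteinRecord(
                        protein_id=f"{proteome_id}_P{j:05d}",
                        sequence=_decode(_random_sequence(bulk, int(ln))),
                        proteome_id=proteome_id,
                    )
                )
            # background HPs
            for j in range(1, n_bg_hp + 1):
                hp_id = f"{proteome_id}_H{j:03d}"
                ln = int(layout.integers(hlo, hhi + 1))
                records.append(
                    ProteinRecord(
                        protein_id=hp_id,
                        sequence=_decode(_random_sequence(bulk, ln)),
                        proteome_id=proteome_id,
                    )
                )
                truth.background_hp_ids.add(hp_id)
                truth.hp_proteome[hp_id] = proteome_id
            proteomes[proteome_id] = records
            metas.append(
                ProteomeMeta(
                    proteome_id=proteome_id,
                    taxid=taxid,
                    superkingdom=superkingdom,
                    phylum=phylum,
                    proteome_size=size,
                    assembly_level=str(layout.choice(_ASSEMBLY_LEVELS)),
                    busco_completeness=float(np.clip(layout.normal(92.0, 6.0), 0, 100)),
                    is_plasmid=bool(layout.random() < config.plasmid_prob),
                )
            )

    # planted HP families, spread round-robin over proteomes
    proteome_ids = sorted(proteomes)
    if config.n_hp_families > 0 and proteome_ids:
        order = [proteome_ids[i] for i in layout.permutation(len(proteome_ids))]
        slot = 0
        for k in range(config.n_hp_families):
            length = int(fam_rng.integers(hlo, hhi + 1))
            members = simulate_hp_family(
                length, config.family_size, config.within_family_target_identity, fam_rng
            )
            ids = set()
            for j, seq in enumerate(members, start=1):
                home = order[slot % len(order)]
                slot += 1
                hp_id = f"HPF{k:02d}M{j:02d}"
                proteomes[home].append(
                    ProteinRecord(protein_id=hp_id, sequence=seq, proteome_id=home)
                )
                ids.add(hp_id)
                truth.hp_proteome[hp_id] = home
            truth.hp_ids_per_family[k] = ids
        # family members add to proteome sizes
        extra: dict[str, int] = {}
        for hp_id, home in truth.hp_proteome.items():
            if hp_id not in truth.background_hp_ids:
                extra[home] = extra.get(home, 0) + 1
        for i, m in enumerate(metas):
            if m.proteome_id in extra:
                metas[i] = replace(m, proteome_size=m.proteome_size + extra[m.proteome_id])

    _plant_architectures(config, proteomes, truth)
    return proteomes, metas, truth


def _plant_architectures(
    config: SimulationConfig,
    proteomes: dict[str, list[ProteinRecord]],
    truth: GroundTruth,
) -> None:
    """Assign one library architecture per HP (shared within a family)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS["layout"], 1))
    )
    lib = config.architecture_library
    if not lib:
        return
    for fam, ids in sorted(truth.hp_ids_per_family.items()):
        arch = lib[int(rng.integers(0, len(lib)))]
        for hp_id in sorted(ids):
            truth.architecture_per_hp[hp_id] = list(arch)
    for hp_id in sorted(truth.background_hp_ids):
        truth.architecture_per_hp[hp_id] = list(lib[int(rng.integers(0, len(lib)))])


def simulate_annotations(
    config: SimulationConfig,
    proteomes: dict[str, list[ProteinRecord]],
    truth: GroundTruth,
) -> list[AnnotationRecord]:
    """Draw per-protein annotations from the configured distributions.

    HP vs non-HP existence levels use separate categorical laws; family
    members receive COG-style category labels; a fixed number of HPs is
    planted with >= 99% (and exactly 100%) disorder to exercise the
    artifact flags.
    """
    rng = _stream(config.seed, "annotations")
    hp_ids = truth.all_hp_ids
    hp_probs = np.asarray(config.hp_existence_probs, dtype=float)
    hp_probs = hp_probs / hp_probs.sum()
    nonhp_probs = np.asarray(config.nonhp_existence_probs, dtype=float)
    nonhp_probs = nonhp_probs / nonhp_probs.sum()
    cats = sorted(config.family_category_probs)
    cat_probs = np.array([config.family_category_probs[c] for c in cats], dtype=float)
    cat_probs = cat_probs / cat_probs.sum()

    sorted_hp = sorted(hp_ids)
    n99 = min(config.n_disorder_ge99, len(sorted_hp))
    n100 = min(config.n_disorder_eq100, n99)
    flagged = list(rng.choice(sorted_hp, size=n99, replace=False)) if n99 else []
    exact100 = set(flagged[:n100])
    ge99_only = set(flagged[n100:])

    records: list[AnnotationRecord] = []
    for proteome_id in sorted(proteomes):
        for prot in proteomes[proteome_id]:
            is_hp = prot.protein_id in hp_ids
            probs = hp_probs if is_hp else nonhp_probs
            level = int(rng.choice([1, 2, 3, 4], p=probs))
            n = prot.length
            if prot.protein_id in exact100:
                n_dis = n
            elif prot.protein_id in ge99_only:
                n_dis = int(rng.integers(math.ceil(0.99 * n), n))  # >=99%, <100%
            else:
                pct = float(np.clip(rng.normal(config.mean_disorder_pct, 8.0), 0, 95))
                n_dis = int(round(pct / 100.0 * n))
            if is_hp:
                truth.disorder_pct_per_hp[prot.protein_id] = 100.0 * n_dis / n
            scores = np.empty(n)
            scores[:n_dis] = rng.uniform(0.5, 1.0, n_dis)
            # upper bound keeps values below 0.5 after 3-decimal rounding
            scores[n_dis:] = rng.uniform(0.0, 0.4994, n - n_dis)
            rng.shuffle(scores)
            category = None
            for fam, ids in truth.hp_ids_per_family.items():
                if prot.protein_id in ids:
                    category = cats[int(rng.choice(len(cats), p=cat_probs))]
                    truth.category_per_hp[prot.protein_id] = category
                    break
            n_go = int(rng.integers(0, 4))
            go = set(rng.choice(config.go_pool, size=n_go, replace=False)) if n_go else set()
            records.append(
                AnnotationRecord(
                    protein_id=prot.protein_id,
                    disorder_scores=[float(s) for s in np.round(scores, 3)],
                    has_signal_peptide=bool(rng.random() < config.signal_peptide_prob),
                    n_tmh=int(rng.poisson(config.tmh_mean)),
                    go_terms={str(g) for g in go},
                    functional_category=category,
                    existence_level=level,
                )
            )
    return records


def simulate_domtblout(
    truth: GroundTruth,
    protein_lengths: dict[str, int],
    path: str | Path,
    seed: int,
    decoy_prob: float = 0.5,
) -> int:
    """Write an hmmscan-style domtblout for the planted architectures.

    True hits get E-values well below the 0.001 thresholds and envelope
    coordinates laid out in architecture order with >= 5 residue gaps;
    decoys (probability ``decoy_prob`` per protein) get a domain
    i-Evalue above 0.001 so downstream filtering removes them.  Returns
    the number of data lines written.
    """
    rng = _stream(seed, "domtblout")
    lines = []
    for hp_id in sorted(truth.architecture_per_hp):
        arch = truth.architecture_per_hp[hp_id]
        qlen = protein_lengths[hp_id]
        spans = _layout_domains(rng, arch, qlen)
        for i, (acc, (start, end)) in enumerate(zip(arch, spans), start=1):
            seq_e = 10.0 ** rng.uniform(-30, -5)
            dom_e = 10.0 ** rng.uniform(-28, -4)
            score = float(rng.uniform(50, 500))
            lines.append(
                _domtbl_line(
                    target=f"{acc}_dom",
                    acc=f"{acc}.1",
                    tlen=end - start + 1,
                    query=hp_id,
                    qlen=qlen,
                    seq_e=seq_e,
                    dom_i=i,
                    dom_n=len(arch),
                    dom_e=dom_e,
                    score=score,
                    env=(start, end),
                )
            )
        if rng.random() < decoy_prob:
            start = int(rng.integers(1, max(2, qlen - 100)))
            end = min(qlen, start + int(rng.integers(30, 120)))
            lines.append(
                _domtbl_line(
                    target="PF09999_decoy",
                    acc="PF09999.1",
                    tlen=end - start + 1,
                    query=hp_id,
                    qlen=qlen,
                    seq_e=10.0 ** rng.uniform(-20, -5),
                    dom_i=1,
                    dom_n=1,
                    dom_e=10.0 ** rng.uniform(-2, 1),  # always > 0.001
                    score=float(rng.uniform(5, 20)),
                    env=(start, end),
                )
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# hugeprot synthetic domtblout\n")
        fh.write("#" + "-" * 60 + "\n")
        fh.writelines(lines)
    return len(lines)


def _layout_domains(
    rng: np.random.Generator, arch: Sequence[str], qlen: int
) -> list[tuple[int, int]]:
    """Place domains left-to-right with >= 5 residue gaps; error if they
    cannot fit."""
    n = len(arch)
    dom_lens = [int(rng.integers(50, 151)) for _ in range(n)]
    needed = sum(dom_lens) + 5 * (n + 1)
    if needed > qlen:
        raise ValueError(
            f"architecture of {n} domains ({needed} aa incl. gaps) does not fit "
            f"protein of length {qlen}"
        )
    slack = qlen - needed
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) + 5
    spans = []
    pos = 0
    for ln, gap in zip(dom_lens, gaps[:-1]):
        start = pos + int(gap) + 1
        end = start + ln - 1
        spans.append((start, end))
        pos = end
    return spans


def _domtbl_line(
    *,
    target: str,
    acc: str,
    tlen: int,
    query: str,
    qlen: int,
    seq_e: float,
    dom_i: int,
    dom_n: int,
    dom_e: float,
    score: float,
    env: tuple[int, int],
) -> str:
    """One 23-column domtblout data line (hmmscan layout)."""
    c_e = dom_e / 10.0
    ali = env
    cols = [
        target, acc, str(tlen), query, "-", str(qlen),
        f"{seq_e:.1e}", f"{score:.1f}", "0.1",
        str(dom_i), str(dom_n),
        f"{c_e:.1e}", f"{dom_e:.1e}", f"{score:.1f}", "0.1",
        "1", str(tlen),
        str(ali[0]), str(ali[1]),
        str(env[0]), str(env[1]),
        "0.90", "synthetic planted hit",
    ]
    return " ".join(cols) + "\n"


DEMO_OBO = """format-version: 1.2
ontology: synthetic-go-mini

[Term]
id: GO:0000001
name: root molecular activity
namespace: molecular_function

[Term]
id: GO:0000002
name: binding-like activity
namespace: molecular_function
is_a: GO:0000001 ! root molecular activity

[Term]
id: GO:0000003
name: catalytic-like activity
namespace: molecular_function
is_a: GO:0000001 ! root molecular activity

[Term]
id: GO:0000004
name: root biological process
namespace: biological_process

[Term]
id: GO:0000005
name: metabolic-like process
namespace: biological_process
is_a: GO:0000004 ! root biological process

[Term]
id: GO:0000006
name: biosynthetic-like process
namespace: biological_process
is_a: GO:0000005 ! metabolic-like process

[Term]
id: GO:0000007
name: root cellular component
namespace: cellular_component

[Term]
id: GO:0000008
name: membrane-like component
namespace: cellular_component
is_a: GO:0000007 ! root cellular component

[Term]
id: GO:0000009
name: cytoskeleton-like component
namespace: cellular_component
is_a: GO:0000007 ! root cellular component
"""


def write_demo_obo(path: str | Path) -> None:
    """Write the small synthetic GO-style mini ontology used by defaults."""
    Path(path).write_text(DEMO_OBO, encoding="utf-8")


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Run the full generator and write every io_formats schema to a
    directory: per-proteome FASTA, metadata TSV, annotation TSV,
    domtblout, mini ontology, and a ground-truth JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteomes, metas, truth = simulate_proteomes(config)
    annotations = simulate_annotations(config, proteomes, truth)

    all_records = [p for pid in sorted(proteomes) for p in proteomes[pid]]
    write_fasta(all_records, out / "proteins.fasta")
    write_metadata(metas, out / "metadata.tsv")
    write_annotations(annotations, out / "annotations.tsv")
    lengths = {p.protein_id: p.length for p in all_records}
    simulate_domtblout(
        truth, lengths, out / "hits.domtblout", config.seed, config.decoy_prob
    )
    write_demo_obo(out / "go_mini.obo")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "families": {
                    str(k): sorted(v) for k, v in truth.hp_ids_per_family.items()
                },
                "background_hp_ids": sorted(truth.background_hp_ids),
                "architecture_per_hp": {
                    k: truth.architecture_per_hp[k]
                    for k in sorted(truth.architecture_per_hp)
                },
                "category_per_hp": {
                    k: truth.category_per_hp[k] for k in sorted(truth.category_per_hp)
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return truth
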