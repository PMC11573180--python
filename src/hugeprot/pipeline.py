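"""One-command orchestration of the whole survey on a data directory.

``run_pipeline`` wires the stages in dependency order — HP extraction
and prevalence, existence statistics, greedy clustering, architecture
fingerprinting, feature/artifact profiling — reading the io_formats
schemas from one input directory and writing every stage table (TSV)
plus a manifest (config hash, seed, row counts) into a run directory.
Re-running with the same config and inputs is byte-identical: no
timestamps enter any output, and every random stream is seeded from the
one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import architecture as arch_mod
from . import clustering as clust_mod
from . import existence_stats as exist_mod
from . import features as feat_mod
from . import io_formats as io_mod
from . import prevalence as prev_mod
from .io_formats import EXISTENCE_LEVELS
from .synthetic_data import DEFAULT_PFAM_TYPES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths, thresholds and seeds of one pipeline run."""

    input_dir: str
    out_dir: str
    min_length: int = 5000
    min_identity: float = 0.3
    min_coverage: float = 0.8
    seq_evalue: float = 0.001
    dom_evalue: float = 0.001
    rep_counts: tuple[int, ...] = (5, 10, 100)
    max_proteomes_per_phylum: int = 50
    seed: int = 0
    fasta_name: str = "proteins.fasta"
    meta_name: str = "metadata.tsv"
    annotations_name: str = "annotations.tsv"
    domtblout_name: str = "hits.domtblout"
    obo_name: str = "go_mini.obo"
    with_architecture: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for name, v in (
            ("min_identity", self.min_identity),
            ("min_coverage", self.min_coverage),
        ):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.seq_evalue <= 0 or self.dom_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["rep_counts"] = list(self.rep_counts)
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "rep_counts" in data:
            data["rep_counts"] = tuple(data["rep_counts"])
        return cls(**data)

    def content_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis in two directories hashes identically)."""
        data = {**asdict(self), "rep_counts": list(self.rep_counts)}
        data.pop("input_dir")
        data.pop("out_dir")
        canon = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    ind = Path(config.input_dir)
    out = Path(config.out_dir)
    for required in (config.fasta_name, config.meta_name, config.annotations_name):
        if not (ind / required).exists():
            raise FileNotFoundError(f"missing input file: {ind / required}")
    if config.with_architecture and not (ind / config.domtblout_name).exists():
        raise FileNotFoundError(
            f"architecture stage enabled but {ind / config.domtblout_name} is missing"
        )
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    counts: dict[str, int] = {}

    # ingest
    proteins = list(io_mod.read_fasta(ind / config.fasta_name))
    metas = io_mod.read_metadata(ind / config.meta_name)
    annotations = io_mod.read_annotations(
        ind / config.annotations_name,
        known_proteins={p.protein_id: p.length for p in proteins},
    )
    proteins = io_mod.attach_annotations(proteins, annotations)
    counts["proteins"] = len(proteins)
    counts["proteomes"] = len(metas)

    # stage: extract + prevalence
    hp_set = prev_mod.extract_hps(proteins, config.min_length)
    counts["hps"] = len(hp_set.all_ids)
    kept, removal_log = prev_mod.filter_proteomes(metas)
    counts["proteomes_kept"] = len(kept)
    counts["removal_log"] = _write(removal_log, out / "removal_log.tsv")
    summaries = prev_mod.phylum_likelihood(hp_set, kept)
    counts["likelihood_phyla"] = _write(
        prev_mod.likelihood_table(summaries), out / "likelihood.tsv"
    )
    counts["size_vs_hp"] = _write(
        prev_mod.proteome_size_vs_hp_table(hp_set, kept), out / "size_vs_hp.tsv"
    )

    # stage: existence
    cmp = exist_mod.full_comparison(
        proteins, hp_set.all_ids, config.rep_counts, config.seed
    )
    counts["existence"] = _write(_existence_table(cmp), out / "existence.tsv")
    counts["quality_correlations"] = _write(
        exist_mod.quality_correlations(kept, hp_set, proteins),
        out / "quality_correlations.tsv",
    )
    counts["assembly_levels"] = _write(
        exist_mod.assembly_level_summary(kept, hp_set), out / "assembly_levels.tsv"
    )

    # stage: clustering
    hp_records = [p for p in proteins if p.protein_id in hp_set.all_ids]
    clusters = clust_mod.greedy_cluster(
        hp_records, config.min_identity, config.min_coverage
    )
    counts["clusters"] = len(clusters)
    counts["clusters_multi"] = sum(1 for c in clusters if c.size >= 2)
    counts["cluster_members"] = _write(
        clust_mod.membership_table(clusters), out / "clusters.tsv"
    )
    summary = clust_mod.cluster_summary(clusters, hp_records, kept, annotations)
    _write(summary["clusters"], out / "cluster_composition.tsv")
    _write(summary["categories"], out / "cluster_categories.tsv")

    # stage: architecture
    if config.with_architecture:
        raw_hits = list(io_mod.read_domtblout(ind / config.domtblout_name))
        archs = arch_mod.architectures_from_hits(
            raw_hits,
            protein_ids=sorted(hp_set.all_ids),
            seq_e=config.seq_evalue,
            dom_e=config.dom_evalue,
        )
        groups = arch_mod.group_architectures(archs.values())
        counts["architecture_groups"] = len(groups)
        counts["no_domain_proteins"] = len(arch_mod.no_domain_ids(archs.values()))
        _write(_architecture_table(archs), out / "architectures.tsv")
        _write(_group_table(groups), out / "architecture_groups.tsv")
        proteome_of = {p.protein_id: p.proteome_id or "" for p in proteins}
        counts["domain_distribution"] = _write(
            arch_mod.domain_distribution(
                archs.values(),
                proteome_of,
                kept,
                config.max_proteomes_per_phylum,
                seed=config.seed,
            ),
            out / "domain_distribution.tsv",
        )
        try:
            counts["repeat_proteins"] = arch_mod.repeat_census(
                archs.values(), DEFAULT_PFAM_TYPES
            )
        except KeyError:
            logger.warning("repeat census skipped: accessions without a type mapping")
        patterns = {pid: a.pattern for pid, a in archs.items()}
    else:
        patterns = None

    # stage: features
    cluster_sizes = {
        pid: c.size for c in clusters for pid in c.member_ids
    }
    profiles = feat_mod.profile_features(
        annotations,
        patterns=patterns,
        cluster_sizes=cluster_sizes,
        protein_ids=sorted(hp_set.all_ids),
    )
    counts["feature_profiles"] = _write(_profile_table(profiles), out / "features.tsv")
    counts["artifacts"] = sum(1 for p in profiles.values() if p.artifact_flags)
    obo_path = ind / config.obo_name
    if obo_path.exists():
        ontology = io_mod.read_obo(obo_path)
        sk_of_proteome = {m.proteome_id: m.superkingdom for m in metas}
        sk_of = {
            p.protein_id: sk_of_proteome.get(p.proteome_id or "", "unknown")
            for p in proteins
        }
        hp_ann = {pid: annotations[pid] for pid in sorted(hp_set.all_ids) if pid in annotations}
        go_frames = [
            feat_mod.go_rollup(hp_ann, ontology, ns, superkingdom_of=sk_of)
            for ns in feat_mod.GO_NAMESPACES
        ]
        for frame, ns in zip(go_frames, feat_mod.GO_NAMESPACES):
            frame.insert(0, "namespace", ns)
        counts["go_rollup"] = _write(
            pd.concat(go_frames, ignore_index=True), out / "go_rollup.tsv"
        )
    counts["feature_length_profile"] = _write(
        feat_mod.feature_length_profile(
            feat_mod.profile_features(annotations),
            proteins,
            hp_set.all_ids,
            seed=config.seed,
        ),
        out / "feature_length_profile.tsv",
    )

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "row_counts": dict(sorted(counts.items())),
        "stages": [
            "extract",
            "prevalence",
            "existence",
            "cluster",
            "architect" if config.with_architecture else None,
            "features",
        ],
    }
    manifest["stages"] = [s for s in manifest["stages"] if s]
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _existence_table(cmp: exist_mod.ExistenceComparison) -> pd.DataFrame:
    rows = []
    for lvl in EXISTENCE_LEVELS:
        row = {
            "existence_level": lvl,
            "hp_count": cmp.hp_counts.get(lvl, 0),
            "hp_pct": round(cmp.hp_pct.get(lvl, 0.0), 6),
            "nonhp_count": cmp.nonhp_counts.get(lvl, 0),
            "nonhp_pct": round(cmp.nonhp_pct.get(lvl, 0.0), 6),
        }
        for n_reps in sorted(cmp.resample_mean):
            row[f"resample_mean_{n_reps}"] = round(cmp.resample_mean[n_reps][lvl], 6)
            row[f"resample_sd_{n_reps}"] = round(cmp.resample_sd[n_reps][lvl], 6)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["kruskal_h"] = cmp.kruskal_h
    df["kruskal_p"] = cmp.kruskal_p
    df["anova_f"] = cmp.anova_f
    df["anova_p"] = cmp.anova_p
    return df


def _architecture_table(archs: dict[str, arch_mod.Architecture]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": pid,
                "pattern": a.pattern,
                "collapsed_pattern": a.collapsed_pattern,
                "n_domains": len(a.ordered_hits),
                "envelopes": ";".join(f"{acc}:{s}-{e}" for acc, s, e in a.ordered_hits),
            }
            for pid, a in sorted(archs.items())
        ],
        columns=["protein_id", "pattern", "collapsed_pattern", "n_domains", "envelopes"],
    )


def _group_table(groups: dict[str, tuple[str, list[str]]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group_code": code, "pattern": pattern, "n_proteins": len(ids)}
            for pattern, (code, ids) in sorted(groups.items())
        ],
        columns=["group_code", "pattern", "n_proteins"],
    )


def _profile_table(profiles: dict[str, feat_mod.FeatureProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": pid,
                "disorder_pct": None if p.disorder_pct is None else round(p.disorder_pct, 6),
                "has_signal_peptide": p.has_signal_peptide,
                "n_tmh": p.n_tmh,
                "artifact_flags": ";".join(sorted(p.artifact_flags)),
                "unknown_flags": ";".join(sorted(p.unknown_flags)),
            }
            for pid, p in sorted(profiles.items())
        ],
        columns=[
            "protein_id",
            "disorder_pct",
            "has_signal_peptide",
            "n_tmh",
            "artifact_flags",
            "unknown_flags",
        ],
    )


def render_report(run_dir: str | Path, plots: bool = False) -> Path:
    """Summary tables (and optional plots) from a completed run.

    Deterministic and idempotent; a plotting failure never alters the
    tables.
    """
    run = Path(run_dir)
    report = run / "report"
    report.mkdir(exist_ok=True)
    mapping = {
        "size_vs_hp.tsv": "fig_size_vs_hp_count.tsv",
        "likelihood.tsv": "fig_phylum_likelihood.tsv",
        "existence.tsv": "fig_existence_levels.tsv",
        "assembly_levels.tsv": "fig_assembly_levels.tsv",
        "cluster_categories.tsv": "table_functional_categories.tsv",
        "domain_distribution.tsv": "fig_domain_distribution.tsv",
    }
    for src, dst in mapping.items():
        src_path = run / src
        if src_path.exists():
            df = pd.read_csv(src_path, sep="\t")
        else:
            df = pd.DataFrame()
        df.to_csv(report / dst, sep="\t", index=False, lineterminator="\n")
    if plots:
        try:
            _render_plots(run, report)
        except Exception as exc:  # plots are best-effort by contract
            logger.warning("plot rendering failed: %s", exc)
    return report


def _render_plots(run: Path, report: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lik = pd.read_csv(run / "likelihood.tsv", sep="\t")
    if not lik.empty:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(lik["phylum"], lik["median_likelihood_pct"])
        ax.set_ylabel("median HP likelihood (%)")
        ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(report / "phylum_likelihood.png", dpi=120)
        plt.close(fig)
    scatter = pd.read_csv(run / "size_vs_hp.tsv", sep="\t")
    if not scatter.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(scatter["log10_size"], scatter["hp_count"], s=12)
        ax.set_xlabel("log10 proteome size")
        ax.set_ylabel("HP count")
        fig.tight_layout()
        fig.savefig(report / "size_vs_hp.png", dpi=120)
        plt.close(fig)
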