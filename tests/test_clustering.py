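import numpy as np
import pytest

from hugeprot.clustering import (
    AlignParams,
    align_pair,
    cluster_summary,
    greedy_cluster,
    membership_table,
)
from hugeprot.io_formats import ProteinRecord
from hugeprot.synthetic_data import simulate_hp_family

from .conftest import make_meta, random_protein_seq
from .sw_oracle import sw_align


class TestAlignPair:
    def test_self_alignment(self):
        seq = "MKVLAAGGTREWEMKDEFGHIKLMNPQRSTVWY"
        r = align_pair(("a", seq), ("b", seq))
        assert r.identity == 1.0
        assert r.coverage_query == 1.0 and r.coverage_target == 1.0

    def test_prefix_half_coverage(self):
        b = "MKVLAAGGTREWEMKDEFGHIKLMNPQRSTVW"
        a = b[: len(b) // 2]
        r = align_pair(("a", a), ("b", b))
        assert r.identity == 1.0
        assert r.coverage_query == 1.0
        assert r.coverage_target == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = random_protein_seq(rng, 80), random_protein_seq(rng, 60)
        r1 = align_pair(("a", a), ("b", b))
        r2 = align_pair(("b", b), ("a", a))
        assert r1.score == r2.score and r1.identity == r2.identity
        assert (r1.coverage_query, r1.coverage_target) == (
            r2.coverage_target,
            r2.coverage_query,
        )

    def test_empty_or_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair(("a", ""), ("b", "MKV"))
        with pytest.raises(ValueError):
            align_pair(("a", "MK1"), ("b", "MKV"))

    def test_matches_independent_sw_oracle_on_random_pairs(self):
        """Exact score/identity equality against the textbook DP oracle
        on 50 random short pairs."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            a = random_protein_seq(rng, int(rng.integers(10, 61)))
            b = random_protein_seq(rng, int(rng.integers(10, 61)))
            got = align_pair(("a", a), ("b", b))
            score, ncols, nident, a_span, b_span = sw_align(a, b)
            assert got.score == score
            if ncols:
                assert got.n_columns == ncols and got.n_identical == nident
                assert got.identity == nident / ncols
                assert got.coverage_query == (a_span[1] - a_span[0] + 1) / len(a)
                assert got.coverage_target == (b_span[1] - b_span[0] + 1) / len(b)

    def test_banded_equals_full_on_near_diagonal_pair(self):
        m1, m2 = simulate_hp_family(3000, 2, 0.7, rng=9)
        full = align_pair(("a", m1), ("b", m2), AlignParams())
        banded = align_pair(("a", m1), ("b", m2), AlignParams(band=300))
        assert banded.score == full.score and banded.identity == full.identity

    def test_rare_residues_scored_as_x(self):
        r = align_pair(("a", "MKVUUU"), ("b", "MKVOOO"))
        # U and O both map to X, so the tail is identical by convention
        assert r.identity == pytest.approx(1.0)


def _records(seqs, prefix="S"):
    return [
        ProteinRecord(protein_id=f"{prefix}{i:03d}", sequence=s, proteome_id="PX")
        for i, s in enumerate(seqs)
    ]


def brute_force_greedy(records, min_identity=0.3, min_coverage=0.8):
    """Independent oracle: full pairwise matrix first, then the same
    greedy rule (length-desc / id-asc representatives)."""
    recs = sorted(records, key=lambda r: (-r.length, r.protein_id))
    n = len(recs)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                ok[i, j] = True
                continue
            r = align_pair(recs[i], recs[j])
            ok[i, j] = (
                r.identity >= min_identity
                and r.coverage_query >= min_coverage
                and r.coverage_target >= min_coverage
            )
    assigned = [False] * n
    partitions = []
    for i in range(n):
        if assigned[i]:
            continue
        members = [recs[i].protein_id]
        assigned[i] = True
        for j in range(i + 1, n):
            if not assigned[j] and ok[i, j]:
                members.append(recs[j].protein_id)
                assigned[j] = True
        partitions.append(set(members))
    return partitions


class TestGreedyCluster:
    def test_identical_pair_forms_one_cluster(self):
        seq = "MKVLAAGGTREWEMKDEFGHIKLMNPQRSTVW" * 3
        clusters = greedy_cluster(_records([seq, seq]))
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_maximal_stringency_gives_singletons(self):
        rng = np.random.default_rng(4)
        recs = _records([random_protein_seq(rng, 90) for _ in range(5)])
        clusters = greedy_cluster(recs, min_identity=1.0, min_coverage=1.0)
        assert len(clusters) == 5 and all(c.size == 1 for c in clusters)

    def test_empty_input(self):
        assert greedy_cluster([]) == []

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            greedy_cluster([], min_identity=0.0)

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        fams = [simulate_hp_family(120, 3, 0.8, rng=s) for s in (1, 2)]
        seqs = [s for f in fams for s in f] + [
            random_protein_seq(rng, 100) for _ in range(4)
        ]
        recs = _records(seqs)
        clusters = greedy_cluster(recs)
        seen = [pid for c in clusters for pid in c.member_ids]
        assert sorted(seen) == sorted(r.protein_id for r in recs)

    def test_matches_brute_force_oracle_small_n(self):
        rng = np.random.default_rng(17)
        fams = [simulate_hp_family(100, 4, 0.75, rng=s) for s in (11, 12, 13)]
        seqs = [s for f in fams for s in f] + [
            random_protein_seq(rng, int(rng.integers(80, 120))) for _ in range(8)
        ]
        recs = _records(seqs)
        got = [set(c.member_ids) for c in greedy_cluster(recs)]
        expected = brute_force_greedy(recs)
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_determinism_under_input_permutation(self):
        rng = np.random.default_rng(21)
        fams = [simulate_hp_family(100, 3, 0.7, rng=s) for s in (5, 6)]
        seqs = [s for f in fams for s in f]
        recs = _records(seqs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        c1 = [tuple(sorted(c.member_ids)) for c in greedy_cluster(recs)]
        c2 = [tuple(sorted(c.member_ids)) for c in greedy_cluster(shuffled)]
        assert c1 == c2

    def test_planted_family_recovery_short(self):
        """Miniature planted-family recovery: adjusted Rand index 1.0."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(31)
        labels_true, seqs = [], []
        for fam, seed in enumerate((41, 42, 43)):
            for s in simulate_hp_family(150, 4, 0.6, rng=seed):
                labels_true.append(fam)
                seqs.append(s)
        for k in range(5):
            labels_true.append(100 + k)
            seqs.append(random_protein_seq(rng, 150))
        recs = _records(seqs)
        clusters = greedy_cluster(recs)
        label_of = {
            pid: i for i, c in enumerate(clusters) for pid in c.member_ids
        }
        labels_pred = [label_of[r.protein_id] for r in recs]
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0


class TestClusterSummary:
    def test_category_planting_recovered_exactly(self):
        seq = "MKVLAAGGTREWEMKDEFGHIKLMNPQRSTVW" * 4
        recs = _records([seq] * 10)
        from hugeprot.io_formats import AnnotationRecord

        cats = ["Q"] * 5 + ["M"] * 3 + ["T"] * 2  # proportions 0.5/0.3/0.2
        anns = {
            r.protein_id: AnnotationRecord(r.protein_id, functional_category=c)
            for r, c in zip(recs, cats)
        }
        clusters = greedy_cluster(recs)
        out = cluster_summary(clusters, recs, [make_meta("PX")], anns)
        table = out["categories"].set_index("functional_category")["n_proteins"]
        assert table.to_dict() == {"Q": 5, "M": 3, "T": 2}

    def test_uncategorized_tallied_as_unassigned(self):
        seq = "MKVLAAGGTREWEMKDEFGHIKLMNPQRSTVW" * 4
        recs = _records([seq, seq])
        clusters = greedy_cluster(recs)
        out = cluster_summary(clusters, recs, [make_meta("PX")], {})
        assert out["n_unassigned"] == 2
        assert out["categories"].empty

    def test_membership_table_thresholds_hold(self):
        m1, m2 = simulate_hp_family(200, 2, 0.7, rng=3)
        recs = _records([m1, m2])
        clusters = greedy_cluster(recs)
        df = membership_table(clusters)
        nonrep = df[df["member"] != df["representative"]]
        assert (nonrep["identity_to_rep"] >= 0.3).all()
        assert (nonrep[["cov_rep", "cov_member"]] >= 0.8).all().all()
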