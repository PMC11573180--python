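import pytest

from hugeprot.architecture import (
    Architecture,
    architectures_from_hits,
    deduce_architecture,
    domain_distribution,
    filter_hits,
    group_architectures,
    no_domain_ids,
    repeat_census,
    resolve_overlaps,
)
from hugeprot.io_formats import DomainHitRaw
from hugeprot.synthetic_data import (
    DEFAULT_PFAM_TYPES,
    GroundTruth,
    simulate_domtblout,
)

from .conftest import make_meta


def hit(pid="P1", acc="PF00001.1", seq_e=1e-9, dom_e=1e-9, score=100.0, env=(10, 100)):
    return DomainHitRaw(pid, acc, acc.split(".")[0] + "_dom", seq_e, dom_e, score, *env)


class TestFilterHits:
    def test_both_thresholds_must_pass(self):
        kept = filter_hits([hit(seq_e=1e-5, dom_e=1e-4)])
        assert len(kept) == 1
        assert filter_hits([hit(seq_e=1e-5, dom_e=0.01)]) == []
        assert filter_hits([hit(seq_e=0.01, dom_e=1e-5)]) == []

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_monotone_in_thresholds(self):
        hits = [hit(seq_e=10.0 ** -e, dom_e=10.0 ** -d) for e in range(1, 6) for d in range(1, 6)]
        strict = {id(h) for h in filter_hits(hits, 1e-3, 1e-3)}
        loose = {id(h) for h in filter_hits(hits, 1e-2, 1e-3)}
        looser = {id(h) for h in filter_hits(hits, 1e-2, 1e-2)}
        assert strict <= loose <= looser


class TestResolveOverlaps:
    def test_majority_overlap_keeps_higher_bitscore(self):
        # overlap 61 > 50% of the shorter envelope (100) -> conflict
        a = hit(acc="PF00001.1", score=80.0, env=(1, 100))
        b = hit(acc="PF00002.1", score=50.0, env=(40, 140))
        kept = resolve_overlaps([a, b])
        assert [h.pfam_accession for h in kept] == ["PF00001.1"]

    def test_small_overlap_keeps_both(self):
        # overlap 11 <= 50% of the shorter envelope (100)
        a = hit(acc="PF00001.1", score=80.0, env=(1, 100))
        b = hit(acc="PF00002.1", score=50.0, env=(90, 200))
        kept = resolve_overlaps([a, b])
        assert [h.pfam_accession for h in kept] == ["PF00001.1", "PF00002.1"]

    def test_single_hit_unchanged(self):
        a = hit()
        assert resolve_overlaps([a]) == [a]

    def test_pairwise_overlap_bound_after_resolution(self):
        import numpy as np

        rng = np.random.default_rng(2)
        hits = [
            hit(
                acc=f"PF{i:05d}.1",
                score=float(rng.uniform(10, 100)),
                env=tuple(sorted(rng.integers(1, 500, size=2) + [0, 60])),
            )
            for i in range(25)
        ]
        kept = resolve_overlaps(hits)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                ov = min(a.env_to, b.env_to) - max(a.env_from, b.env_from) + 1
                shorter = min(a.env_to - a.env_from + 1, b.env_to - b.env_from + 1)
                assert ov <= 0.5 * shorter


class TestDeduceArchitecture:
    def test_pattern_orders_by_envelope(self):
        hits = [
            hit(acc="PF00001.21", env=(10, 100)),
            hit(acc="PF00002.3", env=(150, 300)),
            hit(acc="PF00001.23", env=(350, 500)),
        ]
        arch = deduce_architecture("P1", hits)
        assert arch.pattern == "PF00001|PF00002|PF00001"

    def test_no_hits_empty_pattern(self):
        arch = deduce_architecture("P1", [])
        assert arch.pattern == "" and "P1" in no_domain_ids([arch])

    def test_version_suffix_stripped(self):
        arch = deduce_architecture("P1", [hit(acc="PF00001.21"), ])
        assert arch.pattern == "PF00001"

    def test_collapsed_pattern_marks_repeat_runs(self):
        arch = Architecture(
            "P1",
            [("PF00069", 1, 50), ("PF00400", 60, 100), ("PF00400", 110, 150), ("PF00001", 200, 260)],
        )
        assert arch.collapsed_pattern == "PF00069|PF00400*|PF00001"


class TestGrouping:
    def test_same_pattern_one_group(self):
        archs = [
            Architecture("P1", [("PF00001", 1, 50), ("PF00002", 60, 120)]),
            Architecture("P2", [("PF00001", 5, 55), ("PF00002", 70, 130)]),
        ]
        groups = group_architectures(archs)
        assert len(groups) == 1
        code, ids = groups["PF00001|PF00002"]
        assert len(code) == 6 and ids == ["P1", "P2"]

    def test_order_matters(self):
        archs = [
            Architecture("P1", [("A", 1, 10), ("B", 20, 30)]),
            Architecture("P2", [("B", 1, 10), ("A", 20, 30)]),
        ]
        groups = group_architectures(archs)
        assert len(groups) == 2
        assert groups["A|B"][0] != groups["B|A"][0]

    def test_codes_stable_across_runs(self):
        archs = [Architecture("P1", [("PF00001", 1, 50)])]
        c1 = group_architectures(archs)["PF00001"][0]
        c2 = group_architectures(archs)["PF00001"][0]
        assert c1 == c2

    def test_forced_collision_resolved_injectively(self):
        from hugeprot.architecture import _hash_code

        def colliding(text):  # every un-bumped pattern hashes identically
            return "SAME00" if "#" not in text else _hash_code(text)

        archs = [
            Architecture("P1", [("A", 1, 10)]),
            Architecture("P2", [("B", 1, 10)]),
            Architecture("P3", [("C", 1, 10)]),
        ]
        groups = group_architectures(archs, hash_fn=colliding)
        codes = [groups[p][0] for p in ("A", "B", "C")]
        assert len(set(codes)) == 3


class TestDistributionAndCensus:
    def _archs(self, n, acc="PF00400", per_protein=1):
        return [
            Architecture(
                f"P{i}", [(acc, 10 + 60 * j, 50 + 60 * j) for j in range(per_protein)]
            )
            for i in range(n)
        ]

    def test_small_phylum_fully_retained(self):
        metas = [make_meta(f"U{i}", phylum="P") for i in range(3)]
        proteome_of = {f"P{i}": f"U{i}" for i in range(3)}
        df = domain_distribution(self._archs(3), proteome_of, metas)
        assert df["n_proteins"].sum() == 3

    def test_subsampling_deterministic(self):
        metas = [make_meta(f"U{i}", phylum="P") for i in range(80)]
        proteome_of = {f"P{i}": f"U{i}" for i in range(80)}
        archs = self._archs(80)
        d1 = domain_distribution(archs, proteome_of, metas, max_proteomes_per_phylum=50, seed=5)
        d2 = domain_distribution(archs, proteome_of, metas, max_proteomes_per_phylum=50, seed=5)
        assert d1.equals(d2)
        assert d1["n_proteins"].sum() == 50

    def test_presence_vs_occurrence_counting(self):
        metas = [make_meta("U0", phylum="P")]
        proteome_of = {"P0": "U0"}
        df = domain_distribution(self._archs(1, per_protein=2), proteome_of, metas)
        row = df.iloc[0]
        assert row["n_proteins"] == 1 and row["n_occurrences"] == 2

    def test_repeat_census_presence_based(self):
        archs = self._archs(1, acc="PF00400", per_protein=30)
        assert repeat_census(archs, DEFAULT_PFAM_TYPES) == 1
        assert repeat_census(self._archs(4, acc="PF00069"), DEFAULT_PFAM_TYPES) == 0

    def test_repeat_census_planted_fraction(self):
        archs = self._archs(7, acc="PF00400") + [
            Architecture(f"Q{i}", [("PF00069", 1, 60)]) for i in range(13)
        ]
        assert repeat_census(archs, DEFAULT_PFAM_TYPES) == 7

    def test_unmapped_accession_raises(self):
        with pytest.raises(KeyError, match="PF99999"):
            repeat_census(self._archs(1, acc="PF99999"), DEFAULT_PFAM_TYPES)


class TestRoundTrip:
    def test_planted_architectures_recovered_exactly(self, tmp_path):
        """100 proteins with planted architectures (incl. a repeat block)
        and one above-threshold decoy each: the 0.001/0.001 filter
        removes every decoy and recovery is exact."""
        from hugeprot.io_formats import read_domtblout
        from hugeprot.synthetic_data import DEFAULT_ARCHITECTURE_LIBRARY

        truth = GroundTruth()
        lengths = {}
        for i in range(100):
            pid = f"HP{i:03d}"
            truth.background_hp_ids.add(pid)
            truth.architecture_per_hp[pid] = list(
                DEFAULT_ARCHITECTURE_LIBRARY[i % len(DEFAULT_ARCHITECTURE_LIBRARY)]
            )
            lengths[pid] = 5500
        path = tmp_path / "h.domtblout"
        simulate_domtblout(truth, lengths, path, seed=9, decoy_prob=1.0)
        archs = architectures_from_hits(
            read_domtblout(path), protein_ids=sorted(lengths)
        )
        for pid, planted in truth.architecture_per_hp.items():
            assert archs[pid].pattern == "|".join(planted), pid
            assert "PF09999" not in archs[pid].pattern
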