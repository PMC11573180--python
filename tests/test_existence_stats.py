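import numpy as np
import pytest

from hugeprot.existence_stats import (
    assembly_level_summary,
    compare_distributions,
    existence_proportions,
    full_comparison,
    quality_correlations,
    resample_nonhp,
)
from hugeprot.prevalence import HPSet

from .conftest import make_meta, make_protein


def kruskal_by_hand(groups):
    """Textbook tie-corrected Kruskal-Wallis H (independent of scipy)."""
    pooled = sorted(x for g in groups for x in g)
    N = len(pooled)
    # average ranks with ties
    ranks = {}
    i = 0
    while i < N:
        j = i
        while j < N and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks[pooled[i]] = avg
        i = j
    h = 12.0 / (N * (N + 1)) * sum(
        sum(ranks[x] for x in g) ** 2 / len(g) for g in groups
    ) - 3 * (N + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < N:
        j = i
        while j < N and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    denom = 1.0 - ties / (N**3 - N)
    return h / denom if denom > 0 else float("nan")


def anova_f_by_hand(groups):
    """Textbook between/within mean-square ratio."""
    all_x = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_x.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_x) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestProportions:
    def test_all_level_four(self):
        proteins = [make_protein(f"H{i}", 5000, level=4) for i in range(3)] + [
            make_protein("N1", 100, level=1)
        ]
        cmp = existence_proportions(proteins, {"H0", "H1", "H2"})
        assert cmp.hp_pct == {1: 0.0, 2: 0.0, 3: 0.0, 4: 100.0}

    def test_direct_count_25_75(self):
        levels = [1, 4, 4, 4]
        proteins = [make_protein(f"H{i}", 5000, level=l) for i, l in enumerate(levels)]
        cmp = existence_proportions(proteins, {p.protein_id for p in proteins})
        assert cmp.hp_pct[1] == 25.0 and cmp.hp_pct[4] == 75.0
        assert sum(cmp.hp_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_missing_level_is_error(self):
        with pytest.raises(ValueError, match="existence level"):
            existence_proportions([make_protein("P", 10)], set())

    def test_survey_proportions_recovered_within_binomial_error(self):
        """Cohort drawn at the HP evidence proportions (0.8% protein
        level, 0.06% transcript, ~22% homology, 77% predicted) is
        recovered within 3 binomial SEs."""
        probs = np.array([0.008, 0.0006, 0.2214, 0.77])
        probs = probs / probs.sum()
        rng = np.random.default_rng(42)
        n = 20000
        levels = rng.choice([1, 2, 3, 4], size=n, p=probs)
        proteins = [
            make_protein(f"H{i}", 5000, level=int(l)) for i, l in enumerate(levels)
        ]
        cmp = existence_proportions(proteins, {p.protein_id for p in proteins})
        for lvl, p in zip((1, 2, 3, 4), probs):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(cmp.hp_pct[lvl] / 100.0 - p) < 3 * se

    def test_percentages_invariant_under_relabeling(self):
        levels = [1, 3, 3, 4, 4, 4]
        a = [make_protein(f"A{i}", 5000, level=l) for i, l in enumerate(levels)]
        b = [make_protein(f"B{i}", 5000, level=l) for i, l in enumerate(levels)]
        ca = existence_proportions(a, {p.protein_id for p in a})
        cb = existence_proportions(b, {p.protein_id for p in b})
        assert ca.hp_pct == cb.hp_pct


class TestResampling:
    def test_exhaustive_sample_sd_zero(self):
        levels = [1] * 3 + [3] * 5 + [4] * 12
        means, sds = resample_nonhp(levels, sample_size=len(levels), n_reps=10, rng=0)
        assert means == {1: 3.0, 2: 0.0, 3: 5.0, 4: 12.0}
        assert all(s == 0.0 for s in sds.values())

    def test_hypergeometric_calibration(self):
        """Level-4 mean count over 100 replicates sits within 3
        hypergeometric SEs of 0.5 * sample_size."""
        N, n = 2000, 400
        levels = [4] * (N // 2) + [3] * (N // 2)
        means, _ = resample_nonhp(levels, sample_size=n, n_reps=100, rng=1)
        expect = 0.5 * n
        var = n * 0.5 * 0.5 * (N - n) / (N - 1)
        se = np.sqrt(var / 100)
        assert abs(means[4] - expect) < 3 * se

    def test_seed_reproducibility(self):
        levels = [1, 3, 4] * 50
        out1 = resample_nonhp(levels, 30, 5, rng=7)
        out2 = resample_nonhp(levels, 30, 5, rng=7)
        assert out1 == out2

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError, match="exceeds population"):
            resample_nonhp([1, 2, 3], sample_size=4, n_reps=1, rng=0)


class TestGroupTests:
    def test_identical_multisets_give_h0_p1(self):
        h, p, _, _ = compare_distributions([1, 3, 4, 4], [4, 4, 1, 3])
        assert h == 0.0 and p == 1.0

    def test_complete_separation_matches_hand_ranks(self):
        hp, nonhp = [1, 1, 1], [4, 4, 4]
        h, _, f, _ = compare_distributions(hp, nonhp)
        assert h == pytest.approx(kruskal_by_hand([hp, nonhp]), abs=1e-12)

    def test_anova_f_matches_textbook_on_toy(self):
        hp, nonhp = [1.0, 2.0, 2.0], [3.0, 4.0, 4.0]
        _, _, f, _ = compare_distributions(hp, nonhp)
        assert f == pytest.approx(anova_f_by_hand([hp, nonhp]), abs=1e-12)

    def test_agreement_with_hand_oracles_on_random_cohorts(self):
        """H and F match independent textbook computations to 1e-9 on 50
        random toy cohorts."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = list(rng.integers(1, 5, size=rng.integers(4, 30)))
            b = list(rng.integers(1, 5, size=rng.integers(4, 30)))
            if sorted(a) == sorted(b) or len(set(a + b)) == 1:
                continue
            h, _, f, _ = compare_distributions(a, b)
            assert h == pytest.approx(kruskal_by_hand([a, b]), abs=1e-9)
            if len(set(a)) > 1 or len(set(b)) > 1:
                assert f == pytest.approx(anova_f_by_hand([a, b]), abs=1e-9)

    def test_single_protein_cohort_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1], [2, 3, 4])


class TestQualityCorrelations:
    def _setup(self, buscos, counts):
        metas = [
            make_meta(f"U{i}", phylum="P", busco_completeness=b)
            for i, b in enumerate(buscos)
        ]
        hp = HPSet(
            hp_ids={
                f"U{i}": {f"U{i}_H{j}" for j in range(c)} for i, c in enumerate(counts)
            }
        )
        proteins = [
            make_protein(f"U{i}_H{j}", 5000 + 10 * j, proteome=f"U{i}")
            for i, c in enumerate(counts)
            for j in range(c)
        ]
        return metas, hp, proteins

    def test_collinear_gives_r_one(self):
        metas, hp, proteins = self._setup([50, 60, 70, 80], [1, 2, 3, 4])
        df = quality_correlations(metas, hp, proteins)
        assert df.iloc[0]["r_completeness_vs_hp_count"] == pytest.approx(1.0)

    def test_anticollinear_gives_r_minus_one(self):
        metas, hp, proteins = self._setup([50, 60, 70, 80], [4, 3, 2, 1])
        df = quality_correlations(metas, hp, proteins)
        assert df.iloc[0]["r_completeness_vs_hp_count"] == pytest.approx(-1.0)

    def test_matches_hand_computed_covariance_ratio(self):
        x = np.array([50.0, 60.0, 72.0, 81.0, 95.0])
        y = np.array([0.0, 2.0, 1.0, 4.0, 3.0])
        metas, hp, proteins = self._setup(list(x), [int(v) for v in y])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        df = quality_correlations(metas, hp, proteins)
        assert df.iloc[0]["r_completeness_vs_hp_count"] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_points_absent(self):
        metas, hp, proteins = self._setup([50, 60], [1, 2])
        df = quality_correlations(metas, hp, proteins)
        assert np.isnan(df.iloc[0]["r_completeness_vs_hp_count"])


class TestAssemblySummary:
    def test_median_and_empty_groups(self):
        metas = [
            make_meta("U1", assembly_level="Contig"),
            make_meta("U2", assembly_level="Contig"),
            make_meta("U3", assembly_level="Contig"),
            make_meta("U4", assembly_level="Chromosome"),
        ]
        hp = HPSet(
            hp_ids={
                "U1": {"a"},
                "U2": {"b", "c"},
                "U3": {f"x{i}" for i in range(31)},
            }
        )
        df = assembly_level_summary(metas, hp).set_index("assembly_level")
        assert df.loc["Contig", "median"] == 2  # counts [1, 2, 31]
        assert df.loc["Chromosome", "median"] == 0
        assert "Scaffold" not in df.index  # empty group absent


class TestFullComparison:
    def test_resample_blocks_present_for_all_rep_counts(self):
        rng = np.random.default_rng(0)
        proteins = [
            make_protein(f"H{i}", 5000, level=int(l))
            for i, l in enumerate(rng.integers(3, 5, size=20))
        ] + [
            make_protein(f"N{i}", 100, level=int(l))
            for i, l in enumerate(rng.integers(1, 5, size=200))
        ]
        cmp = full_comparison(
            proteins, {f"H{i}" for i in range(20)}, rep_counts=(5, 10, 100), seed=3
        )
        assert set(cmp.resample_mean) == {5, 10, 100}
        assert cmp.kruskal_h is not None and cmp.anova_f is not None
        for n_reps in (5, 10, 100):
            assert all(sd >= 0 for sd in cmp.resample_sd[n_reps].values())
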