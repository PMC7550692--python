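"""Contingency construction, Fisher oracle, enrichment ratio,
permutation test convergence and determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from pdacdriver import (
    ContingencyTable,
    GeneSet,
    build_contingency,
    enrich_families,
    enrichment_ratio,
    fisher_enrichment,
    permutation_enrichment,
    read_gmt,
)
from pdacdriver.geneset_enrichment import results_to_frame


def brute_force_fisher_p(table: ContingencyTable) -> float:
    """Two-sided Fisher P by enumerating all hypergeometric tables with the
    same margins and summing those no more probable than the observed one."""
    rv = stats.hypergeom(table.N, table.m, table.k)
    support = np.arange(max(0, table.k + table.m - table.N), min(table.m, table.k) + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(table.a)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


def random_table(rng: np.random.Generator, max_n: int = 60) -> ContingencyTable:
    N = int(rng.integers(4, max_n + 1))
    m = int(rng.integers(1, N))
    k = int(rng.integers(1, N))
    lo, hi = max(0, k + m - N), min(m, k)
    a = int(rng.integers(lo, hi + 1))
    return ContingencyTable(a=a, m=m, k=k, N=N)


class TestContingency:
    def test_set_arithmetic(self):
        background = [f"g{i}" for i in range(20)]
        family = GeneSet("fam", set(background[:4]))
        degs = background[2:7]
        table = build_contingency(degs, family, background)
        assert (table.a, table.m, table.k, table.N) == (2, 4, 5, 20)

    def test_degs_outside_background_dropped(self, caplog):
        background = ["g1", "g2", "g3"]
        family = GeneSet("fam", {"g1"})
        with caplog.at_level("WARNING"):
            table = build_contingency(["g1", "alien"], family, background)
        assert (table.a, table.k) == (1, 1)
        assert "alien" in caplog.text

    def test_family_disjoint_from_background(self):
        table = build_contingency(["g1"], GeneSet("fam", {"x"}), ["g1", "g2"])
        assert table.m == 0
        with pytest.raises(ValueError, match="m = 0"):
            enrichment_ratio(table)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            build_contingency(["g1"], GeneSet("fam", {"g1"}), [])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=5, m=4, k=10, N=20)
        with pytest.raises(ValueError):
            ContingencyTable(a=1, m=30, k=5, N=20)


class TestFisher:
    def test_small_table_matches_enumeration(self):
        table = ContingencyTable(a=2, m=4, k=5, N=20)
        result = fisher_enrichment(table)
        assert result.p_value == pytest.approx(0.2487100103, abs=1e-9)
        assert result.p_value == pytest.approx(brute_force_fisher_p(table), rel=1e-9)

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            table = random_table(rng)
            assert fisher_enrichment(table).p_value == pytest.approx(
                brute_force_fisher_p(table), rel=1e-6, abs=1e-12
            ), table

    def test_sample_or_conventions(self):
        assert fisher_enrichment(ContingencyTable(0, 4, 5, 20)).sample_or == 0.0
        # all family genes are DEGs -> (m-a) = 0 with a > 0
        assert math.isinf(fisher_enrichment(ContingencyTable(3, 3, 5, 20)).sample_or)
        result = fisher_enrichment(ContingencyTable(2, 4, 5, 20))
        assert result.sample_or == pytest.approx(2 * 13 / (2 * 3))

    def test_conditional_ci_contains_point_estimate(self):
        result = fisher_enrichment(ContingencyTable(10, 28, 90, 11789))
        assert result.or_ci[0] < result.sample_or < result.or_ci[1]
        assert result.p_value < 1e-12


class TestEnrichmentRatio:
    # frozen arithmetic of (a/m) / ((k-a)/(N-m)) on the printed family counts
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 28, 90, 11789), 52.5045),
            ((2, 5, 90, 11789), 53.5636),
            ((12, 33, 90, 11789), 54.8065),
            ((2, 7, 90, 11789), 38.2532),
            ((4, 48, 90, 16859), 16.2897),
            ((3, 13, 90, 16859), 44.6844),
            ((4, 55, 90, 16859), 14.2106),
            ((0, 7, 90, 16859), 0.0),
        ],
    )
    def test_frozen_values(self, counts, expected):
        assert enrichment_ratio(ContingencyTable(*counts)) == pytest.approx(expected, abs=5e-4)

    def test_all_degs_in_family_is_infinite(self):
        assert math.isinf(enrichment_ratio(ContingencyTable(5, 8, 5, 20)))


class TestPermutation:
    def test_zero_overlap_gives_unit_p_and_zero_or(self):
        result = permutation_enrichment(ContingencyTable(0, 7, 90, 16859), reps=10_000, seed=1)
        assert result.p_value == 1.0
        assert not result.p_is_bound
        assert result.odds_ratio == 0.0
        assert result.or_ci == (0.0, 0.0)

    def test_p_converges_to_hypergeometric_tail(self):
        table = ContingencyTable(2, 4, 5, 20)
        reps = 100_000
        result = permutation_enrichment(table, reps=reps, seed=2)
        exact = stats.hypergeom(table.N, table.m, table.k).sf(table.a - 1)
        mc_se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(result.p_value - exact) < 4 * mc_se
        # expected overlap k*m/N = 1.0 -> permutation OR near a/1 = 2
        assert result.odds_ratio == pytest.approx(2.0, rel=0.02)

    def test_or_converges_to_expected_count_ratio(self):
        table = ContingencyTable(4, 48, 90, 16859)
        result = permutation_enrichment(table, reps=1_000_000, seed=3)
        expected_or = table.a * table.N / (table.k * table.m)
        assert result.odds_ratio == pytest.approx(expected_or, rel=0.01)
        assert result.or_ci[0] < result.odds_ratio < result.or_ci[1]

    def test_zero_tail_count_reported_as_bound(self):
        # overlap far beyond anything 10^4 draws can reach
        result = permutation_enrichment(ContingencyTable(20, 25, 30, 1000), reps=10_000, seed=4)
        assert result.p_is_bound
        assert result.p_display.startswith("<")
        assert result.p_value == pytest.approx(1e-4)

    def test_monotone_in_overlap(self):
        previous_fisher, previous_perm = 1.1, 1.1
        for a in range(0, 5):
            table = ContingencyTable(a, 6, 8, 40)
            fisher_p = fisher_enrichment(table).p_value
            perm = permutation_enrichment(table, reps=20_000, seed=5)
            if a >= 2:  # two-sided Fisher is not monotone at the low-overlap end
                assert fisher_p <= previous_fisher + 1e-12
            assert perm.p_value <= previous_perm + 1e-12
            previous_fisher, previous_perm = fisher_p, perm.p_value

    def test_subset_mode_agrees_with_hypergeometric_mode(self):
        table = ContingencyTable(2, 4, 5, 20)
        hyper = permutation_enrichment(table, reps=20_000, seed=6)
        subset = permutation_enrichment(table, reps=20_000, seed=6, mode="subset")
        assert abs(hyper.p_value - subset.p_value) < 0.02
        assert subset.odds_ratio == pytest.approx(hyper.odds_ratio, rel=0.05)

    def test_depletion_alternative(self):
        table = ContingencyTable(0, 10, 40, 80)
        result = permutation_enrichment(table, reps=20_000, seed=7, alternative="less")
        exact = stats.hypergeom(80, 10, 40).cdf(0)
        assert result.p_value == pytest.approx(exact, abs=0.01)

    def test_determinism_and_seed_sensitivity(self):
        table = ContingencyTable(3, 13, 90, 16859)
        a = permutation_enrichment(table, reps=50_000, seed=8)
        b = permutation_enrichment(table, reps=50_000, seed=8)
        assert a == b
        c = permutation_enrichment(table, reps=50_000, seed=9)
        assert a.odds_ratio != c.odds_ratio

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            permutation_enrichment(ContingencyTable(2, 4, 5, 20), reps=10)


class TestEnrichFamilies:
    def test_cartesian_product_and_determinism(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(200)]
        sets = [
            GeneSet("fam1", set(background[:10])),
            GeneSet("fam2", set(background[10:25])),
            GeneSet("fam3", set(background[25:30])),
            GeneSet("fam4", set(background[30:43])),
        ]
        degs = {
            "t_test": list(rng.choice(background, 20, replace=False)),
            "rank_based": list(rng.choice(background, 20, replace=False)),
        }
        results = enrich_families(degs, sets, background, reps=2000, seed=1)
        assert len(results) == 8
        frame_a = results_to_frame(results)
        frame_b = results_to_frame(enrich_families(degs, sets, background, reps=2000, seed=1))
        assert frame_a.equals(frame_b)

    def test_planted_family_has_smallest_permutation_p(self):
        background = [f"g{i}" for i in range(500)]
        planted = GeneSet("planted", set(background[:20]))
        decoy = GeneSet("decoy", set(background[20:40]))
        degs = {"list": background[:15] + background[100:110]}  # 15 of 20 planted genes
        results = enrich_families(degs, [planted, decoy], background, reps=5000, seed=2)
        by_name = {r.family: r for r in results}
        assert by_name["planted"].permutation.p_value < by_name["decoy"].permutation.p_value
        assert by_name["planted"].ratio > by_name["decoy"].ratio

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enrich_families({}, [GeneSet("f", {"g"})], ["g"], reps=2000)
        with pytest.raises(ValueError):
            enrich_families({"l": ["g"]}, [], ["g"], reps=2000)


class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "families.gmt"
        path.write_text(
            "box_HACA_snoRNAs\tpseudouridylation guides\tSNORA1\tSNORA2\n"
            "box_CD_snoRNAs\tmethylation guides\tSNORD1\n"
        )
        sets = read_gmt(path)
        assert [s.name for s in sets] == ["box_HACA_snoRNAs", "box_CD_snoRNAs"]
        assert sets[0].members == {"SNORA1", "SNORA2"}

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)
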