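"""Fisher exact test, enrichment workflow, and Spearman correlation."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from nanofix.stats import (
    EnrichmentResult,
    fisher_exact_2x2,
    normalize_effort,
    odds_ratio,
    run_enrichment,
    spearman,
)
from nanofix.synthetic_data import simulate_enrichment_counts


def fisher_oracle(a, b, c, d):
    """Two-sided p by dumb full enumeration with exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        # hypergeometric point probability from factorials
        f = math.factorial
        return Fraction(f(r1) * f(r2) * f(c1) * f(n - c1),
                        f(x) * f(r1 - x) * f(c1 - x) * f(r2 - (c1 - x)) * f(n))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


class TestFisherExact:
    def test_balanced_table_is_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0

    def test_diagonal_table_by_hand(self):
        # margins (3,3,3,3): 4 feasible tables; the two extreme ones each have
        # probability C(3,3)C(3,0)/C(6,3) = 1/20, so p = 2/20 = 0.1
        _, p = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 31, size=4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_large_table_route_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(100, 3000, size=4))
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            _, p_scipy = sps.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(float(p_scipy), abs=1e-12)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            _, p1 = fisher_exact_2x2([[a, b], [c, d]])
            _, p2 = fisher_exact_2x2([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_odds_ratio_division_by_zero(self):
        assert odds_ratio([[3, 0], [0, 3]]) == math.inf
        assert odds_ratio([[0, 3], [3, 0]]) == 0.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert 0.0 < p <= 1.0


class TestRunEnrichment:
    GROUPS = tuple(f"g{i}" for i in range(9))

    def null_counts(self, n=500):
        pu = {g: n for g in self.GROUPS}
        counts = {(g, ds): n for g in self.GROUPS
                  for ds in ("UO", "UO_ld", "UO_dm", "WUO", "WUO_ld", "WUO_dm")}
        return counts, pu

    def test_default_design_has_54_tests_and_bonferroni_factor(self):
        counts, pu = self.null_counts()
        results = run_enrichment(counts, pu, self.GROUPS)
        assert len(results) == 54
        # Bonferroni factor 54: p_adj = min(1, 54 * p_raw)
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 54 * r.p_raw))

    def test_proportions_identical_to_pu_are_ns(self):
        counts, pu = self.null_counts()
        for r in run_enrichment(counts, pu, self.GROUPS):
            assert r.verdict == "ns" and r.odds_ratio == pytest.approx(1.0)

    def test_doubled_proportion_detected_as_enriched(self):
        counts, pu = self.null_counts(1000)
        # group g0 doubles its share in UO_dm, others shrink to compensate
        counts[("g0", "UO_dm")] = 2000
        for g in self.GROUPS[1:]:
            counts[(g, "UO_dm")] = 875
        results = run_enrichment(counts, pu, self.GROUPS)
        verdicts = {(r.group, r.dataset): r.verdict for r in results}
        assert verdicts[("g0", "UO_dm")] == "enriched"
        (hit,) = [r for r in results if (r.group, r.dataset) == ("g0", "UO_dm")]
        assert hit.odds_ratio > 1 and hit.p_adj < 0.05

    def test_missing_group_in_pu_is_configuration_error(self):
        counts, pu = self.null_counts()
        del pu["g3"]
        with pytest.raises(ValueError, match="g3"):
            run_enrichment(counts, pu, self.GROUPS)

    def test_planted_cpr_enrichment_scenario_detected(self):
        counts, pu = simulate_enrichment_counts(
            123, n_per_group=500,
            shift={("CPR", ds): 2.5 for ds in ("UO", "UO_ld", "UO_dm")},
        )
        results = run_enrichment(counts, pu)
        cpr = {r.dataset: r.verdict for r in results if r.group == "CPR"}
        assert cpr["UO"] == "enriched"
        assert cpr["UO_ld"] == "enriched"
        assert cpr["UO_dm"] == "enriched"

    def test_verdict_requires_significance(self):
        with pytest.raises(ValueError):
            EnrichmentResult("UO", "g", ((1, 1), (1, 1)), 1.0, 0.9, 1.0, "enriched")


class TestSpearman:
    def test_monotone_relations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 8.0, 20.0]) == pytest.approx(1.0)
        assert spearman(x, [20.0, 8.0, 3.0, 2.0]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx = sps.rankdata(x)  # mid-ranks
            ry = sps.rankdata(y)
            expected = float(np.corrcoef(rx, ry)[0, 1])
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_nan(self):
        assert math.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEffortMetrics:
    def test_best_sampled_site_scores_one(self):
        raw = {
            ("037", "MES"): (1000, 900, 100, 20.0),
            ("038", "MES"): (500, 450, 50, 10.0),
        }
        metrics = normalize_effort(raw)
        assert metrics[("037", "MES")].normalized_effort == pytest.approx(1.0)
        assert metrics[("038", "MES")].normalized_effort == pytest.approx(0.5)

    def test_completeness_tracks_effort_in_rigged_scenario(self):
        # sites sorted by effort should sort by completeness -> rho == 1
        effort = [0.1, 0.3, 0.5, 0.8, 1.0]
        completeness = [10.0, 25.0, 50.0, 75.0, 100.0]
        assert spearman(effort, completeness) == pytest.approx(1.0)
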