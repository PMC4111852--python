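import math

import numpy as np
import pytest
from scipy import stats

from mudpac import (
    EnrichmentResult,
    GeneScore,
    RankedList,
    enrichment_pvalue,
    fdr_correct,
    impute_outside_scores,
    ranking_score,
    select_top_pathways,
    wks_statistic,
)


def gs(gene, score, imputed=False, mf=0.0):
    return GeneScore(gene=gene, mf=mf, if_value=0.5, score=score, imputed=imputed)


def ranked(member_scores, outside_scores):
    members = [gs(f"m{i}", s) for i, s in enumerate(member_scores)]
    outside = [gs(f"o{i}", s, imputed=True) for i, s in enumerate(outside_scores)]
    return RankedList.build("p", members, outside)


def brute_force_md(scores, membership):
    """Independent per-position walk of the ranked list (distinct scores)."""
    total = sum(s for s, m in zip(scores, membership) if m)
    n_miss = sum(1 for m in membership if not m)
    hit = miss = 0.0
    best = 0.0
    for s, m in zip(scores, membership):
        if m:
            hit += s / total
        else:
            miss += 1 / n_miss
        best = max(best, abs(hit - miss))
    return best


class TestRankingScore:
    def test_zero_mf_passes_if_through(self):
        assert ranking_score(0.0, 0.5) == pytest.approx(0.5)

    def test_log_two_case(self):
        assert ranking_score(math.log(2), 0.25) == pytest.approx(0.5)

    def test_monotone_in_mf(self):
        assert ranking_score(1.0, 0.3) > ranking_score(0.5, 0.3)

    @pytest.mark.parametrize("bad_if", [0.0, 1.0, -0.1, 1.5])
    def test_if_outside_unit_interval_rejected(self, bad_if):
        with pytest.raises(ValueError):
            ranking_score(0.0, bad_if)


class TestImputation:
    def test_zero_pass_rate_all_fallback(self):
        rng = np.random.default_rng(0)
        out = impute_outside_scores(
            [("a", 0.5), ("b", -1.0)], 10.0, 1.0, 0.0, 0.005, rng
        )
        assert [s.score for s in out] == pytest.approx(
            [math.exp(0.5) * 0.005, math.exp(-1.0) * 0.005]
        )
        assert all(s.imputed for s in out)

    def test_point_mass_background(self):
        rng = np.random.default_rng(0)
        out = impute_outside_scores([("a", 0.0)] * 5, 3.3, 0.0, 1.0, 0.005, rng)
        assert all(s.score == pytest.approx(3.3) for s in out)

    def test_pass_fraction_binomial(self):
        rng = np.random.default_rng(123)
        n = 10000
        out = impute_outside_scores(
            [(f"g{i}", 0.0) for i in range(n)], 5.0, 0.1, 0.5, 0.005, rng
        )
        # drawn scores cluster near 5, fallbacks at exp(0)*alpha
        n_drawn = sum(1 for s in out if s.score > 1)
        sigma = math.sqrt(n * 0.25)
        assert abs(n_drawn - 0.5 * n) < 3 * sigma

    def test_scores_stay_positive(self):
        rng = np.random.default_rng(7)
        out = impute_outside_scores(
            [("a", 0.0)] * 200, -5.0, 0.5, 1.0, 0.005, rng
        )
        assert all(s.score > 0 for s in out)


class TestWksStatistic:
    def test_members_on_top_give_one(self):
        rl = ranked([9.0, 8.0], [3.0, 2.0, 1.0])
        assert wks_statistic(rl) == pytest.approx(1.0)

    def test_interleaved_equal_weights_small_md(self):
        # exact ties collapse into one block: both CDFs finish together
        rl = ranked([1.0, 1.0], [1.0, 1.0])
        assert wks_statistic(rl) <= 0.5

    def test_brute_force_oracle_random_lists(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            k = int(rng.integers(1, n - 1))
            scores = np.sort(rng.random(n) + 1e-9)[::-1]
            membership = np.zeros(n, dtype=bool)
            membership[rng.choice(n, size=k, replace=False)] = True
            entries = [
                gs(f"g{i}", float(s), imputed=not m)
                for i, (s, m) in enumerate(zip(scores, membership))
            ]
            rl = RankedList(pathway_id="p", entries=entries, membership=membership)
            assert wks_statistic(rl) == pytest.approx(
                brute_force_md(scores, membership), abs=1e-12
            )

    def test_fixed_six_gene_list(self):
        scores = [5.0, 4.0, 3.0, 2.0, 1.0, 0.9]
        membership = [True, True, False, False, False, False]
        rl = ranked(scores[:2], scores[2:])
        assert wks_statistic(rl) == pytest.approx(
            brute_force_md(scores, membership)
        )


class TestEnrichmentPvalue:
    def test_extreme_list_minimum_p(self):
        # members occupy the top positions; permutations essentially never
        # reproduce MD = 1, so p sits at the +1-smoothed minimum
        rng = np.random.default_rng(0)
        member = list(np.linspace(60, 50, 5))
        outside = list(np.linspace(40, 1, 45))
        rl = ranked(member, outside)
        res = enrichment_pvalue(rl, n_perm=100, rng=rng)
        assert res.md == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 101)

    def test_null_membership_p_uniform(self):
        """Random membership over iid scores yields calibrated p-values."""
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            scores = rng.random(60) + 1e-9
            order = np.argsort(-scores)
            member_idx = set(rng.choice(60, size=6, replace=False).tolist())
            member = [scores[i] for i in order if i in member_idx]
            outside = [scores[i] for i in order if i not in member_idx]
            rl = ranked(member, outside)
            ps.append(enrichment_pvalue(rl, n_perm=99, rng=rng).p)
        d = stats.kstest(ps, "uniform").statistic
        assert d < 1.63 / math.sqrt(len(ps))  # KS bound at level 0.01

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        rl = ranked([2.0, 1.5], [1.0, 0.5, 0.2])
        res = enrichment_pvalue(rl, n_perm=50, rng=rng)
        assert 0 < res.p <= 1


class TestFdrCorrect:
    def test_direct_formula(self):
        # rank 10 with p = 0.01 and m = 200 -> 0.2; later ranks larger
        results = [EnrichmentResult(f"p{i:02d}", 0.5, 0.001 + 0.001 * i)
                   for i in range(9)]
        results.append(EnrichmentResult("p10", 0.5, 0.01))
        results += [EnrichmentResult(f"q{i}", 0.5, 0.5 + 0.01 * i) for i in range(3)]
        out = fdr_correct(results, m_total=200)
        tenth = [r for r in out if r.rank == 10][0]
        assert tenth.p == 0.01
        assert tenth.fdr == pytest.approx(0.2)

    def test_cap_at_one(self):
        out = fdr_correct([EnrichmentResult("a", 0.5, 1.0)], m_total=5)
        assert out[0].fdr == 1.0

    def test_single_pathway_identity(self):
        out = fdr_correct([EnrichmentResult("a", 0.5, 0.05)], m_total=1)
        assert out[0].fdr == pytest.approx(0.05)
        assert out[0].rank == 1

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        results = [
            EnrichmentResult(f"p{i}", 0.5, float(p))
            for i, p in enumerate(rng.random(50))
        ]
        # inject ties
        results += [EnrichmentResult(f"t{i}", 0.5, 0.25) for i in range(5)]
        out = fdr_correct(results, m_total=200)
        fdrs = [r.fdr for r in out]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_m_total_smaller_than_results_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([EnrichmentResult("a", 0.5, 0.1)] * 2, m_total=1)


class TestSelectTop:
    def test_k_exceeding_pool_returns_all(self):
        res = [EnrichmentResult(f"p{i}", 0.5, 0.1 * (i + 1)) for i in range(3)]
        assert len(select_top_pathways(res, 60)) == 3

    def test_tie_broken_by_larger_md(self):
        res = [
            EnrichmentResult("lo", 0.5, 0.01),
            EnrichmentResult("hi", 0.9, 0.01),
        ]
        assert select_top_pathways(res, 1) == ["hi"]

    def test_smallest_p_first(self):
        res = [
            EnrichmentResult("a", 0.5, 0.001),
            EnrichmentResult("b", 0.5, 0.02),
            EnrichmentResult("c", 0.5, 0.5),
        ]
        assert select_top_pathways(res, 2) == ["a", "b"]
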