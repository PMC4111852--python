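import itertools
import math

import numpy as np
import pytest

from mudpac import (
    CoverageProfile,
    PathwayGraph,
    RunConfig,
    collab_pvalue,
    dominance_ok,
    greedy_select,
    joint_coverage,
    max_single_gene_rate,
    pathway_coverage,
)
from .conftest import make_matrix, path_graph


def profile_matrix(profiles):
    return make_matrix(np.asarray(profiles, dtype=int))


class TestPathwayCoverage:
    def test_union_over_member_genes(self):
        mat = profile_matrix([[1, 0, 0, 0], [0, 1, 0, 0]])
        pw = path_graph("p", ["g0", "g1"])
        prof = pathway_coverage(mat, pw)
        assert prof.rate == pytest.approx(0.5)
        assert prof.covered_samples == {"s0", "s1"}

    def test_unmutated_pathway_rate_zero(self):
        mat = profile_matrix(np.zeros((2, 3)))
        pw = path_graph("p", ["g0", "g1"])
        assert pathway_coverage(mat, pw).rate == 0.0

    def test_full_coverage(self):
        mat = profile_matrix([[1, 0], [0, 1]])
        pw = path_graph("p", ["g0", "g1"])
        assert pathway_coverage(mat, pw).rate == 1.0

    def test_no_gene_in_matrix_raises(self):
        mat = profile_matrix([[1, 0]])
        pw = path_graph("p", ["x", "y"])
        with pytest.raises(ValueError, match="no gene"):
            pathway_coverage(mat, pw)


class TestJointCoverage:
    def test_single_profile_identity(self):
        pr = CoverageProfile("p", frozenset({"s0", "s2"}), 0.5)
        assert joint_coverage([pr], 4) == pytest.approx(0.5)

    def test_intersection(self):
        a = CoverageProfile("a", frozenset({"s1", "s2"}), 0.5)
        b = CoverageProfile("b", frozenset({"s2", "s3"}), 0.5)
        assert joint_coverage([a, b], 4) == pytest.approx(0.25)

    def test_disjoint_is_zero(self):
        a = CoverageProfile("a", frozenset({"s1"}), 0.25)
        b = CoverageProfile("b", frozenset({"s2"}), 0.25)
        assert joint_coverage([a, b], 4) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            joint_coverage([], 4)

    def test_matches_per_sample_brute_force(self):
        rng = np.random.default_rng(9)
        m = 12
        samples = [f"s{j}" for j in range(m)]
        for _ in range(50):
            k = int(rng.integers(1, 5))
            profs = []
            for i in range(k):
                mask = rng.random(m) < 0.5
                profs.append(
                    CoverageProfile(
                        f"p{i}",
                        frozenset(s for s, c in zip(samples, mask) if c),
                        float(mask.mean()),
                    )
                )
            brute = sum(
                1 for s in samples if all(s in p.covered_samples for p in profs)
            ) / m
            assert joint_coverage(profs, m) == pytest.approx(brute)


class TestMaxSingleGeneRate:
    def test_counts(self):
        profiles = np.zeros((2, 10), dtype=int)
        profiles[0, :3] = 1  # g0 in 3 of 10
        profiles[1, 0] = 1
        mat = profile_matrix(profiles)
        pw = path_graph("p", ["g0", "g1"])
        assert max_single_gene_rate(mat, pw) == ("g0", pytest.approx(0.3))

    def test_tie_broken_alphabetically(self):
        mat = profile_matrix([[1, 0], [0, 1]])
        pw = path_graph("p", ["g1", "g0"])
        gene, rate = max_single_gene_rate(mat, pw)
        assert gene == "g0" and rate == pytest.approx(0.5)

    def test_all_unmutated_rate_zero(self):
        mat = profile_matrix(np.zeros((2, 4)))
        pw = path_graph("p", ["g0", "g1"])
        assert max_single_gene_rate(mat, pw)[1] == 0.0


class TestDominance:
    def test_clear_margin_passes(self):
        # a 70% set coverage against a 44% top gene passes the 5% margin
        assert dominance_ok(0.70, 0.44, 0.05)

    def test_equal_rates_fail(self):
        # 72% MCR cannot clear a 72% single-gene rate by 5%
        assert not dominance_ok(0.72, 0.72, 0.05)

    def test_exact_boundary_passes(self):
        assert dominance_ok(0.30, 0.25, 0.05)


class TestCollabPvalue:
    def _toy(self):
        # 3 samples; candidate gene with 2 events in distinct samples
        nsy_counts = np.array([[1, 1, 0]])
        mat = make_matrix(nsy_counts)
        pw = PathwayGraph.make("c", "c", ["g0"], [])
        return mat, pw

    def test_matches_exhaustive_enumeration(self):
        """With all samples pre-covered, the permuted joint MCR is just the
        occupancy of 2 uniform assignments over 3 samples; the exact null is
        enumerable."""
        mat, pw = self._toy()
        selected = [CoverageProfile("s", frozenset({"s0", "s1", "s2"}), 1.0)]
        observed = 2 / 3
        exact = sum(
            1
            for a in itertools.product(range(3), repeat=2)
            if len(set(a)) / 3 >= observed
        ) / 9
        rng = np.random.default_rng(4)
        n_perm = 20000
        p = collab_pvalue(mat, pw, selected, n_perm, rng)
        sigma = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 4 * sigma

    def test_zero_mutation_candidate_p_one(self):
        mat = profile_matrix(np.zeros((1, 3)))
        pw = PathwayGraph.make("c", "c", ["g0"], [])
        assert collab_pvalue(mat, pw, [], 10, np.random.default_rng(0)) == 1.0

    def test_planted_cooccurrence_is_significant(self):
        rng = np.random.default_rng(8)
        m = 200
        block = np.zeros(m, dtype=bool)
        block[:80] = True  # co-mutated block
        cand = np.zeros((1, m), dtype=int)
        cand[0, block] = 1
        mat = make_matrix(cand)
        pw = PathwayGraph.make("c", "c", ["g0"], [])
        samples = [f"s{j}" for j in range(m)]
        selected = [
            CoverageProfile(
                "s", frozenset(s for s, b in zip(samples, block) if b), 0.4
            )
        ]
        p = collab_pvalue(mat, pw, selected, 1000, rng)
        assert p < 0.01

    def test_uniformly_scattered_candidate_calibrated(self):
        """Candidate events drawn from the redistribution null itself give
        approximately uniform p-values."""
        from scipy import stats

        rng = np.random.default_rng(15)
        m = 300
        n_events = 90
        samples = [f"s{j}" for j in range(m)]
        sel_mask = rng.random(m) < 0.6
        selected = [
            CoverageProfile(
                "s", frozenset(s for s, b in zip(samples, sel_mask) if b),
                float(sel_mask.mean()),
            )
        ]
        ps = []
        for _ in range(30):
            counts = np.bincount(rng.integers(0, m, n_events), minlength=m)
            mat = make_matrix(counts[None, :])
            pw = PathwayGraph.make("c", "c", ["g0"], [])
            ps.append(collab_pvalue(mat, pw, selected, 400, rng))
        d = stats.kstest(ps, "uniform").statistic
        assert d < 1.63 / np.sqrt(len(ps))  # KS bound at level 0.01


class TestGreedySelect:
    def _cfg(self, **kw):
        base = dict(n_perm_collab=300, rng_seed=0)
        base.update(kw)
        return RunConfig(**base)

    def test_single_gene_coverage_never_selected_first(self):
        # pathway A: coverage produced entirely by one gene (rate == MCR)
        m = 20
        profiles = np.zeros((3, m), dtype=int)
        profiles[0, :10] = 1  # gene g0 dominates pathway A
        profiles[1, :6] = 1  # pathway B spread over two genes
        profiles[2, 6:12] = 1
        mat = profile_matrix(profiles)
        pa = path_graph("A", ["g0"])
        pb = path_graph("B", ["g1", "g2"])
        out = greedy_select(mat, [pa, pb], self._cfg(), np.random.default_rng(0))
        assert out.pathway_ids and out.pathway_ids[0] == "B"
        assert "A" not in out.pathway_ids

    def test_all_dominated_gives_empty_set(self):
        mat = profile_matrix([[1, 1, 0, 0]])
        pw = path_graph("A", ["g0"])
        out = greedy_select(mat, [pw], self._cfg(), np.random.default_rng(0))
        assert out.steps == [] and out.mcr == 0.0

    def test_mcr_trajectory_non_increasing(self):
        rng = np.random.default_rng(33)
        m = 50
        profiles = (rng.random((8, m)) < 0.4).astype(int)
        mat = profile_matrix(profiles)
        pws = [path_graph(f"P{i}", [f"g{2*i}", f"g{2*i+1}"]) for i in range(4)]
        out = greedy_select(
            mat, pws, self._cfg(collab_p_threshold=0.999),
            np.random.default_rng(1),
        )
        mcrs = [st.mcr_after for st in out.steps]
        assert all(a >= b - 1e-12 for a, b in zip(mcrs, mcrs[1:]))

    def test_unconstrained_mode_ignores_dominance(self):
        mat = profile_matrix([[1, 1, 1, 0]])
        pw = path_graph("A", ["g0"])
        out = greedy_select(
            mat, [pw], self._cfg(), np.random.default_rng(0), constrained=False
        )
        assert out.pathway_ids == ["A"]

    def test_reproducible_given_seed(self):
        rng_profiles = np.random.default_rng(2)
        profiles = (rng_profiles.random((10, 40)) < 0.3).astype(int)
        mat = profile_matrix(profiles)
        pws = [path_graph(f"P{i}", [f"g{2*i}", f"g{2*i+1}"]) for i in range(5)]
        outs = [
            greedy_select(mat, pws, self._cfg(), np.random.default_rng(77))
            for _ in range(2)
        ]
        a, b = outs[0].steps, outs[1].steps
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.pathway_id == sb.pathway_id
            assert sa.mcr_after == sb.mcr_after
            assert sa.max_gene_rate == sb.max_gene_rate
            assert sa.p == sb.p or (np.isnan(sa.p) and np.isnan(sb.p))
        assert outs[0].covered_samples == outs[1].covered_samples

    def test_removing_mutations_never_raises_coverage(self):
        rng = np.random.default_rng(6)
        profiles = (rng.random((4, 30)) < 0.4).astype(int)
        mat = profile_matrix(profiles)
        pw = path_graph("P", ["g0", "g1", "g2", "g3"])
        base = pathway_coverage(mat, pw).rate
        for _ in range(20):
            reduced = profiles.copy()
            hits = np.argwhere(reduced > 0)
            if not len(hits):
                break
            i, j = hits[rng.integers(len(hits))]
            reduced[i, j] = 0
            assert pathway_coverage(profile_matrix(reduced), pw).rate <= base
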