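"""Combinatorics, hypergeometric overlap, mutation baselines and signatures."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest

from bcrmrd.clone_phylo import CloneMember, align_members
from bcrmrd.errors import InsufficientDataError
from bcrmrd.overlap_stats import (
    CONTEXTS_96,
    CloneMutationRecord,
    clone_overlap_tests,
    combine_pvalues_fisher,
    compare_profiles,
    compare_shared_mutations,
    diag_relapse_shared_fraction,
    error_site_overlap,
    error_sites,
    mutational_combinations,
    n_significant,
    overlap_pvalue,
    pairwise_shared_fractions,
    shared_fraction,
    shared_mutation_baseline,
    triplet_profile,
)
from bcrmrd.synthetic_repertoire import SimConfig, hotspot_weights, simulate_clone

from conftest import make_rep


def enumerate_shell(l, d):
    """Count l-mers at exact Hamming distance d from a fixed reference."""
    ref = ("ACGT" * (l // 4 + 1))[:l]
    return sum(
        1
        for s in map("".join, product("ACGT", repeat=l))
        if sum(a != b for a, b in zip(s, ref)) == d
    )


def hypergeom_tail_oracle(N, a, b, k):
    """Exact rational pmf summation, independent of the implementation."""
    lo = max(k, a + b - N)
    num = sum(comb(a, x) * comb(N - a, b - x) for x in range(lo, min(a, b) + 1))
    return float(Fraction(num, comb(N, b)))


class TestMutationalCombinations:
    @pytest.mark.parametrize("l,d", [(1, 1), (4, 2), (5, 0), (6, 3), (3, 3)])
    def test_matches_exhaustive_enumeration(self, l, d):
        assert mutational_combinations(l, d) == enumerate_shell(l, d)

    def test_distance_zero_is_single_sequence(self):
        assert mutational_combinations(100, 0) == 1

    def test_single_position_three_choices(self):
        assert mutational_combinations(1, 1) == 3

    def test_d_beyond_l_rejected(self):
        with pytest.raises(ValueError):
            mutational_combinations(3, 4)

    def test_exact_integer_arithmetic_at_scale(self):
        assert mutational_combinations(300, 8) == comb(300, 8) * 3**8


class TestOverlapPvalue:
    def test_k_zero_is_one(self):
        assert overlap_pvalue(1000, 30, 40, 0) == 1.0

    def test_hand_checkable_case(self):
        assert overlap_pvalue(54, 2, 2, 1) == pytest.approx(105 / 1431, abs=1e-12)

    def test_degenerate_certainty(self):
        # when diagnosis members fill the population, overlap is forced
        assert overlap_pvalue(54, 54, 5, 5) == pytest.approx(1.0)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(10, 12, 3, 1)
        with pytest.raises(ValueError):
            overlap_pvalue(10, 4, 3, 4)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            N = int(rng.integers(2, 5000))
            a = int(rng.integers(1, N + 1))
            b = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, a + b - N), min(a, b) + 1))
            assert overlap_pvalue(N, a, b, k) == pytest.approx(
                hypergeom_tail_oracle(N, a, b, k), abs=1e-12
            )

    def test_large_population_path_consistent_with_oracle(self):
        # exercises the log-space falling-factorial branch (N > 1e8)
        N = 5 * 10**8
        for a, b, k in [(20, 15, 3), (40, 40, 1), (8, 8, 8)]:
            assert overlap_pvalue(N, a, b, k) == pytest.approx(
                hypergeom_tail_oracle(N, a, b, k), rel=1e-9
            )

    def test_super_uniform_under_independence(self):
        """Drawing both variant sets independently keeps the test conservative."""
        rng = np.random.default_rng(17)
        N, a, b = 90, 10, 10
        rejections = 0
        n_seeds = 300
        for _ in range(n_seeds):
            da = set(rng.choice(N, a, replace=False).tolist())
            db_ = set(rng.choice(N, b, replace=False).tolist())
            p = overlap_pvalue(N, a, b, len(da & db_))
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds <= 0.05 + 3 * se


class TestCloneOverlapTests:
    def test_shared_variants_drive_combined_significance(self):
        anc = "A" * 60
        members = [CloneMember(anc, 100, 100)]
        rng = np.random.default_rng(3)
        for i in range(12):
            s = list(anc)
            s[i] = "T"
            members.append(CloneMember("".join(s), 3, 3 if i < 10 else 0))
        aln = align_members(members)
        tests, combined, infeasible = clone_overlap_tests(aln)
        assert infeasible == []
        d1 = next(t for t in tests if t.d == 1)
        assert (d1.n_diag, d1.n_rel, d1.k) == (12, 10, 10)
        assert d1.N == 180
        assert combined < 1e-10

    def test_no_shared_variants_gives_p_one(self):
        anc = "A" * 30
        v1 = "T" + anc[1:]
        v2 = anc[:-1] + "T"
        members = [
            CloneMember(anc, 50, 50),
            CloneMember(v1, 3, 0),
            CloneMember(v2, 0, 3),
        ]
        tests, combined, _ = clone_overlap_tests(align_members(members))
        assert all(t.p_value == 1.0 for t in tests)
        assert combined == pytest.approx(1.0)


class TestSharedMutationBaseline:
    def test_shared_fraction_definition(self):
        assert shared_fraction(frozenset({1, 2}), frozenset({3, 4})) == 0.0
        assert shared_fraction(frozenset({1, 2}), frozenset({1, 2})) == 1.0
        assert shared_fraction(frozenset(), frozenset({1})) == 0.0

    def test_pair_eligibility_labels(self):
        recs = [
            CloneMutationRecord("s1", "IGHV1", "IGHJ1", frozenset({1})),
            CloneMutationRecord("s1", "IGHV1", "IGHJ2", frozenset({1})),
            CloneMutationRecord("s2", "IGHV1", "IGHJ1", frozenset({2})),
            CloneMutationRecord("s1", "IGHV2", "IGHJ1", frozenset({3})),
        ]
        base = pairwise_shared_fractions(recs)
        assert sorted(set(base.labels)) == [
            "same V, different J",
            "same V, different individuals",
        ]
        assert len(base.fractions) == 3  # V2 record pairs with nobody

    def test_same_sample_same_j_pairs_excluded(self):
        recs = [
            CloneMutationRecord("s1", "IGHV1", "IGHJ1", frozenset({1})),
            CloneMutationRecord("s1", "IGHV1", "IGHJ1", frozenset({2})),
        ]
        with pytest.raises(InsufficientDataError):
            pairwise_shared_fractions(recs)

    def test_collision_oracle_uniform_mutations(self):
        """Independent m-mutation clones share ~m/L of their sites."""
        rng = np.random.default_rng(21)
        L, m = 120, 6
        fractions = []
        for pair in range(500):
            a = frozenset(rng.choice(L, m, replace=False).tolist())
            b = frozenset(rng.choice(L, m, replace=False).tolist())
            fractions.append(shared_fraction(a, b))
        mean = np.mean(fractions)
        se = np.std(fractions) / np.sqrt(len(fractions))
        assert abs(mean - m / L) <= 3 * se

    def test_full_pipeline_on_clustered_healthy_data(self, small_cfg, db):
        """Clusters of >= 7 sequences in SHM-heavy healthy samples yield a baseline."""
        cfg = SimConfig(seed=61, healthy_cells=200, healthy_shm_rate=0.004,
                        read_count_mu=3.0, read_count_sigma=0.3)
        from bcrmrd.synthetic_repertoire import simulate_healthy

        reps = [simulate_healthy(cfg, db, sample_id=f"b{i}", salt=i)[0] for i in range(2)]
        base = shared_mutation_baseline(reps, db, min_cluster_size=7)
        assert base.n_records >= 2
        assert all(0.0 <= f <= 1.0 for f in base.fractions)


class TestCompareSharedMutations:
    def test_exact_extreme_ranks(self):
        assert compare_shared_mutations([0, 0, 0.1], [0.5, 0.6]) == pytest.approx(0.1)

    def test_wrong_direction_not_significant(self):
        p = compare_shared_mutations([0.5, 0.6, 0.7], [0.1, 0.2])
        assert p >= 0.5

    def test_identical_groups_near_half(self):
        p = compare_shared_mutations([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert 0.3 <= p <= 0.7

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 0.1, 50).tolist()
        obs = rng.uniform(0.5, 0.9, 50).tolist()
        assert compare_shared_mutations(base, obs) < 1e-10


class TestTripletProfile:
    def test_pyrimidine_context_classification(self):
        profile = triplet_profile("AACGA", [("AATGA", 1)])
        assert profile.counts["A[C>T]G"] == 1
        assert profile.total == 1

    def test_terminal_mutation_excluded_and_counted(self):
        profile = triplet_profile("AACGA", [("TACGA", 2)])
        assert profile.total == 0
        assert profile.n_excluded_terminal == 2

    def test_purine_strand_collapse(self):
        # G>C at position 2 of AAGTA: complement -> C>G, flanks swap+complement
        profile = triplet_profile("AAGTA", [("AACTA", 1)])
        assert profile.counts["A[C>G]T"] == 1

    def test_counts_weighted_by_reads(self):
        profile = triplet_profile("AACGA", [("AATGA", 7)])
        assert profile.counts["A[C>T]G"] == 7

    def test_planted_hotspot_enrichment_detected(self, db):
        """WRC/GYW-weighted SHM concentrates mutations at hotspot positions."""
        cfg = SimConfig(seed=71, clone_variants=150, hotspot_multiplier=8.0)
        clone = simulate_clone(cfg, db)
        anc = clone.ancestor_seq
        weights = hotspot_weights(anc, 8.0)
        hot = {i for i, w in enumerate(weights) if w > 1}
        hits = total = 0
        for _, row in clone.truth.iterrows():
            for p in row["positions"]:
                total += 1
                hits += p in hot
        p0 = len(hot) / len(anc)
        from scipy import stats as sps

        res = sps.binomtest(hits, total, p0, alternative="greater")
        assert res.pvalue < 0.005


class TestCompareProfiles:
    def test_identical_profiles_nothing_significant(self):
        rng = np.random.default_rng(2)
        p1 = triplet_profile("A" * 3, [])
        for ctx in CONTEXTS_96:
            p1.counts[ctx] = int(rng.integers(0, 10))
        table = compare_profiles(p1, p1)
        assert n_significant(table) == 0 and n_significant(table, corrected=False) == 0

    def test_concentrated_context_significant_after_bonferroni(self):
        p1 = triplet_profile("A" * 3, [])
        p2 = triplet_profile("A" * 3, [])
        p1.counts["A[C>T]G"] = 100
        for i, ctx in enumerate(CONTEXTS_96):
            p2.counts[ctx] = 1 if i < 96 else 0  # ~uniform spread, total ~96
        table = compare_profiles(p1, p2).set_index("context")
        assert bool(table.loc["A[C>T]G", "significant_bonferroni"])
        # oracle: Fisher on the same 2x2
        from scipy import stats as sps

        expected = sps.fisher_exact([[100, 0], [1, 95]])[1]
        assert table.loc["A[C>T]G", "p_value"] == pytest.approx(expected)


class TestErrorSiteOverlap:
    def test_true_sequence_is_most_frequent(self):
        rep = make_rep({"AAAA": 100, "AATA": 3, "TAAA": 2})
        true_seq, sites = error_sites(rep)
        assert true_seq == "AAAA"
        assert sites == frozenset({0, 2})

    def test_disjoint_sites_give_p_one(self):
        r1 = make_rep({"A" * 20: 50, "T" + "A" * 19: 1}, sample_id="c1")
        r2 = make_rep({"A" * 20: 50, "A" * 19 + "T": 1}, sample_id="c2")
        table = error_site_overlap([r1, r2])
        assert table["p_value"].iloc[0] == 1.0

    def test_identical_sites_extreme_p(self):
        L = 300
        base = "A" * L
        variants = {base: 1000}
        for i in range(5):
            variants["".join("T" if j == 40 + i * 7 else "A" for j in range(L))] = 2
        r1 = make_rep(dict(variants), sample_id="c1")
        r2 = make_rep(dict(variants), sample_id="c2")
        table = error_site_overlap([r1, r2])
        assert table["k_shared"].iloc[0] == 5
        assert table["p_value"].iloc[0] < 1e-9
        assert table["p_value"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(L, 5, 5, 5), rel=1e-9
        )

    def test_uniform_errors_null_holds(self):
        """Random error sites: no Bonferroni-significant pair overlap."""
        rng = np.random.default_rng(9)
        L = 250
        reps = []
        for s in range(12):
            base = "A" * L
            counts = {base: 2000}
            for pos in rng.choice(L, 6, replace=False):
                counts["".join("C" if j == pos else "A" for j in range(L))] = 2
            reps.append(make_rep(counts, sample_id=f"ctrl{s}"))
        table = error_site_overlap(reps)
        n_pairs = len(table)
        assert n_pairs == 66
        assert (table["p_value"] < 0.05 / n_pairs).sum() == 0


class TestCombineFisher:
    def test_matches_scipy_on_moderate_pvalues(self):
        from scipy import stats as sps

        ps = [0.01, 0.2, 0.6]
        expected = sps.combine_pvalues(ps, method="fisher")[1]
        assert combine_pvalues_fisher(ps) == pytest.approx(expected, rel=1e-12)

    def test_survives_tiny_pvalues(self):
        assert 0 <= combine_pvalues_fisher([1e-200, 1e-180]) < 1e-300


class TestDiagRelapseSharedFraction:
    def test_pooled_site_sharing(self):
        anc = "A" * 20
        m_shared = "T" + anc[1:]
        m_diag = anc[:5] + "G" + anc[6:]
        members = [
            CloneMember(anc, 50, 50),
            CloneMember(m_shared, 3, 3),
            CloneMember(m_diag, 3, 0),
        ]
        aln = align_members(members)
        # diag sites {0, 5}, relapse sites {0} -> shared 1/min(2,1) = 1.0
        assert diag_relapse_shared_fraction(aln) == pytest.approx(1.0)
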