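"""Clone member collection, center-star alignment and Fitch parsimony trees."""

from itertools import product

import numpy as np
import pytest

from bcrmrd.clone_phylo import (
    CloneMember,
    ORIGIN_BOTH,
    align_members,
    bootstrap_support,
    build_parsimony_tree,
    collect_clone_members,
    exhaustive_parsimony,
    member_shell,
    structure_summary,
)
from bcrmrd.errors import InsufficientDataError
from bcrmrd.mrd_tracker import ClonotypeSignature
from bcrmrd.synthetic_repertoire import SimConfig, simulate_diagnosis_relapse

from conftest import make_rep


def sig_of(*seqs):
    return ClonotypeSignature(
        patient_id="P1",
        clone_id=1,
        member_seqs=frozenset(seqs),
        dominant_seq=sorted(seqs)[0],
        index_fraction=0.3,
    )


def star_members(rng, n_tips, length=40, d_max=3):
    """Random star-like member set (independent mutations off one ancestor)."""
    anc = "".join(rng.choice(list("ACGT"), length))
    seqs = {anc}
    while len(seqs) < n_tips:
        s = list(anc)
        for p in rng.choice(length, int(rng.integers(1, d_max + 1)), replace=False):
            s[p] = "ACGT"[int(rng.integers(4))]
        seqs.add("".join(s))
    ordered = [anc] + sorted(seqs - {anc})
    return [CloneMember(s, (100 if s == anc else 5) - i, 0) for i, s in enumerate(ordered)]


class TestCollectCloneMembers:
    def test_min_count_filter_and_origin_labels(self):
        a, b, c = "A" * 10, "A" * 9 + "T", "A" * 8 + "TT"
        diag = make_rep({a: 5, b: 2, c: 1}, sample_id="d")
        relapse = make_rep({a: 9, b: 3}, sample_id="r")
        members = collect_clone_members(sig_of(a), diag, relapse)
        by_seq = {m.seq: m for m in members}
        assert set(by_seq) == {a, b}
        assert by_seq[a].origin == ORIGIN_BOTH and by_seq[b].origin == ORIGIN_BOTH

    def test_disjoint_member_sets_single_origin(self):
        a, b = "A" * 10, "A" * 9 + "T"
        members = collect_clone_members(
            sig_of(a), make_rep({a: 5}), make_rep({b: 4})
        )
        assert sorted(m.origin for m in members) == ["diagnosis-only", "relapse-only"]

    def test_fewer_than_two_members_raise(self):
        a = "A" * 10
        with pytest.raises(InsufficientDataError):
            collect_clone_members(sig_of(a), make_rep({a: 5}), make_rep({a: 9}))


def sp_cost(rows):
    """Sum-of-pairs unit cost of an alignment (mismatch 1, indel 1, gap-gap 0)."""
    total = 0
    for col in zip(*rows):
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                a, b = col[i], col[j]
                if a == "-" and b == "-":
                    continue
                total += a != b
    return total


def optimal_sp3(s1, s2, s3):
    """Exact 3-sequence sum-of-pairs alignment cost by dynamic programming."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    INF = 10**9
    dp = np.full((n1 + 1, n2 + 1, n3 + 1), INF, dtype=np.int64)
    dp[0, 0, 0] = 0

    def col_cost(a, b, c):
        cost = 0
        for x, y in ((a, b), (a, c), (b, c)):
            if x == "-" and y == "-":
                continue
            cost += x != y
        return cost

    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                cur = dp[i, j, k]
                if cur == INF:
                    continue
                for di, dj, dk in product((0, 1), repeat=3):
                    if di + dj + dk == 0:
                        continue
                    if i + di > n1 or j + dj > n2 or k + dk > n3:
                        continue
                    a = s1[i] if di else "-"
                    b = s2[j] if dj else "-"
                    c = s3[k] if dk else "-"
                    nc = cur + col_cost(a, b, c)
                    if nc < dp[i + di, j + dj, k + dk]:
                        dp[i + di, j + dj, k + dk] = nc
    return int(dp[n1, n2, n3])


class TestAlignMembers:
    def test_equal_length_members_identity_alignment(self):
        ms = [CloneMember("ACGT", 5, 0), CloneMember("ACGA", 2, 1)]
        aln = align_members(ms)
        assert aln.rows == ["ACGT", "ACGA"]
        assert aln.central_seq == "ACGT"

    def test_central_is_highest_count_tie_lexicographic(self):
        ms = [CloneMember("TTTT", 4, 0), CloneMember("AAAA", 2, 1)]
        assert align_members(ms).central_seq == "TTTT"
        ms = [CloneMember("TTTT", 2, 1), CloneMember("AAAA", 3, 0)]  # tie at 3
        assert align_members(ms).central_seq == "AAAA"

    def test_deletion_introduces_gap_columns(self):
        ms = [
            CloneMember("ACGTACGTACGTACG", 9, 0),
            CloneMember("ACGTACGTACGT", 1, 1),  # 3-base deletion
        ]
        aln = align_members(ms)
        assert aln.length == 15
        assert aln.rows[1].count("-") == 3
        assert aln.rows[0] == "ACGTACGTACGTACG"

    def test_center_star_within_twice_optimal_sp_cost(self):
        """Classical 2-approximation bound, checked against an exact 3-way DP."""
        rng = np.random.default_rng(6)
        for _ in range(15):
            seqs = []
            base = "".join(rng.choice(list("ACGT"), 6))
            for _k in range(3):
                s = list(base)
                if rng.random() < 0.5 and len(s) > 4:
                    del s[int(rng.integers(len(s)))]
                for p in rng.choice(len(s), 1):
                    s[p] = "ACGT"[int(rng.integers(4))]
                seqs.append("".join(s))
            if len(set(seqs)) < 3:
                continue
            ms = [CloneMember(s, 10 - i, 0) for i, s in enumerate(seqs)]
            aln = align_members(ms)
            ours = sp_cost(aln.rows)
            best = optimal_sp3(*seqs)
            assert ours <= 2 * best


class TestParsimony:
    def test_two_tips_edge_length_equals_distance(self):
        aln = align_members([CloneMember("AATT", 5, 0), CloneMember("AAGG", 2, 0)])
        tree = build_parsimony_tree(aln)
        assert tree.total_length == 2
        assert tree.newick().endswith(";")

    def test_forced_star_two_single_mutants(self):
        anc = "AAAAAAAA"
        ms = [
            CloneMember(anc, 50, 0),
            CloneMember("TAAAAAAA", 3, 0),
            CloneMember("AAAAAAAT", 2, 0),
        ]
        aln = align_members(ms)
        tree = build_parsimony_tree(aln)
        assert tree.total_length == 2
        assert tree.tips_adjacent_to_central(aln.central_index) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_heuristic_matches_exhaustive_on_six_tips(self, seed):
        rng = np.random.default_rng(seed)
        ms = star_members(rng, 6, length=25)
        aln = align_members(ms)
        heuristic = build_parsimony_tree(aln, seed=seed)
        exact = exhaustive_parsimony(aln)
        assert heuristic.total_length == exact.total_length
        # the heuristic can never beat a full enumeration
        assert heuristic.total_length >= exact.total_length

    def test_score_lower_bounds(self):
        rng = np.random.default_rng(12)
        ms = star_members(rng, 8, length=30)
        aln = align_members(ms)
        tree = build_parsimony_tree(aln)
        variable_cols = sum(1 for col in zip(*aln.rows) if len(set(col)) > 1)
        assert tree.total_length >= variable_cols
        max_pairwise = max(
            sum(a != b for a, b in zip(x, y))
            for x in aln.rows
            for y in aln.rows
        )
        assert tree.total_length >= max_pairwise

    def test_edge_lengths_sum_to_total(self):
        rng = np.random.default_rng(3)
        ms = star_members(rng, 7, length=30)
        tree = build_parsimony_tree(align_members(ms))
        assert sum(tree.edge_lengths.values()) == tree.total_length

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        ms = star_members(rng, 9, length=30)
        aln = align_members(ms)
        t1 = build_parsimony_tree(aln, seed=4)
        t2 = build_parsimony_tree(aln, seed=4)
        assert t1.newick() == t2.newick()

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(5)
        ms = star_members(rng, 6, length=20)
        tree = build_parsimony_tree(align_members(ms))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 6
        total = sum(e.length or 0 for e in parsed.edges())
        assert total == tree.total_length

    def test_star_property_central_dominates(self, db):
        """Most-frequent member sits at the tree's center in star-like clones."""
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=300 + seed, clone_variants=12)
            pair = simulate_diagnosis_relapse(cfg, db, salt=seed)
            ms = [CloneMember(pair.ancestor_seq, 400, 400)] + [
                CloneMember(s, 4, 0) for s in sorted(pair.diag_variant_seqs)
            ]
            aln = align_members(ms)
            tree = build_parsimony_tree(aln, seed=seed)
            if tree.tips_adjacent_to_central(aln.central_index) >= len(ms) // 2:
                hits += 1
        assert hits >= 9

    def test_bootstrap_support_in_unit_range(self):
        rng = np.random.default_rng(14)
        ms = star_members(rng, 6, length=25)
        aln = align_members(ms)
        tree = build_parsimony_tree(aln)
        support = bootstrap_support(aln, tree, n_replicates=20, seed=1)
        assert all(0.0 <= v <= 1.0 for v in support.values())


class TestStructureSummary:
    def test_overlap_fraction_hand_example(self):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT"]
        # diagnosis: s1..s4; relapse: s1, s2, s3, s5
        ms = [
            CloneMember(seqs[0], 10, 10),
            CloneMember(seqs[1], 5, 5),
            CloneMember(seqs[2], 4, 4),
            CloneMember(seqs[3], 3, 0),
            CloneMember(seqs[4], 0, 2),
        ]
        summ = structure_summary(align_members(ms))
        assert summ.overlap_fraction == pytest.approx(0.75)
        assert summ.n_diag_members == 4 and summ.n_rel_members == 4

    def test_identical_frequency_vectors_r2_one(self):
        ms = [CloneMember("AAAA", 10, 20), CloneMember("AAAT", 5, 10),
              CloneMember("AATT", 1, 2)]
        summ = structure_summary(align_members(ms))
        assert summ.r_squared_raw == pytest.approx(1.0)
        assert summ.r_squared_cuberoot == pytest.approx(1.0)

    def test_shells_count_members_by_distance(self):
        ms = [CloneMember("AAAA", 10, 10), CloneMember("AAAT", 2, 2),
              CloneMember("AATT", 2, 0)]
        aln = align_members(ms)
        assert [member_shell(aln, i) for i in range(3)] == [0, 1, 2]
        summ = structure_summary(aln)
        shells = summ.shells.set_index("d")
        assert shells.loc[1, "n_diag"] == 1 and shells.loc[2, "n_rel"] == 0

    def test_planted_sharing_recovered(self, db):
        """Recovered overlap stays within 3 s.e. of the planted 80% rate."""
        cfg = SimConfig(seed=55)
        pair = simulate_diagnosis_relapse(cfg, db)
        from bcrmrd.mrd_tracker import define_signatures

        sig = define_signatures(pair.diagnosis)[0]
        members = collect_clone_members(sig, pair.diagnosis, pair.relapse)
        summ = structure_summary(align_members(members))
        n = summ.n_diag_members
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(summ.overlap_fraction - 0.8) <= 3 * se
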