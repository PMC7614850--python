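"""UMI grouping, consensus and deduplication against independent oracles."""

from collections import Counter

import numpy as np
import pytest

from cellosim import readsim as rs
from cellosim import umi


def _edit_distance_dp(a: str, b: str) -> int:
    """Independent quadratic DP edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _components_oracle(seqs, threshold):
    """Brute-force single-linkage components as a set of frozensets."""
    n = len(seqs)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if _edit_distance_dp(seqs[i], seqs[j]) <= threshold:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x])
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def _partition(groups):
    return {frozenset(g.member_indices) for g in groups}


def _random_umis(n, length, rng):
    return [rs.make_umi(length, "NNN", rng) for _ in range(n)]


class TestLevenshtein:
    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = rs.make_umi(8, "NNN", rng)
            b = rs.make_umi(int(rng.integers(5, 12)), "NNN", rng)
            assert umi.levenshtein(a, b) == _edit_distance_dp(a, b)

    def test_known_values(self):
        assert umi.levenshtein("", "") == 0
        assert umi.levenshtein("ACGT", "ACGT") == 0
        assert umi.levenshtein("ACGT", "AGGT") == 1
        assert umi.levenshtein("ACGT", "ACGGT") == 1
        assert umi.levenshtein("AAAA", "TTTT") == 4


class TestPairwiseDistances:
    def test_condensed_order_matches_oracle(self, rng):
        seqs = _random_umis(12, 9, rng)
        d = umi.pairwise_distances(seqs)
        pos = 0
        for i in range(len(seqs) - 1):
            for j in range(i + 1, len(seqs)):
                assert d[pos] == _edit_distance_dp(seqs[i], seqs[j])
                pos += 1
        assert pos == len(d)

    def test_cap_stores_k_plus_one(self):
        d = umi.pairwise_distances(["AAAAAA", "TTTTTT"], k=2)
        assert d[0] == 3

    def test_distribution_full_census(self, rng):
        seqs = _random_umis(10, 8, rng)
        hist = umi.pairwise_distance_distribution(seqs)
        assert sum(hist.values()) == 45
        oracle = Counter(
            _edit_distance_dp(seqs[i], seqs[j])
            for i in range(9)
            for j in range(i + 1, 10)
        )
        assert hist == oracle

    def test_distribution_subsample_size(self, rng):
        seqs = _random_umis(30, 8, rng)
        hist = umi.pairwise_distance_distribution(seqs, max_pairs=50, rng=1)
        assert sum(hist.values()) == 50


class TestPregroup:
    def test_none_mode(self):
        assert umi.pregroup(3) == ["pg0", "pg0", "pg0"]

    def test_blocks_by_first_appearance(self):
        trues = ["u0", "u1", "u0", "u2", "u3", "u1"]
        labels = umi.pregroup(
            len(trues), "by_true_umi_blocks", true_umis=trues, block_size=2
        )
        assert labels == ["pg0", "pg0", "pg0", "pg1", "pg1", "pg0"]

    def test_alignment_target_mode(self):
        labels = umi.pregroup(
            3, "by_alignment_target", alignment_targets=["el1", None, "el1"]
        )
        assert labels == ["pg_el1", "pg_unmapped", "pg_el1"]

    def test_missing_inputs_raise(self):
        with pytest.raises(ValueError):
            umi.pregroup(2, "by_true_umi_blocks")
        with pytest.raises(ValueError):
            umi.pregroup(2, "nope")


class TestGroupUmis:
    def test_matches_brute_force_oracle_randomised(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seqs = _random_umis(18, 6, rng)
            for threshold in (0, 1, 2, 3):
                got = _partition(umi.group_umis(seqs, threshold))
                assert got == _components_oracle(seqs, threshold)

    def test_distance_equal_threshold_joins(self):
        # d("AAAAAA","AAAATT") = 2: joined at threshold 2, split at 1
        seqs = ["AAAAAA", "AAAATT"]
        assert len(umi.group_umis(seqs, 2)) == 1
        assert len(umi.group_umis(seqs, 1)) == 2

    def test_group_count_monotone_in_threshold(self, rng):
        seqs = _random_umis(40, 10, rng)
        counts = [len(umi.group_umis(seqs, t)) for t in (0, 1, 2, 4, 6, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_pregroups_are_hard_boundaries(self):
        seqs = ["ACGTACGT", "ACGTACGT", "ACGTACGT"]
        groups = umi.group_umis(seqs, 2, pregroups=["a", "a", "b"])
        assert _partition(groups) == {frozenset({0, 1}), frozenset({2})}

    def test_groups_partition_all_reads(self, rng):
        seqs = _random_umis(50, 8, rng)
        groups = umi.group_umis(seqs, 2)
        members = sorted(i for g in groups for i in g.member_indices)
        assert members == list(range(50))

    def test_multi_threshold_equals_single_threshold(self, rng):
        seqs = _random_umis(60, 10, rng)
        pregroups = ["pgA" if i < 30 else "pgB" for i in range(60)]
        multi = umi.group_umis_multi(seqs, [1, 3, 6], pregroups=pregroups)
        for t in (1, 3, 6):
            single = umi.group_umis(seqs, t, pregroups=pregroups)
            assert _partition(multi[t]) == _partition(single)


class TestConsensus:
    def test_single_sequence_returned_verbatim(self):
        assert umi.consensus(["ACGTACGT"]) == "ACGTACGT"

    def test_majority_corrects_substitution(self):
        assert umi.consensus(["ACGTACGT", "ACGAACGT", "ACGTACGT"]) == "ACGTACGT"

    def test_majority_restores_deleted_base(self):
        assert umi.consensus(["ACGTACGT", "ACGACGT", "ACGTACGT"]) == "ACGTACGT"

    def test_majority_removes_inserted_base(self):
        assert umi.consensus(["ACGTACGT", "ACGTTACGT", "ACGTACGT"]) == "ACGTACGT"

    def test_recovers_truth_from_noisy_copies(self, rng):
        from cellosim.reference import generate_ancestral

        truth = generate_ancestral(300, seed=21)
        copies = [rs.corrupt(truth, 0.92, (0.5, 0.25, 0.25), rng) for _ in range(9)]
        cons = umi.consensus(copies, rng=0)
        assert _edit_distance_dp(cons, truth) <= 3

    def test_subsampling_cap_and_determinism(self, rng):
        truth = "ACGT" * 30
        copies = [rs.corrupt(truth, 0.90, (0.5, 0.25, 0.25), rng) for _ in range(80)]
        a = umi.consensus(copies, max_reads=50, rng=7)
        b = umi.consensus(copies, max_reads=50, rng=7)
        assert a == b
        assert _edit_distance_dp(a, truth) <= 4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            umi.consensus([])


class TestDeduplicate:
    def test_multinomial_fairness(self):
        members = ["a", "b", "c", "d"]
        counts = Counter(umi.deduplicate(members, rng=s) for s in range(2000))
        for m in members:
            assert abs(counts[m] - 500) < 150  # >4 sigma for Binomial(2000, .25)

    def test_deterministic_under_seed(self):
        assert umi.deduplicate(list("wxyz"), rng=3) == umi.deduplicate(list("wxyz"), rng=3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            umi.deduplicate([])


class TestAssessGroups:
    def test_purity_and_summary(self):
        seqs = ["A", "A", "C", "G"]
        groups = [
            umi.UmiGroup("g0", [0, 1], ["A", "A"], "pg0"),
            umi.UmiGroup("g1", [2, 3], ["C", "G"], "pg0"),
        ]
        truths = ["u1", "u1", "u2", "u3"]
        assessments, summary = umi.assess_groups(groups, truths)
        assert [a.is_pure for a in assessments] == [True, False]
        assert summary["n_groups"] == 2
        assert summary["fraction_pure"] == 0.5
        assert summary["size_histogram"] == {2: 2}

    def test_missing_truth_rejected(self):
        groups = [umi.UmiGroup("g0", [0, 5], ["A", "A"], "pg0")]
        with pytest.raises(ValueError):
            umi.assess_groups(groups, ["u1"])

    def test_grouping_on_simulated_arm(self, ont_reads):
        # end-to-end: observed UMIs of a 5x ONT arm group near-perfectly at
        # the default 22 nt length and threshold 6
        from cellosim import preprocess as pp

        reads, truth, _ = ont_reads
        kept, _ = pp.preprocess_reads(reads, pp.AdapterConfig())
        observed = [r.umi for r in kept]
        trues = [rs.parse_read_name(r.read_id)["true_umi"] for r in kept]
        n_molecules = len(set(trues))
        _, at6 = umi.assess_groups(umi.group_umis(observed, 6), trues)
        # threshold 6 splits molecules whose reads drifted apart but never
        # merges distinct 22-mers: pure, with bounded oversplitting
        assert at6["fraction_pure"] >= 0.9
        assert n_molecules <= at6["n_groups"] <= 2 * n_molecules
        # a radius at the inter-UMI distance scale chains everything together
        _, at12 = umi.assess_groups(umi.group_umis(observed, 12), trues)
        assert at12["n_groups"] < n_molecules
        assert at12["fraction_pure"] < at6["fraction_pure"]
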