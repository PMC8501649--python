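import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlmc.sequence_io import encode_corpus
from vlmc.simulate import brute_force_kmer_counts
from vlmc.suffix_counting import (
    KmerRecord,
    NodeRange,
    count_supported_kmers,
    evaluate_node,
    init_root_range,
    longest_common_extension,
    sort_and_partition,
)


def oracle_table(sequence, min_count, max_depth):
    """Sliding-window reference, filtered by the support rule."""
    full = brute_force_kmer_counts(sequence, max_depth)
    return {w: r for w, r in full.items() if r.count >= min_count or w == ""}


class TestInitRootRange:
    def test_residue_positions_only(self, cacac_corpus):
        ws, root = init_root_range(cacac_corpus)
        assert list(ws) == [0, 1, 2, 3, 4]
        assert (root.left, root.right, root.depth) == (0, 4, 0)

    def test_single_residue(self):
        ws, root = init_root_range(encode_corpus(["A"]))
        assert list(ws) == [0]
        assert (root.left, root.right) == (0, 0)

    def test_sentinels_excluded_across_records(self):
        ws, _ = init_root_range(encode_corpus(["AC", "GT"]))
        assert list(ws) == [0, 1, 3, 4]


class TestLongestCommonExtension:
    def test_shared_prefix_of_two_suffixes(self, cacac_corpus):
        ws = np.array([1, 3])
        assert longest_common_extension(cacac_corpus, ws, NodeRange(0, 1, 0)) == "AC"

    def test_singleton_runs_to_the_sentinel(self):
        corpus = encode_corpus(["GT"])
        ws, root = init_root_range(corpus)
        assert longest_common_extension(corpus, ws, NodeRange(0, 0, 0)) == "GT"

    def test_immediate_divergence(self, cacac_corpus):
        ws, root = init_root_range(cacac_corpus)
        assert longest_common_extension(cacac_corpus, ws, root) == ""

    def test_sentinel_never_matches_another_sentinel(self):
        # two records with identical tails must not co-extend past the break
        corpus = encode_corpus(["TA", "TA"])
        ws = np.array([0, 3])
        assert longest_common_extension(corpus, ws, NodeRange(0, 1, 0)) == "TA"


class TestSortAndPartition:
    def test_worked_example_root(self, cacac_corpus):
        ws, root = init_root_range(cacac_corpus)
        children, terminal = sort_and_partition(cacac_corpus, ws, root, 0)
        assert terminal == 0
        assert {sym: (c.left, c.right) for sym, c in children.items()} == {
            0: (0, 1),  # A group, size 2
            1: (2, 4),  # C group, size 3
        }
        # stable: position-ascending (longest suffix first) within groups
        assert list(ws) == [1, 3, 0, 2, 4]

    def test_terminal_suffixes_grouped_last(self):
        corpus = encode_corpus(["AC", "A"])  # suffixes "AC$" and "A$"
        ws = np.array([0, 3])
        children, terminal = sort_and_partition(corpus, ws, NodeRange(0, 1, 1), 1)
        assert terminal == 1
        assert set(children) == {1}  # only the C group
        assert children[1].size == 1

    def test_absent_symbol_emits_no_range(self, cacac_corpus):
        ws, root = init_root_range(cacac_corpus)
        children, _ = sort_and_partition(cacac_corpus, ws, root, 0)
        assert 2 not in children and 3 not in children


class TestEvaluateNode:
    def test_implicit_nodes_expanded_to_unit_edges(self, cacac_corpus):
        ws = np.array([1, 3])
        recs, children = evaluate_node(
            cacac_corpus, ws, NodeRange(0, 1, 0), "", max_depth=5
        )
        assert recs == [
            KmerRecord("A", 2, (0, 2, 0, 0), 0),
            KmerRecord("AC", 2, (1, 0, 0, 0), 1),
        ]
        assert [(ctx, c.size) for c, ctx in children] == [("AC", 1)]

    def test_singleton_leaf_expansion(self):
        corpus = encode_corpus(["GT"])
        ws = np.array([0])  # the lone suffix "GT$"
        recs, children = evaluate_node(corpus, ws, NodeRange(0, 0, 0), "",
                                       max_depth=5)
        assert recs == [
            KmerRecord("G", 1, (0, 0, 0, 1), 0),
            KmerRecord("GT", 1, (0, 0, 0, 0), 1),
        ]
        assert children == []

    def test_emission_truncates_at_max_depth(self):
        corpus = encode_corpus(["GTACA"])
        ws, root = init_root_range(corpus)
        recs, children = evaluate_node(
            corpus, ws, NodeRange(0, 0, 0), "", max_depth=2
        )
        assert [r.context for r in recs] == ["G", "GT"]
        assert recs[-1] == KmerRecord("GT", 1, (1, 0, 0, 0), 0)
        assert children == []


class TestCountSupportedKmers:
    def test_worked_example_shallow(self, cacac_corpus):
        table = count_supported_kmers(cacac_corpus, 1, 2)
        by_ctx = {w: r.count for w, r in table.records.items()}
        assert by_ctx == {"": 5, "A": 2, "C": 3, "CA": 2, "AC": 2}

    def test_support_threshold_drops_rare_contexts(self, cacac_corpus):
        table = count_supported_kmers(cacac_corpus, 2, 5)
        assert set(table.records) == {"", "A", "C", "CA", "AC", "CAC"}
        assert table["CAC"].count == 2

    def test_homopolymer(self):
        table = count_supported_kmers(encode_corpus(["AAAA"]), 1, 1)
        assert table[""].count == 4
        assert table["A"] == KmerRecord("A", 4, (3, 0, 0, 0), 1)

    @pytest.mark.parametrize("seed,n,t,L", [
        (0, 2000, 1, 4), (1, 5000, 2, 6), (2, 10000, 5, 8),
        (3, 3000, 1, 8), (4, 8000, 2, 1),
    ])
    def test_matches_sliding_window_oracle(self, random_sequence, seed, n, t, L):
        seq = random_sequence(seed, n, n_fraction=0.02)
        table = count_supported_kmers(encode_corpus([seq]), t, L)
        assert table.records == oracle_table(seq, t, L)

    @settings(derandomize=True, max_examples=80)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=60),
        t=st.integers(1, 2),
        L=st.integers(1, 5),
    )
    def test_oracle_equivalence_property(self, seq, t, L):
        if not any(c in "ACGT" for c in seq):
            return
        table = count_supported_kmers(encode_corpus([seq]), t, L)
        assert table.records == oracle_table(seq, t, L)

    def test_multi_record_counts_do_not_cross_boundaries(self):
        records = ["ACGTACGT", "ACGT"]
        table = count_supported_kmers(encode_corpus(records), 1, 3)
        assert table.records == oracle_table(records, 1, 3)

    def test_conservation_and_substring_counts(self, random_sequence):
        seq = random_sequence(7, 4000)
        table = count_supported_kmers(encode_corpus([seq]), 1, 5)
        for w, rec in table.records.items():
            assert rec.count == sum(rec.next_counts) + rec.terminal_count
            if w:  # overlapping substring occurrences
                occurrences = sum(
                    1 for i in range(len(seq) - len(w) + 1)
                    if seq[i : i + len(w)] == w
                )
                assert rec.count == occurrences

    def test_monotone_in_support_and_depth(self, random_sequence):
        corpus = encode_corpus([random_sequence(8, 3000)])
        base = count_supported_kmers(corpus, 1, 6)
        stricter = count_supported_kmers(corpus, 5, 4)
        assert set(stricter.records) <= set(base.records)
        for w, rec in stricter.records.items():
            assert rec == base[w]

    def test_workspace_is_a_permutation_after_evaluation(self, random_sequence):
        corpus = encode_corpus([random_sequence(9, 1000)])
        ws, root = init_root_range(corpus)
        before = sorted(ws)
        count_supported_kmers(corpus, 1, 5)
        ws2, _ = init_root_range(corpus)
        from collections import deque
        queue = deque([(root, "")])
        while queue:
            node, ctx = queue.popleft()
            _, children = evaluate_node(corpus, ws2, node, ctx, 5)
            queue.extend(children[:1])  # walk one spine, permuting as we go
        assert sorted(ws2) == before

    def test_invalid_parameters_rejected(self, cacac_corpus):
        with pytest.raises(ValueError):
            count_supported_kmers(cacac_corpus, 0, 3)
        with pytest.raises(ValueError):
            count_supported_kmers(cacac_corpus, 1, 0)
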