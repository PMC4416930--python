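"""Simple-path enumeration, maximality filtration, and length statistics."""

from __future__ import annotations

import pytest

from regcascade.cascades import (
    CascadeSet,
    PathExplosionError,
    cascade_length_stats,
    enumerate_simple_paths,
    filter_contained,
    mine_cascades,
    read_cascades_tsv,
    write_cascades_tsv,
)
from tests._oracles import naive_filter_contained, paths_by_pairwise_search, paths_by_permutation
from tests.conftest import chain_net, make_net, random_typed_net


class TestEnumerate:
    def test_single_chain_yields_one_path(self):
        net = chain_net("A", "B", "C")
        assert enumerate_simple_paths(net) == [("A", "B", "C")]

    def test_three_cycle_yields_three_rotations(self):
        net = make_net([("A", "B", "tf_tf"), ("B", "C", "tf_tf"), ("C", "A", "tf_tf")])
        got = set(enumerate_simple_paths(net))
        assert got == {("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B")}
        assert got == paths_by_permutation(net)

    def test_diamond_yields_two_branches(self):
        net = make_net(
            [("A", "B", "tf_tf"), ("A", "C", "tf_tf"), ("B", "D", "tf_tf"), ("C", "D", "tf_tf")]
        )
        assert set(enumerate_simple_paths(net)) == {("A", "B", "D"), ("A", "C", "D")}

    def test_max_len_bounds_path_length(self):
        net = chain_net("A", "B", "C", "D", "E")
        got = enumerate_simple_paths(net, min_len=3, max_len=4)
        assert all(3 <= len(p) <= 4 for p in got)
        assert ("A", "B", "C", "D", "E") not in got
        assert ("A", "B", "C", "D") in got

    def test_path_ceiling_raises_with_advice(self):
        net = chain_net("A", "B", "C", "D", "E", "F")
        with pytest.raises(PathExplosionError, match="max_len"):
            enumerate_simple_paths(net, max_paths=2)

    def test_min_len_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            enumerate_simple_paths(chain_net("A", "B"), min_len=1)


class TestFilterContained:
    def test_prefix_containment_filters_shorter(self):
        cs = filter_contained([("A", "B", "C"), ("A", "B", "C", "D")])
        assert cs.cascades == [("A", "B", "C", "D")]

    def test_cycle_rotations_all_retained(self):
        rotations = [("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B")]
        assert filter_contained(rotations).cascades == sorted(rotations)

    def test_incomparable_paths_both_retained(self):
        paths = [("A", "B", "D"), ("A", "C", "D")]
        assert filter_contained(paths).cascades == sorted(paths)

    def test_interior_window_containment(self):
        cs = filter_contained([("B", "C", "D"), ("A", "B", "C", "D", "E")])
        assert cs.cascades == [("A", "B", "C", "D", "E")]

    def test_gapped_mode_filters_noncontiguous_subsequence(self):
        paths = [("A", "B", "C"), ("A", "X", "B", "Y", "C")]
        assert filter_contained(paths, "contiguous").cascades == sorted(paths)
        assert filter_contained(paths, "gapped").cascades == [("A", "X", "B", "Y", "C")]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_contained([], "fuzzy")


class TestMineCascades:
    def test_five_node_chain_gives_single_maximal_cascade(self):
        cs = mine_cascades(chain_net("A", "B", "C", "D", "E"))
        assert cs.cascades == [("A", "B", "C", "D", "E")]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pairwise_search_oracle_on_random_digraphs(self, seed):
        net = random_typed_net(seed)
        mined = set(mine_cascades(net))
        assert mined == naive_filter_contained(paths_by_pairwise_search(net))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_permutation_oracle_on_tiny_digraphs(self, seed):
        net = random_typed_net(seed, n_tf=4, n_mirna=2, p=0.3)
        assert set(enumerate_simple_paths(net)) == paths_by_permutation(net)

    def test_every_cascade_is_a_valid_simple_path(self):
        net = random_typed_net(3)
        for c in mine_cascades(net):
            assert len(set(c)) == len(c) >= 3
            assert all(net.graph.has_edge(a, b) for a, b in zip(c, c[1:]))

    def test_maximality_no_output_path_contained_in_another(self):
        cs = mine_cascades(random_typed_net(5))
        got = set(cs)
        assert naive_filter_contained(got) == got

    def test_deterministic_ordering_across_reruns(self):
        net = random_typed_net(7)
        assert mine_cascades(net).cascades == mine_cascades(net).cascades

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_under_edge_addition(self, seed):
        # adding an edge never removes a maximal path: every old cascade is
        # either still emitted or contiguously contained in a new one
        def contained(p, q):
            return len(p) < len(q) and any(
                q[i : i + len(p)] == p for i in range(len(q) - len(p) + 1)
            )

        net = random_typed_net(seed, n_tf=5, n_mirna=3, p=0.2)
        before = set(mine_cascades(net))
        tfs = sorted(net.tfs)
        new = next(
            (a, b) for a in tfs for b in tfs if a != b and not net.graph.has_edge(a, b)
        )
        net.graph.add_edge(*new, edge_kind="tf_tf", provenance="added")
        after = set(mine_cascades(net))
        for p in before:
            assert p in after or any(contained(p, q) for q in after)


class TestLengthStats:
    def test_single_cascade(self):
        st = cascade_length_stats(CascadeSet([("A", "B", "C")]))
        assert (st.mean_length, st.max_length, st.histogram) == (3.0, 3, {3: 1})

    def test_mean_over_mixed_lengths(self):
        st = cascade_length_stats(CascadeSet([("A", "B", "C"), ("D", "E", "F", "G", "H")]))
        assert st.mean_length == 4.0 and st.max_length == 5

    def test_empty_set_flagged(self):
        st = cascade_length_stats(CascadeSet([]))
        assert st.mean_length is None and st.histogram == {}

    def test_histogram_sums_to_cascade_count(self):
        cs = mine_cascades(random_typed_net(11))
        st = cascade_length_stats(cs)
        assert sum(st.histogram.values()) == len(cs)


def test_tsv_round_trip(tmp_path):
    cs = mine_cascades(random_typed_net(2))
    path = tmp_path / "cascades.tsv"
    write_cascades_tsv(cs, path)
    assert read_cascades_tsv(path).cascades == cs.cascades
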