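"""Attractor search, basin landscapes and phenotype interpretation."""

import pytest

from cllrs.dynamics_attractors import (
    Attractor,
    classify_phenotype,
    exhaustive_attractors,
    find_attractor_from,
    fuse_landscape,
    phenotype_fractions,
    sampled_attractors,
)
from cllrs.network_core import NetworkState, parse_network
from cllrs.robustness_topology import random_nk_network


class TestFindAttractor:
    def test_swap_two_cycle(self, swap_net):
        att, transient = find_attractor_from(swap_net, NetworkState((0, 1)))
        assert att.length == 2 and transient == 0
        assert att.canonical_key == (1, 2)  # (1,0) encodes 1, (0,1) encodes 2

    def test_constant_net_short_transient(self):
        net = parse_network("targets, factors\nA, 1\nB, 0\n")
        att, transient = find_attractor_from(net, NetworkState((0, 1)))
        assert att.is_fixed_point and transient <= 1

    def test_start_on_fixed_point_has_zero_transient(self, swap_net):
        att, transient = find_attractor_from(swap_net, NetworkState((1, 1)))
        assert att.is_fixed_point and transient == 0

    def test_cycle_canonicalization_is_entry_invariant(self, swap_net):
        a1, _ = find_attractor_from(swap_net, NetworkState((0, 1)))
        a2, _ = find_attractor_from(swap_net, NetworkState((1, 0)))
        assert a1.canonical_key == a2.canonical_key


class TestExhaustive:
    def test_swap_landscape(self, swap_net):
        ls = exhaustive_attractors(swap_net)
        assert sum(ls.basin_counts) == 4
        by_key = dict(zip((a.canonical_key for a in ls.attractors), ls.basin_counts))
        assert by_key == {(0,): 1, (3,): 1, (1, 2): 2}

    def test_identity_network_all_fixed_points(self):
        net = parse_network("targets, factors\nA, A\nB, B\nC, C\n")
        ls = exhaustive_attractors(net)
        assert len(ls.attractors) == 8
        assert all(a.is_fixed_point for a in ls.attractors)
        assert set(ls.basin_counts) == {1}

    def test_basins_partition_state_space(self):
        net = random_nk_network(8, 2, seed=11)
        ls = exhaustive_attractors(net)
        assert sum(ls.basin_counts) == 2**8
        assert ls.exact

    def test_refuses_oversized_networks(self):
        net = random_nk_network(21, 2, seed=0)
        with pytest.raises(ValueError, match="sampl"):
            exhaustive_attractors(net)


class TestSampled:
    def test_swap_ratios_approach_truth(self, swap_net):
        ls = sampled_attractors(swap_net, 100_000, seed=3)
        ratios = dict(zip((a.canonical_key for a in ls.attractors), ls.basin_ratios))
        assert ratios[(1, 2)] == pytest.approx(0.5, abs=0.01)
        assert ratios[(0,)] == pytest.approx(0.25, abs=0.01)
        assert ratios[(3,)] == pytest.approx(0.25, abs=0.01)

    def test_single_sample(self, swap_net):
        ls = sampled_attractors(swap_net, 1, seed=0)
        assert len(ls.attractors) == 1 and ls.basin_ratios == (1.0,)

    def test_same_seed_reproduces_landscape(self, swap_net):
        a = sampled_attractors(swap_net, 5000, seed=42)
        b = sampled_attractors(swap_net, 5000, seed=42)
        assert a.attractor_keys() == b.attractor_keys()
        assert a.basin_counts == b.basin_counts

    def test_respects_fixed_nodes(self, repressor_net):
        ls = sampled_attractors(repressor_net.with_fixed({"R": 1}), 1000, seed=0)
        t_idx = repressor_net.index("T")
        for att in ls.attractors:
            assert all(s.bits[t_idx] == 0 for s in att.cycle)


INDICATOR_NET = parse_network(
    "targets, factors\n"
    "Anergy, Anergy\nSPhase, SPhase\nApoptosis, Apoptosis\nCCND1, CCND1\nCCNE1, CCNE1\n"
)

IND = {
    "anergy": "Anergy",
    "s_phase": "SPhase",
    "apoptosis": "Apoptosis",
    "ccnd1": "CCND1",
    "ccne1": "CCNE1",
}


def _att(*states):
    return Attractor.from_cycle([NetworkState(s) for s in states])


class TestPhenotypes:
    # bit order: (Anergy, SPhase, Apoptosis, CCND1, CCNE1)
    @pytest.mark.parametrize(
        "bits,label",
        [
            ((1, 0, 0, 0, 0), "anergy"),
            ((0, 1, 0, 1, 1), "proliferation"),
            ((0, 0, 0, 0, 0), "quiescent_G0"),
            ((0, 0, 1, 0, 0), "apoptosis"),
            ((0, 0, 0, 1, 1), "cell_cycle_alert"),
            ((1, 1, 1, 0, 0), "apoptosis"),  # precedence within a state
        ],
    )
    def test_fixed_point_labels(self, bits, label):
        call = classify_phenotype(_att(bits), INDICATOR_NET, IND)
        assert call.label == label

    def test_mixed_cycle_reports_mixed_with_fractions(self):
        att = _att((1, 0, 0, 0, 0), (0, 1, 0, 0, 0))
        call = classify_phenotype(att, INDICATOR_NET, IND)
        assert call.label == "mixed"
        assert call.indicator_activity["anergy"] == 0.5
        assert call.indicator_activity["s_phase"] == 0.5

    def test_missing_indicator_node_named_in_error(self, swap_net):
        att = _att((0, 0))
        with pytest.raises(KeyError, match="Anergy"):
            classify_phenotype(att, swap_net, IND)


class TestFuseAndFractions:
    def test_single_fixed_point_activities_equal_bits(self, repressor_net):
        ls = sampled_attractors(repressor_net.with_fixed({"R": 1}), 100, seed=0)
        fused = fuse_landscape(ls)
        assert fused == {"R": 1.0, "T": 0.0}

    def test_two_cycle_node_half_active(self, swap_net):
        ls = exhaustive_attractors(swap_net)
        fused = fuse_landscape(ls)
        # node A: ON in fixed point (1,1) basin 1/4, half-ON in the 2-cycle
        # basin 2/4 -> 0.25 + 0.25 = 0.5
        assert fused["A"] == pytest.approx(0.5)
        assert fused["B"] == pytest.approx(0.5)

    def test_fuse_invariant_to_attractor_ordering(self, swap_net):
        from dataclasses import replace

        ls = exhaustive_attractors(swap_net)
        perm = replace(
            ls,
            attractors=tuple(reversed(ls.attractors)),
            basin_counts=tuple(reversed(ls.basin_counts)),
        )
        assert fuse_landscape(ls) == fuse_landscape(perm)

    def test_fractions_weight_by_basin(self):
        ls = exhaustive_attractors(INDICATOR_NET)
        fr = phenotype_fractions(ls, IND)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_fractions_sum_to_one_on_random_nets(self):
        net = random_nk_network(
            10, 2, seed=5, node_names=["Anergy", "SPhase", "Apoptosis", "CCND1", "CCNE1"]
            + [f"x{i}" for i in range(5)]
        )
        fr = phenotype_fractions(exhaustive_attractors(net), IND)
        assert sum(fr.values()) == pytest.approx(1.0)
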