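"""Bit-flip robustness, random N-K generation and degree/power-law analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cllrs.network_core import NetworkState, parse_network
from cllrs.robustness_topology import (
    bitflip_response,
    degree_distribution,
    normalized_hamming,
    powerlaw_plausibility,
    random_nk_network,
    robustness_test,
    _sample_powerlaw,
)


class TestHamming:
    def test_identical_states(self):
        s = NetworkState((1, 0, 1))
        assert normalized_hamming(s, s) == 0.0

    def test_complement(self):
        assert normalized_hamming(NetworkState((1, 0)), NetworkState((0, 1))) == 1.0

    def test_one_of_ten(self):
        x = NetworkState((0,) * 10)
        y = NetworkState((1,) + (0,) * 9)
        assert normalized_hamming(x, y) == pytest.approx(0.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            normalized_hamming(NetworkState((0,)), NetworkState((0, 1)))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=16), st.data())
    def test_metric_properties(self, bits, data):
        x = NetworkState(tuple(bits))
        y = NetworkState(tuple(data.draw(st.lists(st.integers(0, 1), min_size=len(bits), max_size=len(bits)))))
        d = normalized_hamming(x, y)
        assert 0.0 <= d <= 1.0
        assert d == normalized_hamming(y, x)
        assert (d == 0) == (x == y)


class TestBitflipResponse:
    def test_constant_network_absorbs_flips(self):
        net = parse_network("targets, factors\nA, 1\nB, 0\nC, 1\n")
        assert np.all(bitflip_response(net, 200, seed=0) == 0.0)

    def test_identity_network_preserves_flip(self):
        net = parse_network("targets, factors\nA, A\nB, B\nC, C\nD, D\n")
        assert np.all(bitflip_response(net, 200, seed=0) == pytest.approx(0.25))

    def test_swap_network_moves_flip(self, swap_net):
        assert np.all(bitflip_response(swap_net, 200, seed=0) == pytest.approx(0.5))


class TestRandomNK:
    def test_every_function_references_k_distinct_nodes(self):
        net = random_nk_network(5, 2, seed=1)
        for name in net.nodes:
            assert len(net.functions[name].variables()) == 2

    def test_same_seed_identical_network(self):
        assert random_nk_network(6, 3, seed=9) == random_nk_network(6, 3, seed=9)

    def test_truth_tables_are_fair_coins(self):
        # ON-fraction of f(random state) over many generated 1-input functions
        rng = np.random.default_rng(0)
        on = 0
        trials = 3000
        for i in range(trials):
            net = random_nk_network(2, 1, seed=int(rng.integers(2**31)))
            state = NetworkState(tuple(rng.integers(0, 2, size=2)))
            on += net.functions[net.nodes[0]].evaluate(state.as_dict(net.nodes))
        assert on / trials == pytest.approx(0.5, abs=0.03)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            random_nk_network(3, 4, seed=0)


class TestDegrees:
    def test_swap_degrees(self, swap_net):
        d = degree_distribution(swap_net)
        assert d.in_degrees == (1, 1) and d.out_degrees == (1, 1)
        assert d.total_degrees == (2, 2)

    def test_isolated_constant_node(self):
        net = parse_network("targets, factors\nA, 1\nB, A\n")
        d = degree_distribution(net)
        assert d.in_degrees[0] == 0

    def test_handshake_identity(self, cll_card):
        d = degree_distribution(cll_card.network)
        assert sum(d.in_degrees) == sum(d.out_degrees)


class TestRobustnessTest:
    def test_constant_reference_is_maximally_robust(self):
        net = parse_network(
            "targets, factors\n" + "\n".join(f"x{i}, 1" for i in range(8)) + "\n"
        )
        res = robustness_test(net, n_networks=99, n_states=100, seed=0)
        assert res.observed_mean == 0.0
        assert res.p_value < 0.05

    def test_single_null_network_p_values(self, swap_net):
        res = robustness_test(swap_net, n_networks=1, n_states=50, seed=0)
        assert res.p_value in (0.5, 1.0)  # add-one corrected with n=1
        assert res.p_value_uncorrected in (0.0, 1.0)

    def test_invariant_to_node_relabeling(self):
        a = parse_network("targets, factors\nP, Q\nQ, P & Q\nR, !P\n")
        b = parse_network("targets, factors\nx, y\ny, x & y\nz, !x\n")
        ra = robustness_test(a, n_networks=30, n_states=100, seed=5)
        rb = robustness_test(b, n_networks=30, n_states=100, seed=5)
        assert ra.p_value == rb.p_value
        assert ra.observed_mean == rb.observed_mean


class TestPowerLaw:
    def test_alpha_recovery_single_run(self):
        rng = np.random.default_rng(10)
        degrees = _sample_powerlaw(1000, 2.5, 1, rng)
        fit = powerlaw_plausibility(degrees, n_bootstrap=100, seed=1)
        assert fit.alpha == pytest.approx(2.5, abs=0.3)
        assert fit.plausible

    def test_poisson_degrees_rejected(self):
        rng = np.random.default_rng(10)
        fit = powerlaw_plausibility(rng.poisson(4, size=1000), n_bootstrap=100, seed=1)
        assert fit.bootstrap_p <= 0.1

    def test_degenerate_degrees_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            powerlaw_plausibility([3] * 100, n_bootstrap=10, seed=0)

    def test_too_few_degrees_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_plausibility([1, 2, 3], n_bootstrap=10, seed=0)
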