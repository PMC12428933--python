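"""Fixture hub: toy landscapes, the reconstructed CLL/RS model, synthetic
expression generation and uniform state sampling."""

import numpy as np
import pytest

from cllrs.dynamics_attractors import (
    classify_phenotype,
    exhaustive_attractors,
    find_attractor_from,
    sampled_attractors,
)
from cllrs.synthetic_data import (
    CYCLIN_GENES,
    SCENARIOS,
    SyntheticExpressionSpec,
    export_fixtures,
    random_state,
    synth_expression,
)


class TestToyNetworks:
    def test_swap_ground_truth(self, toys):
        _net, ls = toys["swap"]
        assert sorted(ls.basin_counts, reverse=True) == [2, 1, 1]

    def test_constant_net_single_fixed_point(self, toys):
        net, ls = toys["constant"]
        assert len(ls.attractors) == 1
        assert ls.basin_counts == (2**net.n,)

    def test_fixture_landscapes_equal_exhaustive(self, toys):
        for name, (net, ls) in toys.items():
            fresh = exhaustive_attractors(net)
            assert ls.attractor_keys() == fresh.attractor_keys(), name
            assert ls.basin_counts == fresh.basin_counts, name


class TestReconstruction:
    def test_node_inventory(self, cll_card):
        net = cll_card.network
        for node in ("BCR", "TME", "NFAT", "AKT", "TP53", "MYC", "BMI1",
                     "SPhase", "Apoptosis", "Anergy", "CCND1", "CCNE1"):
            assert node in net.nodes
        assert net.input_nodes == ("BCR", "TME")

    def test_provenance_covers_every_rule(self, cll_card):
        assert set(cll_card.provenance) == set(cll_card.network.nodes)

    def test_canonical_start_is_bcr_only(self, cll_card):
        start = cll_card.canonical_start
        on = [n for n, b in zip(cll_card.network.nodes, start.bits) if b]
        assert on == ["BCR"]

    def test_unperturbed_trajectory_is_anergic(self, cll_card):
        net = cll_card.network.with_fixed(SCENARIOS["unperturbed"])
        att, _ = find_attractor_from(net, cll_card.canonical_start)
        call = classify_phenotype(att, net)
        assert call.label == "anergy"
        bits = att.cycle[0].as_dict(net.nodes)
        assert bits["NFAT"] == 1 and bits["AKT"] == 0 and bits["CD5"] == 1

    def test_bcl2_rescue_of_bcr_withdrawal(self, cll_card):
        # IgM withdrawal with BCL2 gain: neither apoptosis nor S phase
        net = cll_card.network.with_fixed(SCENARIOS["bcr_ko_bcl2_ki"])
        ls = sampled_attractors(net, 3000, seed=4)
        for att in ls.attractors:
            call = classify_phenotype(att, net)
            assert call.indicator_activity["apoptosis"] == 0.0
            assert call.indicator_activity["s_phase"] == 0.0


class TestSynthExpression:
    def test_same_seed_identical_matrix(self):
        spec = SyntheticExpressionSpec(n_genes=20, n_cells=50, seed=5)
        a, b = synth_expression(spec), synth_expression(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.truth, b.truth)

    def test_zero_fraction_tracks_dropout_and_flat_genes(self):
        spec = SyntheticExpressionSpec(n_genes=100, n_cells=400, dropout=0.3, seed=2)
        synth = synth_expression(spec)
        expected = spec.dropout + spec.n_flat_genes / spec.n_genes * (1 - spec.dropout)
        observed = (synth.values == 0).mean()
        assert observed == pytest.approx(expected, abs=0.02)

    def test_cyclins_planted_with_requested_mixing(self):
        spec = SyntheticExpressionSpec(seed=3, cyclin_pi=0.3)
        synth = synth_expression(spec)
        for g in CYCLIN_GENES:
            gi = synth.genes.index(g)
            assert synth.truth[gi].mean() == pytest.approx(0.3, abs=0.07)

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(ValueError):
            SyntheticExpressionSpec(mu_lo=3.0, mu_hi=1.0)
        with pytest.raises(ValueError):
            SyntheticExpressionSpec(dropout=1.5)


class TestRandomState:
    def test_length_and_reproducibility(self):
        s = random_state(12, seed=8)
        assert s.n == 12
        assert s == random_state(12, seed=8)

    def test_single_bit_on_fraction(self):
        on = sum(random_state(1, seed=i).bits[0] for i in range(2000))
        assert on / 2000 == pytest.approx(0.5, abs=0.04)


class TestFixtureExport:
    def test_export_writes_plain_text_bundle(self, tmp_path):
        export_fixtures(tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"toy_swap.bn", "cll_rs_reconstruction.bn", "cll_rs_provenance.tsv",
                "synthetic_expression.tsv", "synthetic_expression.mtx",
                "synthetic_truth.tsv"} <= names
        from cllrs.network_core import parse_network

        net = parse_network((tmp_path / "cll_rs_reconstruction.bn").read_text())
        assert net.n == 39
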