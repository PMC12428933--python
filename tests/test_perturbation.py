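"""Intervention machinery and the exhaustive KO/KI screen."""

from itertools import combinations, product

import pytest
from hypothesis import given, settings, strategies as st

from cllrs.dynamics_attractors import sampled_attractors
from cllrs.network_core import parse_network
from cllrs.perturbation_screen import (
    Intervention,
    ScreenCriteria,
    apply_interventions,
    enumerate_interventions,
    intervention_count,
    screen,
)


class TestApply:
    def test_ko_forces_value_after_one_step(self, swap_net):
        net = apply_interventions(swap_net, Intervention((("A", 0),)))
        ls = sampled_attractors(net, 200, seed=0)
        a_idx = net.index("A")
        assert all(s.bits[a_idx] == 0 for att in ls.attractors for s in att.cycle)

    def test_original_network_untouched(self, swap_net):
        apply_interventions(swap_net, Intervention((("A", 1),)))
        assert swap_net.fixed == {}

    def test_conflicting_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Intervention((("A", 1), ("A", 0)))

    def test_unknown_node_rejected(self, swap_net):
        with pytest.raises(KeyError):
            apply_interventions(swap_net, Intervention((("Z", 1),)))


class TestEnumeration:
    def test_model_scale_count(self):
        # 49 screenable nodes, up to double hits: 98 + 4704 = 4802 candidates
        assert intervention_count(49, 2) == 4802

    def test_single_node(self):
        ivs = enumerate_interventions(1, 1)
        assert [iv.as_dict() for iv in ivs] == [{"n0": 0}, {"n0": 1}]

    def test_five_choose_two(self):
        assert len(enumerate_interventions(5, 2)) == 50  # 5*2 + 10*4

    def test_matches_brute_force(self):
        names = ["a", "b", "c"]
        got = {tuple(sorted(iv.as_dict().items())) for iv in enumerate_interventions(names, 2)}
        want = set()
        for size in (1, 2):
            for combo in combinations(names, size):
                for vals in product((0, 1), repeat=size):
                    want.add(tuple(sorted(zip(combo, vals))))
        assert got == want

    def test_deterministic_order(self):
        assert [iv.describe() for iv in enumerate_interventions(2, 1)] == [
            "n0:KO",
            "n0:KI",
            "n1:KO",
            "n1:KI",
        ]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c=st.integers(1, 10), data=st.data())
    def test_count_law(self, c, data):
        m = data.draw(st.integers(1, c))
        ivs = enumerate_interventions(c, m)
        assert len(ivs) == intervention_count(c, m)
        assert len({iv.assignments for iv in ivs}) == len(ivs)  # no duplicates

    def test_m_larger_than_c_rejected(self):
        with pytest.raises(ValueError):
            enumerate_interventions(3, 4)


class TestCriteria:
    def test_require_and_forbid_same_label_rejected(self):
        with pytest.raises(ValueError, match="required and forbidden"):
            ScreenCriteria(
                forbidden_phenotypes=frozenset({"apoptosis"}),
                required_phenotype=("apoptosis", 0.5),
            )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ScreenCriteria(forbidden_phenotypes=frozenset({"zombie"}))


class TestScreen:
    @pytest.fixture()
    def indicator_repressor(self):
        # repressor circuit padded with the indicator nodes the classifier needs
        return parse_network(
            "targets, factors\n"
            "R, R\nT, !R\n"
            "Anergy, 0\nSPhase, 0\nApoptosis, 0\nCCND1, 0\nCCNE1, 0\n"
        )

    def test_repressor_screen_selects_t_forcing_interventions(self, indicator_repressor):
        criteria = ScreenCriteria(node_constraints={"T": 1})
        hits = screen(
            indicator_repressor,
            criteria,
            m=1,
            basin_method="exhaustive",
            candidate_nodes=["R", "T"],
        )
        names = {iv.describe() for iv, _fr in hits}
        assert "R:KO" in names and "T:KI" in names and "R:KI" not in names

    def test_no_constraints_passes_everything(self, indicator_repressor):
        hits = screen(
            indicator_repressor,
            ScreenCriteria(),
            m=2,
            basin_method="exhaustive",
            candidate_nodes=["R", "T"],
        )
        assert len(hits) == intervention_count(2, 2)

    def test_m1_hits_contained_in_m2_candidates(self, indicator_repressor):
        criteria = ScreenCriteria(node_constraints={"T": 1})
        h1 = {iv.assignments for iv, _ in screen(
            indicator_repressor, criteria, m=1, basin_method="exhaustive",
            candidate_nodes=["R", "T"])}
        c2 = {iv.assignments for iv in enumerate_interventions(["R", "T"], 2)}
        assert h1 <= c2

    def test_exhaustive_and_sampled_agree(self, indicator_repressor):
        criteria = ScreenCriteria(node_constraints={"T": 1})
        kw = dict(m=2, candidate_nodes=["R", "T"])
        exact = {iv.assignments for iv, _ in screen(
            indicator_repressor, criteria, basin_method="exhaustive", **kw)}
        sampled = {iv.assignments for iv, _ in screen(
            indicator_repressor, criteria, basin_method="sampled",
            n_samples=2000, seed=7, **kw)}
        assert exact == sampled
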