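"""Deterministic trajectory recording and per-step attribution of node flips.

Under the synchronous scheme a start state fixes the whole path to its
attractor.  Recording that path and asking, for every node that changes
value, *which regulator change caused it* recovers the regulatory cascades
behind a phenotype: e.g. from the BCR-stimulated all-off start, PKC
activation silences GSK3B, NFAT turns on and locks the anergy program.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from cllrs.dynamics_attractors import (
    Attractor,
    PhenotypeCall,
    classify_phenotype,
    find_attractor_from,
)
from cllrs.network_core import And, BooleanNetwork, NetworkState, Or, synchronous_step


@dataclass(frozen=True)
class FlipAttribution:
    """One node flip and the regulator changes that explain it."""

    step: int  # the flip happened between states[step-1] and states[step]
    node: str
    old: int
    new: int
    #: regulators referenced by the node's function with their values at the
    #: evaluated state (states[step-1])
    regulator_values: dict[str, int]
    #: minimal set of changed regulators whose change flips the function
    #: output (each verified by toggling it back individually); empty when the
    #: flip is jointly caused by several simultaneous changes
    caused_by: tuple[str, ...]
    #: changed regulators, when no single toggle-back explains the flip
    joint_changes: tuple[str, ...]
    #: index of the top-level clause of the function whose truth value changed
    changed_clauses: tuple[int, ...]
    intervention: bool = False


@dataclass(frozen=True)
class Trajectory:
    """States from start to attractor entry plus one full attractor cycle."""

    net: BooleanNetwork
    states: tuple[NetworkState, ...]
    attractor_entry_index: int
    attractor: Attractor
    phenotype: PhenotypeCall | None

    @property
    def transient_length(self) -> int:
        return self.attractor_entry_index

    def flips(self) -> list[tuple[int, str, int, int]]:
        """(step, node, old, new) for every bit differing between consecutive
        states."""
        out = []
        for t in range(1, len(self.states)):
            prev, cur = self.states[t - 1], self.states[t]
            for i, name in enumerate(self.net.nodes):
                if prev.bits[i] != cur.bits[i]:
                    out.append((t, name, prev.bits[i], cur.bits[i]))
        return out


def trajectory(
    net: BooleanNetwork,
    start: NetworkState,
    indicators=None,
    classify: bool = True,
) -> Trajectory:
    """Record the deterministic path from ``start`` into its attractor."""
    attractor, transient = find_attractor_from(net, start)
    states = [start]
    cur = start
    for _ in range(transient + attractor.length):
        cur = synchronous_step(net, cur)
        states.append(cur)
    phenotype = None
    if classify:
        try:
            phenotype = classify_phenotype(attractor, net, indicators)
        except KeyError:
            phenotype = None  # toy networks without indicator nodes
    return Trajectory(
        net=net,
        states=tuple(states[: transient + attractor.length + 1]),
        attractor_entry_index=transient,
        attractor=attractor,
        phenotype=phenotype,
    )


def _top_level_clauses(expr) -> Sequence:
    if isinstance(expr, (And, Or)):
        return expr.args
    return (expr,)


def attribute_flips(net: BooleanNetwork, traj: Trajectory) -> list[FlipAttribution]:
    """Explain every flip along the trajectory by its regulator changes.

    For a node flipping at step t the function was evaluated on
    ``states[t-1]``; a regulator is causal when it changed between
    ``states[t-2]`` and ``states[t-1]`` and toggling it back (alone) restores
    the old output.  Flips of intervention-fixed nodes and flips at step 1
    (forced by the chosen start state) are tagged accordingly.
    """
    out: list[FlipAttribution] = []
    nodes = net.nodes
    for t, node, old, new in traj.flips():
        if node in net.fixed:
            out.append(
                FlipAttribution(
                    step=t,
                    node=node,
                    old=old,
                    new=new,
                    regulator_values={},
                    caused_by=(),
                    joint_changes=(),
                    changed_clauses=(),
                    intervention=True,
                )
            )
            continue
        f = net.functions[node]
        eval_state = traj.states[t - 1].as_dict(nodes)
        regs = sorted(f.variables())
        reg_values = {r: eval_state[r] for r in regs}
        caused: list[str] = []
        joint: tuple[str, ...] = ()
        changed_clauses: list[int] = []
        if t >= 2:
            prev_state = traj.states[t - 2].as_dict(nodes)
            changed = [r for r in regs if prev_state[r] != eval_state[r]]
            for r in changed:
                toggled = dict(eval_state)
                toggled[r] = 1 - toggled[r]
                if f.evaluate(toggled) != new:
                    caused.append(r)
            if changed and not caused:
                joint = tuple(changed)
            for ci, clause in enumerate(_top_level_clauses(f)):
                if clause.evaluate(prev_state) != clause.evaluate(eval_state):
                    changed_clauses.append(ci)
        out.append(
            FlipAttribution(
                step=t,
                node=node,
                old=old,
                new=new,
                regulator_values=reg_values,
                caused_by=tuple(caused),
                joint_changes=joint,
                changed_clauses=tuple(changed_clauses),
            )
        )
    return out


def active_regulation_edges(
    net: BooleanNetwork, attributions: Sequence[FlipAttribution]
) -> list[tuple[str, str, int]]:
    """(regulator, target, step) edge list of the causal regulations, suitable
    for Graphviz-style rendering of the trajectory circuits."""
    edges = []
    for a in attributions:
        for r in a.caused_by or a.joint_changes:
            edges.append((r, a.node, a.step))
    return edges
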