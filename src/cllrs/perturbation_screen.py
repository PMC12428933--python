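"""Knockout/knockin machinery and exhaustive single/double intervention screens.

An intervention clamps up to ``m`` nodes to constant values (KI = 1, KO = 0)
throughout the simulation.  The screen enumerates every combination — in
total ``sum_{i=1..m} C(c, i) * 2^i`` candidates for ``c`` screenable nodes —
simulates each perturbed landscape, and keeps the interventions whose
long-term behaviour satisfies the requested criteria (e.g. for driver
screening: eliminate the anergic attractor and force S phase fully on; for
drug-target screening: induce apoptosis or delete the proliferative
attractors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from typing import Iterable, Mapping, Sequence

from cllrs.dynamics_attractors import (
    AttractorLandscape,
    PHENOTYPE_LABELS,
    exhaustive_attractors,
    phenotype_fractions,
    sampled_attractors,
)
from cllrs.network_core import BooleanNetwork


@dataclass(frozen=True)
class Intervention:
    """A set of (node, value) clamps, at most one per node."""

    assignments: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("intervention must assign at least one node")
        nodes = [n for n, _v in self.assignments]
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if nodes.count(n) > 1})
            raise ValueError(f"conflicting duplicate assignment(s) for: {dupes}")
        for _n, v in self.assignments:
            if v not in (0, 1):
                raise ValueError("intervention values must be 0 (KO) or 1 (KI)")

    @property
    def size(self) -> int:
        return len(self.assignments)

    def as_dict(self) -> dict[str, int]:
        return dict(self.assignments)

    def describe(self) -> str:
        return "+".join(
            f"{node}:{'KI' if value else 'KO'}" for node, value in self.assignments
        )


@dataclass(frozen=True)
class ScreenCriteria:
    """Constraints a perturbed attractor landscape must satisfy.

    ``forbidden_phenotypes``: labels whose basin fraction must be exactly 0.
    ``required_phenotype``: optional (label, minimum basin fraction).
    ``node_constraints``: node -> value that must hold in every cycle state of
    every attractor (e.g. ``{"SPhase": 1}`` demands fully active S phase).
    """

    forbidden_phenotypes: frozenset[str] = frozenset()
    required_phenotype: tuple[str, float] | None = None
    node_constraints: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "forbidden_phenotypes", frozenset(self.forbidden_phenotypes)
        )
        object.__setattr__(self, "node_constraints", dict(self.node_constraints))
        for label in self.forbidden_phenotypes:
            if label not in PHENOTYPE_LABELS:
                raise ValueError(f"unknown phenotype label {label!r}")
        if self.required_phenotype is not None:
            label, min_frac = self.required_phenotype
            if label not in PHENOTYPE_LABELS:
                raise ValueError(f"unknown phenotype label {label!r}")
            if not 0.0 <= min_frac <= 1.0:
                raise ValueError("required basin fraction must lie in [0, 1]")
            if label in self.forbidden_phenotypes:
                raise ValueError(
                    f"phenotype {label!r} cannot be both required and forbidden"
                )
        for node, value in self.node_constraints.items():
            if value not in (0, 1):
                raise ValueError(f"node constraint for {node!r} must be 0 or 1")

    def satisfied_by(
        self, landscape: AttractorLandscape, fractions: Mapping[str, float]
    ) -> bool:
        for label in self.forbidden_phenotypes:
            if fractions.get(label, 0.0) > 0.0:
                return False
        if self.required_phenotype is not None:
            label, min_frac = self.required_phenotype
            if fractions.get(label, 0.0) < min_frac:
                return False
        net = landscape.net
        for node, value in self.node_constraints.items():
            i = net.index(node)
            for attractor in landscape.attractors:
                if any(s.bits[i] != value for s in attractor.cycle):
                    return False
        return True


def apply_interventions(
    net: BooleanNetwork, intervention: Intervention
) -> BooleanNetwork:
    """Return a copy of the network with the intervention's clamps applied."""
    return net.with_fixed(intervention.as_dict())


def enumerate_interventions(
    nodes: int | Sequence[str], m: int
) -> list[Intervention]:
    """All interventions of size 1..m over the given nodes, in a deterministic
    lexicographic order (by node indices, then values).

    The list length equals ``sum_{i=1..m} C(c, i) * 2^i``.
    """
    if isinstance(nodes, int):
        if nodes < 1:
            raise ValueError("node count must be >= 1")
        names: Sequence[str] = tuple(f"n{i}" for i in range(nodes))
    else:
        names = tuple(nodes)
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        if not names:
            raise ValueError("node list must be non-empty")
    c = len(names)
    if not 1 <= m <= c:
        raise ValueError(f"intervention size m={m} must satisfy 1 <= m <= {c}")
    out: list[Intervention] = []
    for size in range(1, m + 1):
        for combo in combinations(range(c), size):
            for values in product((0, 1), repeat=size):
                out.append(
                    Intervention(tuple((names[i], v) for i, v in zip(combo, values)))
                )
    assert len(out) == intervention_count(c, m)
    return out


def intervention_count(c: int, m: int) -> int:
    """Closed form ``sum_{i=1..m} C(c, i) * 2^i`` for the candidate count."""
    return sum(comb(c, i) * 2**i for i in range(1, m + 1))


def screen(
    net: BooleanNetwork,
    criteria: ScreenCriteria,
    m: int = 2,
    basin_method: str = "sampled",
    n_samples: int = 10_000,
    seed: int | None = None,
    candidate_nodes: Sequence[str] | None = None,
    exclude_nodes: Iterable[str] = (),
) -> list[tuple[Intervention, dict[str, float]]]:
    """Exhaustively test interventions; return those matching the criteria.

    Each accepted intervention is paired with the phenotype basin fractions of
    its perturbed landscape.  ``exclude_nodes`` supports curation of
    biologically nonmeaningful targets (e.g. indicator nodes); with sampled
    basins a phenotype counts as eliminated when no sampled start reaches it,
    so report ``n_samples`` with any result.
    """
    if basin_method not in ("exhaustive", "sampled"):
        raise ValueError("basin_method must be 'exhaustive' or 'sampled'")
    exclude = set(exclude_nodes)
    unknown = exclude - set(net.nodes)
    if unknown:
        raise KeyError(f"unknown excluded node(s): {sorted(unknown)}")
    if candidate_nodes is None:
        candidate_nodes = [n for n in net.nodes if n not in exclude and n not in net.fixed]
    else:
        candidate_nodes = [n for n in candidate_nodes if n not in exclude]
        unknown = set(candidate_nodes) - set(net.nodes)
        if unknown:
            raise KeyError(f"unknown candidate node(s): {sorted(unknown)}")
    hits: list[tuple[Intervention, dict[str, float]]] = []
    for k, intervention in enumerate(enumerate_interventions(candidate_nodes, m)):
        perturbed = apply_interventions(net, intervention)
        if basin_method == "exhaustive":
            landscape = exhaustive_attractors(perturbed)
        else:
            sub_seed = None if seed is None else (seed * 9973 + k) % (2**31)
            landscape = sampled_attractors(perturbed, n_samples, seed=sub_seed)
        fractions = phenotype_fractions(landscape)
        if criteria.satisfied_by(landscape, fractions):
            hits.append((intervention, fractions))
    return hits
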