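"""Attractor detection, basin landscapes and phenotype classification.

Under a synchronous update every trajectory eventually enters a recurring
sequence of states (an attractor: a fixed point if of length 1, otherwise a
cycle).  The set of states converging to an attractor is its basin of
attraction.  For small networks the landscape is built exhaustively over all
2^n states; for larger ones attractors are discovered and basins estimated
from uniformly drawn random start states, mirroring the 10-million-start
estimation strategy used for the 49-node CLL model.

Attractors of the CLL/RS model are interpreted through indicator nodes:

* ``anergy`` — NFAT active with NF-kB, AKT and S phase inactive;
* ``proliferation`` — the S-phase node (E2F and CCNE1 jointly active);
* ``apoptosis`` — BIM active with AKT inactive;
* ``cell_cycle_alert`` — cyclin D and cyclin E active without S-phase entry;
* ``quiescent_G0`` — anergy, S phase, cyclins and apoptosis all inactive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from cllrs._engine import CompiledNetwork, attractor_map_exhaustive, find_cycles_batch
from cllrs.network_core import BooleanNetwork, NetworkState, synchronous_step

#: Phenotype labels in decreasing precedence within a single state.
PHENOTYPE_LABELS = (
    "apoptosis",
    "proliferation",
    "cell_cycle_alert",
    "anergy",
    "quiescent_G0",
    "mixed",
)

#: Default indicator-role -> node-name mapping for the packaged CLL/RS model.
DEFAULT_INDICATORS: dict[str, str] = {
    "anergy": "Anergy",
    "s_phase": "SPhase",
    "apoptosis": "Apoptosis",
    "ccnd1": "CCND1",
    "ccne1": "CCNE1",
}

EXHAUSTIVE_LIMIT = 20  # 2^20 ~ 1e6 states keeps full enumeration desk-scale


@dataclass(frozen=True)
class Attractor:
    """A recurring cycle of states, rotated so the minimal encoding is first."""

    cycle: tuple[NetworkState, ...]

    @property
    def length(self) -> int:
        return len(self.cycle)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.cycle) == 1

    @property
    def canonical_key(self) -> tuple[int, ...]:
        return tuple(s.encoding for s in self.cycle)

    @classmethod
    def from_cycle(cls, states: Sequence[NetworkState]) -> "Attractor":
        encodings = [s.encoding for s in states]
        pivot = encodings.index(min(encodings))
        rotated = tuple(states[pivot:]) + tuple(states[:pivot])
        return cls(rotated)

    def activity(self, net: BooleanNetwork, node: str) -> float:
        """Mean ON fraction of ``node`` over the cycle states."""
        i = net.index(node)
        return sum(s.bits[i] for s in self.cycle) / len(self.cycle)


@dataclass(frozen=True)
class PhenotypeCall:
    """Phenotype label of an attractor plus per-indicator activity fractions."""

    label: str
    indicator_activity: Mapping[str, float]
    state_labels: tuple[str, ...]

    def __post_init__(self):
        if self.label not in PHENOTYPE_LABELS:
            raise ValueError(f"unknown phenotype label {self.label!r}")


@dataclass(frozen=True)
class AttractorLandscape:
    """Attractors with basin counts/ratios for one simulation condition."""

    net: BooleanNetwork
    attractors: tuple[Attractor, ...]
    basin_counts: tuple[int, ...]
    exact: bool
    n_samples: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if len(self.attractors) != len(self.basin_counts):
            raise ValueError("one basin count per attractor required")
        total = sum(self.basin_counts)
        if self.exact and total != 2**self.net.n:
            raise ValueError("exhaustive basin counts must partition the state space")

    @property
    def basin_ratios(self) -> tuple[float, ...]:
        total = sum(self.basin_counts)
        return tuple(c / total for c in self.basin_counts)

    def attractor_keys(self) -> frozenset[tuple[int, ...]]:
        return frozenset(a.canonical_key for a in self.attractors)

    def to_json(self) -> str:
        payload = {
            "nodes": list(self.net.nodes),
            "exact": self.exact,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "attractors": [
                {
                    "cycle_encodings": list(a.canonical_key),
                    "length": a.length,
                    "basin_count": c,
                    "basin_ratio": r,
                    "states": [s.as_dict(self.net.nodes) for s in a.cycle],
                }
                for a, c, r in zip(self.attractors, self.basin_counts, self.basin_ratios)
            ],
        }
        return json.dumps(payload, indent=2)


def _cycle_from_state(net: BooleanNetwork, state: NetworkState) -> list[NetworkState]:
    """Walk the cycle containing ``state`` (which must lie on a cycle)."""
    cycle = [state]
    cur = synchronous_step(net, state)
    while cur != state:
        cycle.append(cur)
        cur = synchronous_step(net, cur)
    return cycle


def find_attractor_from(
    net: BooleanNetwork,
    start: NetworkState,
    max_steps: int | None = None,
) -> tuple[Attractor, int]:
    """Iterate from ``start`` until a state repeats; return (attractor, transient).

    ``transient`` is the number of steps taken before the first cycle state.
    """
    if max_steps is None:
        max_steps = max(2**net.n if net.n <= EXHAUSTIVE_LIMIT else 0, 100_000)
    seen: dict[NetworkState, int] = {start: 0}
    path = [start]
    cur = start
    for step_i in range(1, max_steps + 2):
        cur = synchronous_step(net, cur)
        if cur in seen:
            entry = seen[cur]
            return Attractor.from_cycle(path[entry:]), entry
        seen[cur] = step_i
        path.append(cur)
    raise RuntimeError(
        "iteration cap exceeded without revisiting a state; this indicates an "
        "implementation bug since synchronous dynamics must cycle"
    )


def exhaustive_attractors(net: BooleanNetwork) -> AttractorLandscape:
    """Exact landscape over all 2^n states (refuses above the size limit)."""
    if net.n > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration limited to n <= {EXHAUSTIVE_LIMIT} "
            f"(got n={net.n}); use sampled_attractors instead"
        )
    cnet = CompiledNetwork(net)
    canon = attractor_map_exhaustive(cnet)
    reps, counts = np.unique(canon, return_counts=True)
    attractors, basin_counts = _build_attractors(net, reps, counts)
    return AttractorLandscape(net, attractors, basin_counts, exact=True)


def sampled_attractors(
    net: BooleanNetwork,
    n_samples: int,
    seed: int | None = None,
) -> AttractorLandscape:
    """Landscape estimated from uniformly drawn random starting states.

    Basin ratios are the fractions of starts converging to each attractor;
    attractors whose basin is never hit are not discovered (report
    ``n_samples`` alongside results for this coverage caveat).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cnet = CompiledNetwork(net)
    rng = np.random.default_rng(seed)
    starts = cnet.random_states(n_samples, rng)
    canon, _period = find_cycles_batch(cnet, starts)
    reps, counts = np.unique(canon, return_counts=True)
    attractors, basin_counts = _build_attractors(net, reps, counts)
    return AttractorLandscape(
        net, attractors, basin_counts, exact=False, n_samples=n_samples, seed=seed
    )


def _build_attractors(
    net: BooleanNetwork, reps: np.ndarray, counts: np.ndarray
) -> tuple[tuple[Attractor, ...], tuple[int, ...]]:
    attractors = []
    for rep in reps:
        state = NetworkState.from_encoding(int(rep), net.n)
        attractors.append(Attractor.from_cycle(_cycle_from_state(net, state)))
    order = np.argsort(-counts, kind="stable")  # largest basin first
    attractors = tuple(attractors[i] for i in order)
    basin_counts = tuple(int(counts[i]) for i in order)
    return attractors, basin_counts


# ---------------------------------------------------------------------------
# Phenotype interpretation
# ---------------------------------------------------------------------------


def _state_label(bits: Mapping[str, int]) -> str:
    if bits["apoptosis"]:
        return "apoptosis"
    if bits["s_phase"]:
        return "proliferation"
    if bits["ccnd1"] and bits["ccne1"]:
        return "cell_cycle_alert"
    if bits["anergy"]:
        return "anergy"
    return "quiescent_G0"


def classify_phenotype(
    attractor: Attractor,
    net: BooleanNetwork,
    indicators: Mapping[str, str] | None = None,
) -> PhenotypeCall:
    """Assign a phenotype label from the indicator-node activity over the cycle.

    Each cycle state receives a label by precedence (apoptosis > proliferation
    > cell-cycle alert > anergy > quiescent G0); a cycle whose states disagree
    is labelled ``mixed``, with per-indicator activity fractions reported so
    stricter callers can be layered on top.
    """
    indicators = dict(DEFAULT_INDICATORS if indicators is None else indicators)
    missing_roles = {"anergy", "s_phase", "apoptosis", "ccnd1", "ccne1"} - set(indicators)
    if missing_roles:
        raise KeyError(f"missing indicator role(s): {sorted(missing_roles)}")
    for role, node in indicators.items():
        if node not in net.nodes:
            raise KeyError(f"indicator node {node!r} (role {role!r}) not in network")
    idx = {role: net.index(node) for role, node in indicators.items()}
    state_labels = []
    for state in attractor.cycle:
        bits = {role: state.bits[i] for role, i in idx.items()}
        state_labels.append(_state_label(bits))
    label = state_labels[0] if len(set(state_labels)) == 1 else "mixed"
    activity = {
        role: sum(s.bits[i] for s in attractor.cycle) / attractor.length
        for role, i in idx.items()
    }
    return PhenotypeCall(label, activity, tuple(state_labels))


def fuse_landscape(landscape: AttractorLandscape) -> dict[str, float]:
    """Basin-weighted mean activity per node (the collapsed-heatmap values).

    activity(node) = sum over attractors of basin_ratio x mean ON fraction of
    the node over that attractor's cycle.
    """
    if not landscape.attractors:
        raise ValueError("landscape has no attractors")
    net = landscape.net
    fused = dict.fromkeys(net.nodes, 0.0)
    for attractor, ratio in zip(landscape.attractors, landscape.basin_ratios):
        for i, node in enumerate(net.nodes):
            mean_on = sum(s.bits[i] for s in attractor.cycle) / attractor.length
            fused[node] += ratio * mean_on
    return fused


def phenotype_fractions(
    landscape: AttractorLandscape,
    indicators: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Basin fraction per phenotype label (the pie-chart representation)."""
    fractions: dict[str, float] = {}
    for attractor, ratio in zip(landscape.attractors, landscape.basin_ratios):
        call = classify_phenotype(attractor, landscape.net, indicators)
        fractions[call.label] = fractions.get(call.label, 0.0) + ratio
    return fractions
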