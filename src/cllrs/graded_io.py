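"""Graded two-input input-output analysis producing activity heatmap grids.

The Boolean on/off semantics is extended to graded input activities: an input
node is forced to a duty cycle of ON steps — a discrete percentage of the
simulated time steps — while the rest of the network updates synchronously
from random starting states.  The activity of an output node is its mean ON
fraction over the final window of the simulation, averaged across starts.
Scanning two inputs over percentage grids yields the response surfaces used
to study, e.g., how NOTCH1 and TP53 signal intensities shape MYC, BMI1 and
CITED2 output levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from cllrs._engine import CompiledNetwork
from cllrs.network_core import BooleanNetwork


@dataclass(frozen=True)
class InputSchedule:
    """A graded input: ``node`` is ON for ``activity_percent``% of the steps.

    The realisation over ``T`` steps contains exactly ``round(percent * T /
    100)`` ON steps; their placement is drawn by a seeded uniform shuffle,
    freshly per starting state, to avoid phase-locking artefacts of a
    deterministic block layout.
    """

    node: str
    activity_percent: int

    def __post_init__(self):
        if not 1 <= int(self.activity_percent) <= 100:
            raise ValueError("activity_percent must lie in 1..100")

    def n_on(self, T: int) -> int:
        return int(round(self.activity_percent * T / 100.0))

    def realize(self, T: int, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        """(n_starts, T) boolean matrix with the exact ON count per row."""
        n_on = self.n_on(T)
        base = np.zeros(T, dtype=bool)
        base[:n_on] = True
        out = np.empty((n_starts, T), dtype=bool)
        for i in range(n_starts):
            out[i] = rng.permutation(base)
        return out


@dataclass(frozen=True)
class IOGrid:
    """Response surfaces over two input percentage axes."""

    input1: str
    input2: str
    percents1: tuple[int, ...]
    percents2: tuple[int, ...]
    outputs: tuple[str, ...]
    #: activity[node] is a (len(percents1), len(percents2)) matrix in [0, 1]
    activity: Mapping[str, np.ndarray]
    n_starts: int
    T: int
    window: int
    seed: int | None

    def to_long_frame(self):
        """Long-format table (input1_pct, input2_pct, node, activity)."""
        import pandas as pd

        rows = []
        for node in self.outputs:
            mat = self.activity[node]
            for i, p1 in enumerate(self.percents1):
                for j, p2 in enumerate(self.percents2):
                    rows.append((p1, p2, node, mat[i, j]))
        return pd.DataFrame(
            rows, columns=["input1_pct", "input2_pct", "node", "activity"]
        )


def graded_simulation(
    net: BooleanNetwork,
    schedules: Sequence[InputSchedule],
    n_starts: int = 250,
    T: int = 500,
    window: int = 100,
    seed: int | None = None,
) -> dict[str, float]:
    """Mean last-window ON fraction per node under 1-2 graded input schedules.

    Each start draws a random initial state and a fresh duty-cycle
    realisation per scheduled input; scheduled nodes take their realised
    value at every step, overriding their functions.
    """
    if not 1 <= len(schedules) <= 2:
        raise ValueError("provide one or two input schedules")
    names = [s.node for s in schedules]
    if len(set(names)) != len(names):
        raise ValueError("scheduled input nodes must be distinct")
    for s in schedules:
        if s.node not in net.nodes:
            raise KeyError(f"unknown node {s.node!r}")
        if s.node in net.fixed:
            raise ValueError(
                f"node {s.node!r} is fixed by an intervention and cannot be scheduled"
            )
    if window > T:
        raise ValueError("window must not exceed T")
    cnet = CompiledNetwork(net)
    rng = np.random.default_rng(seed)
    states = cnet.random_states(n_starts, rng)
    realizations = {s.node: s.realize(T, n_starts, rng) for s in schedules}
    masks = {node: np.uint64(1) << np.uint64(net.index(node)) for node in names}

    counts = np.zeros((n_starts, net.n), dtype=np.int64)
    shifts = np.arange(net.n, dtype=np.uint64)
    for t in range(T):
        states = cnet.step(states)
        for node in names:
            bit = realizations[node][:, t]
            states = np.where(bit, states | masks[node], states & ~masks[node])
        if t >= T - window:
            counts += ((states[:, None] >> shifts) & np.uint64(1)).astype(np.int64)
    activity = counts.sum(axis=0) / (n_starts * window)
    return {node: float(a) for node, a in zip(net.nodes, activity)}


def io_grid(
    net: BooleanNetwork,
    input1: str,
    input2: str,
    resolution: int | Sequence[int] = 5,
    outputs: Sequence[str] = (),
    n_starts: int = 250,
    T: int = 500,
    window: int = 100,
    seed: int | None = None,
) -> IOGrid:
    """Simulate every combination of the two inputs' percentage levels.

    ``resolution`` is either a grid step that divides 100 (levels step, 2*step,
    ..., 100) or an explicit list of percentages.  Per-cell seeds are derived
    from the master seed and the cell coordinates, so cells are independent
    and evaluation order is immaterial.  With no explicit ``outputs`` all
    non-input nodes are reported.
    """
    if input1 == input2:
        raise ValueError("the two graded inputs must differ")
    if isinstance(resolution, (int, np.integer)):
        if resolution < 1 or 100 % int(resolution) != 0:
            raise ValueError("resolution must divide 100")
        percents = tuple(range(int(resolution), 101, int(resolution)))
    else:
        percents = tuple(int(p) for p in resolution)
        if not percents or any(not 1 <= p <= 100 for p in percents):
            raise ValueError("explicit percent list must lie in 1..100")
    outputs = tuple(outputs) or tuple(
        n for n in net.nodes if n not in (input1, input2)
    )
    unknown = set(outputs) - set(net.nodes)
    if unknown:
        raise KeyError(f"unknown output node(s): {sorted(unknown)}")
    activity = {node: np.zeros((len(percents), len(percents))) for node in outputs}
    for i, p1 in enumerate(percents):
        for j, p2 in enumerate(percents):
            cell_seed = None
            if seed is not None:
                cell_seed = (seed * 1_000_003 + p1 * 101 + p2) % (2**31)
            result = graded_simulation(
                net,
                [InputSchedule(input1, p1), InputSchedule(input2, p2)],
                n_starts=n_starts,
                T=T,
                window=window,
                seed=cell_seed,
            )
            for node in outputs:
                activity[node][i, j] = result[node]
    return IOGrid(
        input1=input1,
        input2=input2,
        percents1=percents,
        percents2=percents,
        outputs=outputs,
        activity=activity,
        n_starts=n_starts,
        T=T,
        window=window,
        seed=seed,
    )
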