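"""Desk-scale validation benchmarks used by the test suite and the
reproduction script.

Each function runs one self-contained computation on synthetic study
conditions — oracle equivalence of the sampling estimator, robustness-test
calibration, power-law fit recovery, binarization recovery, graded-input
endpoint consistency, and the end-to-end concordance pipeline — and returns
plain numbers, so callers (pytest, the acceptance script, analysis drivers)
only assert or report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cllrs.binarize_concordance import (
    ExpressionMatrix,
    NodeGeneMap,
    binarize_matrix,
    concordance,
    select_proliferative_cells,
)
from cllrs.dynamics_attractors import (
    exhaustive_attractors,
    fuse_landscape,
    sampled_attractors,
)
from cllrs.graded_io import InputSchedule, graded_simulation
from cllrs.robustness_topology import (
    _sample_powerlaw,
    powerlaw_plausibility,
    random_nk_network,
    robustness_test,
)
from cllrs.synthetic_data import (
    SyntheticExpressionSpec,
    synth_expression,
    toy_networks,
)


@dataclass(frozen=True)
class OracleComparison:
    n_networks: int
    attractor_set_mismatches: int
    max_basin_ratio_error: float


def oracle_equivalence(
    n_networks: int = 20,
    n: int = 10,
    k: int = 2,
    n_samples: int = 100_000,
    seed: int = 1,
) -> OracleComparison:
    """Sampling estimator vs exhaustive enumeration on random N-K networks.

    For each network, checks that sampling discovers exactly the exhaustive
    attractor set and measures the worst basin-ratio deviation.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    max_err = 0.0
    for _ in range(n_networks):
        net = random_nk_network(n, k, seed=int(rng.integers(2**31)))
        exact = exhaustive_attractors(net)
        sampled = sampled_attractors(net, n_samples, seed=int(rng.integers(2**31)))
        if exact.attractor_keys() != sampled.attractor_keys():
            mismatches += 1
            continue
        exact_ratios = dict(
            zip((a.canonical_key for a in exact.attractors), exact.basin_ratios)
        )
        for att, ratio in zip(sampled.attractors, sampled.basin_ratios):
            max_err = max(max_err, abs(ratio - exact_ratios[att.canonical_key]))
    return OracleComparison(n_networks, mismatches, max_err)


def robustness_calibration(
    n_repetitions: int = 200,
    n_networks: int = 200,
    n_states: int = 200,
    n: int = 10,
    k: int = 2,
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Null rejection rate of the robustness test.

    The reference network is drawn from the same random N-K generator as the
    null networks, so the test's p-value should be calibrated and the
    rejection rate should sit near the nominal level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_repetitions):
        ref = random_nk_network(n, k, seed=int(rng.integers(2**31)))
        res = robustness_test(
            ref, n_networks=n_networks, n_states=n_states, seed=int(rng.integers(2**31))
        )
        rejections += res.p_value < alpha
    return rejections / n_repetitions


@dataclass(frozen=True)
class PowerLawBenchmark:
    recovery_rate: float  # alpha within +-0.3 and p > 0.1, power-law degrees
    poisson_rejection_rate: float  # p <= 0.1, Poisson degrees


def powerlaw_benchmark(
    n_runs: int = 50,
    n_degrees: int = 1000,
    alpha_true: float = 2.5,
    poisson_lambda: float = 4.0,
    n_bootstrap: int = 100,
    seed: int = 1,
) -> PowerLawBenchmark:
    """Power-law fit recovery on true power-law degrees and rejection power on
    Poisson degrees."""
    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_runs):
        degrees = _sample_powerlaw(n_degrees, alpha_true, 1, rng)
        fit = powerlaw_plausibility(
            degrees, n_bootstrap=n_bootstrap, seed=int(rng.integers(2**31))
        )
        recovered += abs(fit.alpha - alpha_true) <= 0.3 and fit.bootstrap_p > 0.1
    rejected = 0
    for _ in range(n_runs):
        degrees = rng.poisson(poisson_lambda, size=n_degrees)
        fit = powerlaw_plausibility(
            degrees, n_bootstrap=n_bootstrap, seed=int(rng.integers(2**31))
        )
        rejected += fit.bootstrap_p <= 0.1
    return PowerLawBenchmark(recovered / n_runs, rejected / n_runs)


@dataclass(frozen=True)
class BinarizationRecovery:
    cell_call_accuracy: float  # on observed (non-dropout) entries
    flat_genes_exactly_excluded: bool
    n_selected_cells: int


def binarization_recovery(
    spec: SyntheticExpressionSpec | None = None, seed: int = 1
) -> BinarizationRecovery:
    """Binarize a synthetic matrix and measure mode-label recovery."""
    spec = spec or SyntheticExpressionSpec(seed=seed)
    synth = synth_expression(spec)
    matrix = ExpressionMatrix(synth.genes, synth.cells, synth.values)
    result = binarize_matrix(matrix, seed=seed)
    correct = total = 0
    for gi, gene in enumerate(synth.genes):
        pg = result.per_gene[gene]
        if gene in synth.flat_genes or pg.excluded:
            continue
        observed = ~synth.dropout_mask[gi]
        correct += int((pg.binary[observed] == synth.truth[gi][observed]).sum())
        total += int(observed.sum())
    flat_ok = sorted(result.excluded_genes) == sorted(synth.flat_genes)
    selected = select_proliferative_cells(result)
    return BinarizationRecovery(correct / total, flat_ok, len(selected))


@dataclass(frozen=True)
class EndpointErrors:
    #: worst error over nodes whose activity is identical in every attractor
    #: of the knockin landscape (their fused value is exact, so the graded
    #: estimate must match it within the stated tolerance)
    constrained: float
    #: worst error over nodes whose activity differs between attractors;
    #: their fused value is a basin average, and a 250-start graded estimate
    #: carries irreducible binomial noise (sd ~ 0.032 at activity 0.5)
    free: float


def graded_endpoint_errors(seed: int = 1, n_starts: int = 250, T: int = 500,
                           window: int = 100) -> dict[str, EndpointErrors]:
    """Per-toy-network |graded(100%) - KI fused activity| endpoint errors.

    A 100% duty cycle is exactly a knockin of the scheduled node, so the
    graded simulation's stationary activities must match the knockin
    landscape's fused activities.  The exact knockin landscape comes from
    exhaustive enumeration.
    """
    errors: dict[str, EndpointErrors] = {}
    for name, (net, _truth) in toy_networks().items():
        input_node = net.nodes[0]
        graded = graded_simulation(
            net, [InputSchedule(input_node, 100)],
            n_starts=n_starts, T=T, window=window, seed=seed,
        )
        ki_landscape = exhaustive_attractors(net.with_fixed({input_node: 1}))
        ki = fuse_landscape(ki_landscape)
        constrained = free = 0.0
        for i, node in enumerate(net.nodes):
            per_attractor = {
                round(att.activity(net, node), 12) for att in ki_landscape.attractors
            }
            err = abs(graded[node] - ki[node])
            if len(per_attractor) == 1:
                constrained = max(constrained, err)
            else:
                free = max(free, err)
        errors[name] = EndpointErrors(constrained, free)
    return errors


def concordance_end_to_end(seed: int = 1, threshold: float = 0.30) -> dict[str, int]:
    """Full synthetic concordance pipeline: binarize, select proliferative
    cells, compare against model fractions set to the planted truth.

    With the model side equal to the data-side planted activation fractions,
    every node must match at the threshold; returns match/mismatch counts.
    The mapped genes are planted clearly active (high-mode fraction 0.7) or
    clearly inactive (0.25), alternating, with a 6-sigma mode separation, so
    both the 30% calls and the per-gene binarization significance carry wide
    margins at any seed.
    """
    node_gene_map = NodeGeneMap({f"N{i:02d}": (f"GENE{i:04d}",) for i in range(20)})
    base = SyntheticExpressionSpec(seed=seed, mu_hi=4.0)
    pis = [base.cyclin_pi] * 5 + [0.5] * (base.n_genes - 5)
    for i in range(20):  # GENE0000.. follow the five cyclins in gene order
        pis[5 + i] = 0.7 if i % 2 == 0 else 0.25
    spec = SyntheticExpressionSpec(seed=seed, mu_hi=4.0, pi=tuple(pis))
    synth = synth_expression(spec)
    matrix = ExpressionMatrix(synth.genes, synth.cells, synth.values)
    binarized = binarize_matrix(matrix, seed=seed)
    cells = select_proliferative_cells(binarized)
    cell_idx = [synth.cells.index(c) for c in cells]
    model_activity = {}
    for node, genes in node_gene_map.mapping.items():
        if binarized.per_gene[genes[0]].excluded:
            continue  # defensive: an excluded planted gene cannot be compared
        gi = synth.genes.index(genes[0])
        # planted truth fraction among the selected cells (OR over one gene),
        # on the observed entries the binarization can see
        observed = ~synth.dropout_mask[gi][cell_idx]
        truth_frac = float(
            (synth.truth[gi][cell_idx] & observed).sum() / len(cell_idx)
        )
        model_activity[node] = truth_frac
    result = concordance(
        model_activity, binarized, node_gene_map, cells=cells, threshold=threshold
    )
    matches = sum(c.match for c in result.values())
    return {"matches": matches, "mismatches": len(result) - matches}
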