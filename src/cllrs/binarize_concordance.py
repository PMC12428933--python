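"""Step-function expression binarization, cell filtering and model/data
concordance at the 30% activity threshold.

Sparse single-cell expression matrices are binarized gene-by-gene with a
step-function procedure: sort the values, fit least-squares optimal step
functions with increasing numbers of discontinuities, take the strongest
discontinuity of each fit, aggregate the candidate break locations (median),
and place the threshold at the midpoint of the two data values flanking the
chosen break.  A resampling test against a no-jump null provides the
significance filter; all-zero genes are excluded outright.

Binarized cells are filtered to proliferative ones by their cyclin signature
(any of CCNE1/CCNE2/CCND1/CCND2/CCND3 ON), and per-node activation
percentages are compared with model-side fused activities: a side counts as
active when its fraction reaches the 30% threshold (the Hans-score
convention), and a node matches when both sides agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from cllrs.synthetic_data import CYCLIN_GENES

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene x cell expression values with identifiers."""

    genes: tuple[str, ...]
    cells: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = self.values
        if sparse.issparse(values):
            values = np.asarray(values.todense())
        values = np.asarray(values, dtype=float)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.genes), columns=list(self.cells)).to_csv(
            path, sep="\t", index_label="gene"
        )

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path | None = None,
        cells_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        mtx_path = Path(mtx_path)
        genes_path = genes_path or mtx_path.with_name("genes.tsv")
        cells_path = cells_path or mtx_path.with_name("barcodes.tsv")
        values = scipy_io.mmread(mtx_path)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        return cls(tuple(genes), tuple(cells), values)

    def to_mtx(self, mtx_path: str | Path) -> None:
        mtx_path = Path(mtx_path)
        scipy_io.mmwrite(str(mtx_path), sparse.csr_matrix(self.values))
        mtx_path.with_name("genes.tsv").write_text("\n".join(self.genes) + "\n")
        mtx_path.with_name("barcodes.tsv").write_text("\n".join(self.cells) + "\n")


@dataclass(frozen=True)
class GeneBinarization:
    threshold: float | None
    binary: np.ndarray | None  # 1 iff value > threshold
    p_value: float | None
    excluded: bool
    exclusion_reason: str | None  # 'all_zero' | 'not_significant'


@dataclass(frozen=True)
class BinarizationResult:
    """Per-gene thresholds, binary vectors and exclusion flags."""

    genes: tuple[str, ...]
    cells: tuple[str, ...]
    per_gene: Mapping[str, GeneBinarization]
    alpha: float

    @property
    def included_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if not self.per_gene[g].excluded)

    @property
    def excluded_genes(self) -> dict[str, str]:
        return {
            g: self.per_gene[g].exclusion_reason
            for g in self.genes
            if self.per_gene[g].excluded
        }

    def binary_frame(self) -> pd.DataFrame:
        data = {g: self.per_gene[g].binary for g in self.included_genes}
        return pd.DataFrame.from_dict(
            data, orient="index", columns=list(self.cells)
        ).astype(int)


# ---------------------------------------------------------------------------
# Step-function binarization (BASC-A style)
# ---------------------------------------------------------------------------


def _block_cost_matrix(u: np.ndarray) -> np.ndarray:
    """cost[i, j] = squared error of u[i..j] around its block mean."""
    n = u.size
    s1 = np.concatenate([[0.0], np.cumsum(u)])
    s2 = np.concatenate([[0.0], np.cumsum(u * u)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    seg_sum = s1[j + 1] - s1[i]
    seg_sq = s2[j + 1] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = seg_sq - seg_sum**2 / length
    cost[j < i] = np.inf
    return np.maximum(cost, 0.0)


def _optimal_breaks(
    u: np.ndarray, max_steps: int, cost: np.ndarray | None = None
) -> list[np.ndarray]:
    """Breakpoints of the least-squares optimal d-step functions, d = 1..D.

    A d-step function partitions the sorted values into d+1 constant blocks;
    a break at position b means the blocks split between u[b-1] and u[b].
    Solved by dynamic programming over block boundaries.
    """
    n = u.size
    D = min(max_steps, n - 2)
    if cost is None:
        cost = _block_cost_matrix(u)
    # best[j] = minimal cost of covering u[0..j] with the current block count
    best = cost[0].copy()
    argmins = []  # argmins[b][j]: start index of the last block in the optimum
    js = np.arange(n)
    for _b in range(D):
        # candidate[i, j] = best[i - 1] + cost[i, j] for 1 <= i <= j
        cand = np.full((n, n), np.inf)
        cand[1:, :] = best[:-1, None] + cost[1:, :]
        arg = np.argmin(cand, axis=0)
        best = cand[arg, js]
        argmins.append(arg)
        if len(argmins) >= n - 1:
            break
    breaks_per_d = []
    for d in range(1, D + 1):
        breaks = []
        j = n - 1
        for b in range(d, 0, -1):
            i = int(argmins[b - 1][j])
            breaks.append(i)
            j = i - 1
        breaks_per_d.append(np.array(sorted(breaks), dtype=int))
    return breaks_per_d


def _strongest_break(u: np.ndarray, breaks: np.ndarray, cost: np.ndarray) -> int:
    """Strongest discontinuity of a step function (ties: lower break index).

    A discontinuity's strength is its jump between adjacent block means
    weighted by the quality of reducing the whole series to a single step at
    that position (the reciprocal of the two-block squared error there): a
    large jump out in a sparse tail approximates the series poorly as a
    global threshold and is down-weighted accordingly.
    """
    n = u.size
    bounds = np.concatenate([[0], breaks, [n]])
    means = [u[bounds[k] : bounds[k + 1]].mean() for k in range(len(bounds) - 1)]
    jumps = np.diff(means)
    one_step_err = np.array([cost[0, b - 1] + cost[b, n - 1] for b in breaks])
    with np.errstate(divide="ignore"):
        scores = np.where(one_step_err > 0, jumps / one_step_err, np.inf)
    return int(breaks[int(np.argmax(scores))])


def _basca_break_and_stat(u_sorted: np.ndarray, max_steps: int) -> tuple[int, float]:
    """Aggregated break index and the break-strength statistic.

    The aggregated break is the (lower) median of the strongest-discontinuity
    locations across the d-step fits.  Break strength is the Gaussian
    likelihood-ratio of splitting the series into the two blocks flanking the
    break, ``n * log(SS_total / SS_within)`` — infinite for a perfect step.
    The statistic is location/scale free, so its no-jump null distribution
    depends only on the sample size.
    """
    n = u_sorted.size
    cost = _block_cost_matrix(u_sorted)
    breaks_per_d = _optimal_breaks(u_sorted, max_steps, cost=cost)
    strongest = [_strongest_break(u_sorted, breaks, cost) for breaks in breaks_per_d]
    b_star = int(np.sort(strongest)[(len(strongest) - 1) // 2])  # lower median
    left, right = u_sorted[:b_star], u_sorted[b_star:]
    ss_within = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
    ss_total = ((u_sorted - u_sorted.mean()) ** 2).sum()
    stat = np.inf if ss_within == 0 else n * np.log(ss_total / ss_within)
    return b_star, float(stat)


def _null_break_stats(
    n: int, max_steps: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Break-strength statistics of no-jump (unimodal Gaussian) null samples
    of size ``n``, run through the identical fitting pipeline."""
    out = np.empty(n_resamples)
    for r in range(n_resamples):
        u = np.sort(rng.normal(size=n))
        _b, out[r] = _basca_break_and_stat(u, max_steps)
    return out


def basca_binarize(
    values: Sequence[float],
    alpha: float = 0.05,
    n_resamples: int = 100,
    seed: int | None = None,
    max_steps: int = 20,
    null_stats: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Binarize a vector by its strongest significant step discontinuity.

    Returns ``(threshold, binary, p_value)`` with ``binary_i = 1`` iff
    ``values_i > threshold``; the threshold is the midpoint of the two sorted
    values flanking the aggregated break.  The p-value compares the
    normalized data gap at the break against the same statistic on sorted
    no-jump (uniform) null samples of equal size; ``null_stats`` allows
    reusing a precomputed null (it only depends on the sample size).

    ``max_steps`` caps the number of step-function levels fitted; the full
    range d = 1..N-2 is available by passing ``max_steps >= len(values) - 2``.
    """
    u = np.asarray(values, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 values to binarize")
    if not np.isfinite(u).all():
        raise ValueError("values must be finite")
    if np.unique(u).size == 1:
        raise ValueError("degenerate input: all values equal")
    order = np.argsort(u, kind="stable")
    u_sorted = u[order]
    b_star, stat = _basca_break_and_stat(u_sorted, max_steps)
    threshold = 0.5 * (u_sorted[b_star - 1] + u_sorted[b_star])
    if null_stats is None:
        rng = np.random.default_rng(seed)
        null_stats = _null_break_stats(u.size, max_steps, n_resamples, rng)
    p_value = (1 + int((null_stats >= stat).sum())) / (null_stats.size + 1)
    binary = (u > threshold).astype(np.int8)
    return float(threshold), binary, float(p_value)


def binarize_matrix(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    seed: int | None = None,
    n_resamples: int = 100,
    max_steps: int = 20,
    log_transform: bool = True,
) -> BinarizationResult:
    """Per-gene binarization with exclusion flags.

    Genes with no expression in any cell are excluded (``all_zero``); genes
    whose break statistic is not significant at ``alpha`` are excluded
    (``not_significant``).  The resampling null is shared across genes (it
    depends only on the number of cells).

    By default each gene is fitted on ``log1p`` of its values — the standard
    normalisation scale for expression data, where bimodal genes separate
    into compact modes instead of a heavy multiplicative tail; the transform
    is monotone, and the reported threshold is mapped back to the original
    scale, so ``binary = value > threshold`` holds on the input values.

    Robustness to sparsity: the step-function fit uses only the expressed
    (nonzero) values of a gene, so the threshold is set by the structure of
    the expressing cells and is unaffected by the number of zeros; zero
    measurements can never exceed a positive threshold and are called OFF.
    """
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_for(n: int) -> np.ndarray:
        # the null depends on the sample size only slowly: bucket to multiples
        # of 50 (exact below 50) so genes of similar coverage share one null
        key = n if n < 50 else int(round(n / 50.0)) * 50
        if key not in null_cache:
            null_cache[key] = _null_break_stats(key, max_steps, n_resamples, rng)
        return null_cache[key]

    per_gene: dict[str, GeneBinarization] = {}
    for gi, gene in enumerate(matrix.genes):
        row = matrix.values[gi]
        if not row.any():
            per_gene[gene] = GeneBinarization(None, None, None, True, "all_zero")
            continue
        positive = row[row > 0]
        if positive.size < 3 or np.unique(positive).size == 1:
            # too few expressed cells / no discontinuity to threshold on
            per_gene[gene] = GeneBinarization(None, None, None, True, "not_significant")
            continue
        fit_vals = np.log1p(positive) if log_transform else positive
        threshold, _bin, p = basca_binarize(
            fit_vals, alpha=alpha, max_steps=max_steps, null_stats=null_for(positive.size)
        )
        if log_transform:
            threshold = float(np.expm1(threshold))
        if p > alpha:
            per_gene[gene] = GeneBinarization(threshold, None, p, True, "not_significant")
        else:
            binary = (row > threshold).astype(np.int8)
            per_gene[gene] = GeneBinarization(threshold, binary, p, False, None)
    return BinarizationResult(matrix.genes, matrix.cells, per_gene, alpha)


# ---------------------------------------------------------------------------
# Proliferative-cell selection and concordance
# ---------------------------------------------------------------------------


def select_proliferative_cells(
    binarized: BinarizationResult,
    cyclin_genes: Sequence[str] = CYCLIN_GENES,
) -> tuple[str, ...]:
    """Cells with at least one cyclin gene ON in the binarized data."""
    available = [
        g for g in cyclin_genes if g in binarized.per_gene and not binarized.per_gene[g].excluded
    ]
    if not available:
        raise ValueError(
            "no non-excluded cyclin gene available for proliferative-cell selection"
        )
    mask = np.zeros(len(binarized.cells), dtype=bool)
    for g in available:
        mask |= binarized.per_gene[g].binary.astype(bool)
    return tuple(c for c, m in zip(binarized.cells, mask) if m)


@dataclass(frozen=True)
class NodeGeneMap:
    """Model node -> gene symbols (isoform groups), OR-aggregated per cell."""

    mapping: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        cleaned = {node: tuple(genes) for node, genes in self.mapping.items()}
        object.__setattr__(self, "mapping", cleaned)
        seen: dict[str, str] = {}
        for node, genes in cleaned.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} mapped to both {seen[g]!r} and {node!r}"
                    )
                seen[g] = node

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeGeneMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["node", "gene"])
        mapping: dict[str, list[str]] = {}
        for node, gene in zip(df["node"], df["gene"]):
            mapping.setdefault(str(node), []).append(str(gene))
        return cls({k: tuple(v) for k, v in mapping.items()})


#: Transcriptionally regulated model nodes and their gene groups (isoforms).
DEFAULT_NODE_GENE_MAP = NodeGeneMap(
    {
        "CD5": ("CD5",),
        "SET": ("SET",),
        "BMI1": ("BMI1",),
        "CITED2": ("CITED2",),
        "NOTCH1": ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"),
        "S100A4": ("S100A4",),
        "PTEN": ("PTEN",),
        "NFAT": ("NFATC1", "NFATC2"),
        "TP53": ("TP53",),
        "MYC": ("MYC",),
        "CDKN1A": ("CDKN1A",),
        "CDKN2A": ("CDKN2A",),
        "CDKN2B": ("CDKN2B",),
        "CDKN1B": ("CDKN1B",),
    }
)


@dataclass(frozen=True)
class NodeConcordance:
    node: str
    data_fraction: float
    model_fraction: float
    data_active: bool
    model_active: bool

    @property
    def match(self) -> bool:
        return self.data_active == self.model_active


def concordance(
    model_activity: Mapping[str, float],
    binarized: BinarizationResult,
    node_gene_map: NodeGeneMap = DEFAULT_NODE_GENE_MAP,
    cells: Sequence[str] | None = None,
    threshold: float = 0.30,
) -> dict[str, NodeConcordance]:
    """Per-node match between model activity and binarized-data activation.

    The data-side fraction of a node is the fraction of (selected) cells in
    which the OR over its mapped, non-excluded genes is 1; a side is active
    when its fraction reaches ``threshold``.  ``model_activity`` is expected
    to come from fused landscapes restricted to fully proliferative
    attractors, mirroring the cyclin-based cell selection.
    """
    if cells is None:
        cell_idx = np.arange(len(binarized.cells))
    else:
        pos = {c: i for i, c in enumerate(binarized.cells)}
        cell_idx = np.array([pos[c] for c in cells], dtype=int)
        if cell_idx.size == 0:
            raise ValueError("empty cell selection")
    out: dict[str, NodeConcordance] = {}
    for node, activity in model_activity.items():
        genes = node_gene_map.mapping.get(node)
        if genes is None:
            raise KeyError(f"node {node!r} has no gene mapping")
        usable = [
            g
            for g in genes
            if g in binarized.per_gene and not binarized.per_gene[g].excluded
        ]
        if not usable:
            raise ValueError(f"node {node!r} has no non-excluded mapped gene")
        agg = np.zeros(cell_idx.size, dtype=bool)
        for g in usable:
            agg |= binarized.per_gene[g].binary[cell_idx].astype(bool)
        data_fraction = float(agg.mean())
        out[node] = NodeConcordance(
            node=node,
            data_fraction=data_fraction,
            model_fraction=float(activity),
            data_active=data_fraction >= threshold,
            model_active=float(activity) >= threshold,
        )
    return out


# ---------------------------------------------------------------------------
# ROC-based binarization of scored markers
# ---------------------------------------------------------------------------


def roc_binarize(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity (Youden J).

    Candidate thresholds are the midpoints between consecutive unique scores;
    a sample is called positive when its score exceeds the threshold, with
    label 1 the positive condition.  Ties resolve to the smallest candidate.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    classes = np.unique(labels)
    if classes.size != 2 or set(classes) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("scores are constant; no separating threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for thr in candidates:
        called = scores > thr
        sens = float((called & (labels == 1)).sum()) / n_pos
        spec = float((~called & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), sens, spec)
    _j, thr, sens, spec = best
    return thr, sens, spec
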