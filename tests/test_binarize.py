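"""Step-function binarization, cell selection, concordance and ROC thresholds."""

import numpy as np
import pytest
from sklearn.metrics import roc_curve

from cllrs.binarize_concordance import (
    DEFAULT_NODE_GENE_MAP,
    ExpressionMatrix,
    NodeGeneMap,
    basca_binarize,
    binarize_matrix,
    concordance,
    roc_binarize,
    select_proliferative_cells,
)
from cllrs.synthetic_data import SyntheticExpressionSpec, synth_expression


class TestBascaBinarize:
    def test_clean_two_level_vector(self):
        thr, binary, p = basca_binarize([1, 1, 1, 10, 10, 10], seed=0)
        assert 1 < thr < 10
        assert binary.tolist() == [0, 0, 0, 1, 1, 1]
        assert p <= 0.05

    def test_linear_ramp_rarely_significant(self):
        ramp = np.arange(1, 21, dtype=float)
        n_sig = sum(basca_binarize(ramp, seed=i)[2] <= 0.05 for i in range(20))
        assert n_sig <= 2  # not significant in >= 90% of seeded runs

    def test_binary_respects_unsorted_input_order(self):
        thr, binary, _p = basca_binarize([10, 1, 10, 1, 1, 10], seed=0)
        assert binary.tolist() == [1, 0, 1, 0, 0, 1]

    @pytest.mark.parametrize("values", [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0]])
    def test_degenerate_inputs_rejected(self, values):
        with pytest.raises(ValueError):
            basca_binarize(values, seed=0)

    def test_monotonicity_raising_one_value_keeps_other_calls(self):
        base = np.array([1.0, 1.2, 0.9, 1.1, 9.8, 10.0, 10.3, 9.9])
        _thr, binary, _ = basca_binarize(base, seed=0)
        for i in range(len(base)):
            bumped = base.copy()
            bumped[i] += 0.3
            _t, b2, _ = basca_binarize(bumped, seed=0)
            others = np.arange(len(base)) != i
            assert np.array_equal(b2[others], binary[others])

    def test_threshold_interval_invariant_to_duplication(self):
        base = np.array([1.0, 1.2, 0.9, 9.8, 10.0, 10.3])
        thr1, _, _ = basca_binarize(base, seed=0)
        thr2, _, _ = basca_binarize(np.repeat(base, 2), seed=0)
        # both thresholds separate the same two groups
        assert (base > thr1).tolist() == (base > thr2).tolist()


@pytest.fixture(scope="module")
def synth():
    return synth_expression(SyntheticExpressionSpec(n_genes=40, n_cells=200, seed=7))


@pytest.fixture(scope="module")
def result(synth):
    matrix = ExpressionMatrix(synth.genes, synth.cells, synth.values)
    return binarize_matrix(matrix, seed=1)


class TestBinarizeMatrix:
    def test_all_zero_genes_excluded(self, synth, result):
        for g in synth.flat_genes:
            assert result.per_gene[g].exclusion_reason == "all_zero"

    def test_only_flat_genes_excluded(self, synth, result):
        assert sorted(result.excluded_genes) == sorted(synth.flat_genes)

    def test_mode_recovery_on_observed_entries(self, synth, result):
        correct = total = 0
        for gi, g in enumerate(synth.genes):
            pg = result.per_gene[g]
            if pg.excluded:
                continue
            obs = ~synth.dropout_mask[gi]
            correct += int((pg.binary[obs] == synth.truth[gi][obs]).sum())
            total += int(obs.sum())
        assert correct / total >= 0.95

    def test_single_gene_matrix_consistent_with_vector_call(self):
        rng = np.random.default_rng(0)
        row = np.concatenate([np.exp(rng.normal(1, 0.5, 50)), np.exp(rng.normal(3, 0.5, 50))])
        matrix = ExpressionMatrix(("G",), tuple(f"c{i}" for i in range(100)), row[None, :])
        res = binarize_matrix(matrix, seed=1)
        thr, binary, _p = basca_binarize(np.log1p(row), seed=1)
        assert np.array_equal(res.per_gene["G"].binary, binary)


class TestCellSelection:
    def test_cyclin_or_rule(self):
        genes = ("CCNE1", "CCND2", "OTHER")
        cells = ("c0", "c1", "c2", "c3")
        values = np.array(
            [
                [0.0, 9.0, 0.0, 0.5],  # CCNE1 high in c1
                [9.0, 0.0, 0.0, 0.4],  # CCND2 high in c0
                [5.0, 5.0, 5.0, 0.1],
            ]
        )
        # thresholds via a hand-made binarization result
        from cllrs.binarize_concordance import BinarizationResult, GeneBinarization

        per_gene = {
            "CCNE1": GeneBinarization(1.0, (values[0] > 1).astype(np.int8), 0.01, False, None),
            "CCND2": GeneBinarization(1.0, (values[1] > 1).astype(np.int8), 0.01, False, None),
            "OTHER": GeneBinarization(1.0, (values[2] > 1).astype(np.int8), 0.01, False, None),
        }
        res = BinarizationResult(genes, cells, per_gene, 0.05)
        assert select_proliferative_cells(res) == ("c0", "c1")

    def test_no_cyclin_available_is_an_error(self):
        from cllrs.binarize_concordance import BinarizationResult, GeneBinarization

        res = BinarizationResult(
            ("X",), ("c0",), {"X": GeneBinarization(1.0, np.array([1], dtype=np.int8), 0.01, False, None)}, 0.05
        )
        with pytest.raises(ValueError):
            select_proliferative_cells(res)


class TestConcordance:
    @pytest.fixture()
    def binarized(self):
        from cllrs.binarize_concordance import BinarizationResult, GeneBinarization

        cells = tuple(f"c{i}" for i in range(10))
        mk = lambda bits: GeneBinarization(1.0, np.array(bits, dtype=np.int8), 0.01, False, None)
        per_gene = {
            "MYC": mk([1] * 5 + [0] * 5),  # 50% active
            "TP53": mk([1] + [0] * 9),  # 10% active
            "NFATC1": mk([0] * 10),
            "NFATC2": mk([1] * 3 + [0] * 7),  # OR makes NFAT 30%
        }
        return BinarizationResult(("MYC", "TP53", "NFATC1", "NFATC2"), cells, per_gene, 0.05)

    def test_match_and_mismatch_calls(self, binarized):
        result = concordance(
            {"MYC": 1.0, "TP53": 0.0}, binarized, DEFAULT_NODE_GENE_MAP
        )
        assert result["MYC"].match  # both sides >= 30%
        assert result["TP53"].match  # both sides < 30%
        result2 = concordance({"TP53": 0.9}, binarized, DEFAULT_NODE_GENE_MAP)
        assert not result2["TP53"].match  # data 10% vs model 90%

    def test_isoform_or_aggregation(self, binarized):
        result = concordance({"NFAT": 0.0}, binarized, DEFAULT_NODE_GENE_MAP)
        assert result["NFAT"].data_fraction == pytest.approx(0.3)
        assert result["NFAT"].data_active  # 30% meets the threshold

    def test_threshold_crossing_symmetry(self, binarized):
        a = concordance({"MYC": 0.1}, binarized)["MYC"]
        flipped = concordance({"TP53": 0.5}, binarized)["TP53"]
        # swapping which side is above/below the threshold preserves mismatch
        assert not a.match and not flipped.match

    def test_unmapped_node_is_an_error(self, binarized):
        with pytest.raises(KeyError):
            concordance({"NOT_A_NODE": 0.5}, binarized)

    def test_gene_mapped_twice_rejected(self):
        with pytest.raises(ValueError):
            NodeGeneMap({"A": ("G1",), "B": ("G1",)})


class TestRocBinarize:
    def test_separable_classes_midpoint(self):
        thr, sens, spec = roc_binarize([1, 2, 3, 8, 9], [0, 0, 0, 1, 1])
        assert thr == pytest.approx(5.5)
        assert sens == 1.0 and spec == 1.0

    def test_identical_distributions_take_smallest_candidate(self):
        scores = [1, 2, 3, 1, 2, 3]
        labels = [0, 0, 0, 1, 1, 1]
        thr, sens, spec = roc_binarize(scores, labels)
        assert thr == pytest.approx(1.5)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_sklearn_youden_on_interleaved_scores(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.5, 1, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        thr, sens, spec = roc_binarize(scores, labels)
        fpr, tpr, thresholds = roc_curve(labels, scores)
        best_j = float(np.max(tpr - fpr))
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_binarize([1, 2, 3], [1, 1, 1])
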