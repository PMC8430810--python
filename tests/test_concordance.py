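import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import rank_then_pearson
from structdrop.concordance import (
    DetectionCall,
    DetectionCallSet,
    DetectionPolicy,
    cross_platform_classify,
    detection_calls,
    log2_transform,
    relative_expression,
    spearman_codetected,
)
from structdrop.io_formats import ExpressionMatrix, ValidationError


def _rnaseq(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix("rnaseq", gene_ids, samples, values)


class TestLog2Transform:
    def test_values(self):
        m = log2_transform(_rnaseq([[3.0, 0.0]]), pseudocount=1)
        np.testing.assert_allclose(m.values, [[2.0, 0.0]])
        assert m.log_transformed

    def test_double_transform_rejected(self):
        m = log2_transform(_rnaseq([[3.0]]))
        with pytest.raises(ValidationError, match="already"):
            log2_transform(m)

    def test_nonpositive_after_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            log2_transform(_rnaseq([[0.0]]), pseudocount=0)


class TestDetectionCalls:
    def test_rnaseq_zero_counts_not_detected(self):
        calls = detection_calls(_rnaseq([[0.0, 0.0], [0.0, 1.0]]))
        assert not calls.calls["g0"].detected  # no read counts at all
        assert calls.calls["g1"].detected  # a single read suffices

    def test_array_percentile_threshold(self, small_array_matrix):
        # mean log2 signals (2, 4, 6, 8): 25th percentile = 3.5, so the
        # genes strictly above it (4, 6, 8) are flagged detected
        calls = detection_calls(small_array_matrix)
        assert calls.threshold == pytest.approx(np.percentile([2, 4, 6, 8], 25))
        assert calls.detected_genes() == {"g2", "g3", "g4"}

    def test_raising_tau_never_adds_detections(self, small_array_matrix):
        taus = np.linspace(0, 10, 21)
        previous = None
        for tau in taus:
            detected = detection_calls(
                small_array_matrix, DetectionPolicy(tau_array=tau)
            ).detected_genes()
            if previous is not None:
                assert detected <= previous
            previous = detected

    def test_mean_signal_on_native_scale(self):
        calls = detection_calls(_rnaseq([[2.0, 4.0]]))
        assert calls.calls["g0"].mean_signal == 3.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(Exception):
            detection_calls(
                ExpressionMatrix("rnaseq", [], ["s1"], np.empty((0, 1)))
            )


def _call_set(platform, detected_map):
    return DetectionCallSet(
        platform,
        {g: DetectionCall(d, 1.0) for g, d in detected_map.items()},
    )


class TestCrossPlatformClassify:
    def test_hand_enumerated_truth_table(self):
        # 10 genes, calls assigned by hand; expected partition enumerated
        # independently of the implementation
        array_det = {f"g{i}": i % 2 == 0 for i in range(10)}  # evens detected
        seq_det = {f"g{i}": i < 5 for i in range(10)}  # first five detected
        table = cross_platform_classify(
            _call_set("array", array_det), _call_set("rnaseq", seq_det)
        )
        assert table.both == {"g0", "g2", "g4"}
        assert table.array_only == {"g6", "g8"}
        assert table.seq_only == {"g1", "g3"}
        assert table.neither == {"g5", "g7", "g9"}

    def test_array_only_is_the_dropout_category(self):
        table = cross_platform_classify(
            _call_set("array", {"sox21": True}),
            _call_set("rnaseq", {"sox21": False}),  # zero read counts
        )
        assert table.array_only == {"sox21"}

    def test_private_genes_reported_not_dropped(self):
        table = cross_platform_classify(
            _call_set("array", {"g1": True, "probe_x": True}),
            _call_set("rnaseq", {"g1": True, "ensg_y": False}),
        )
        assert table.private_array == {"probe_x"}
        assert table.private_seq == {"ensg_y"}
        assert table.universe == {"g1"}

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            cross_platform_classify(
                _call_set("array", {"a": True}), _call_set("rnaseq", {"b": True})
            )

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40
        )
    )
    def test_partition_property(self, flags):
        genes = {f"g{i}": pair for i, pair in enumerate(flags)}
        table = cross_platform_classify(
            _call_set("array", {g: a for g, (a, _) in genes.items()}),
            _call_set("rnaseq", {g: s for g, (_, s) in genes.items()}),
        )
        sizes = [
            len(table.both),
            len(table.array_only),
            len(table.seq_only),
            len(table.neither),
        ]
        assert sum(sizes) == len(genes)
        assert table.universe == set(genes)


def _log2_matrix(platform, means):
    values = np.asarray(means, dtype=float)[:, None]
    return ExpressionMatrix(
        platform,
        [f"g{i}" for i in range(len(means))],
        ["s1"],
        values,
        log_transformed=True,
    )


class TestSpearmanCodetected:
    def _table(self, n):
        genes = {f"g{i}" for i in range(n)}
        from structdrop.concordance import ConcordanceTable

        return ConcordanceTable(both=genes, array_only=set(), seq_only=set(), neither=set())

    def test_monotone_is_plus_one(self):
        a = _log2_matrix("array", [1, 2, 3, 4, 5])
        b = _log2_matrix("rnaseq", [2, 4, 8, 9, 20])
        assert spearman_codetected(a, b, self._table(5)) == 1.0

    def test_reversed_is_minus_one(self):
        a = _log2_matrix("array", [1, 2, 3, 4, 5])
        b = _log2_matrix("rnaseq", [10, 8, 6, 4, 2])
        assert spearman_codetected(a, b, self._table(5)) == -1.0

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 8.0, 9.0, 9.5]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 9.0, 8.0]
        a = _log2_matrix("array", x)
        b = _log2_matrix("rnaseq", y)
        rho = spearman_codetected(a, b, self._table(8))
        assert rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = _log2_matrix("array", x)
        b1 = _log2_matrix("rnaseq", y)
        b2 = _log2_matrix("rnaseq", np.exp(y))  # strictly monotone transform
        t1, t2 = self._table(20), self._table(20)
        assert spearman_codetected(a, b1, t1) == pytest.approx(
            spearman_codetected(a, b2, t2), abs=1e-12
        )

    def test_too_few_codetected_rejected(self):
        a = _log2_matrix("array", [1, 2])
        b = _log2_matrix("rnaseq", [1, 2])
        with pytest.raises(ValidationError, match=">= 3"):
            spearman_codetected(a, b, self._table(2))


class TestRelativeExpression:
    def test_housekeeper_ratio(self):
        matrix = ExpressionMatrix(
            "rnaseq",
            ["GAPDH", "SOX3"],
            ["s1", "s2"],
            np.array([[1000.0, 2000.0], [1.0, 4.0]]),
        )
        # per-sample ratios 0.001 and 0.002 -> mean 0.0015
        assert relative_expression(matrix, "SOX3", "GAPDH") == pytest.approx(0.0015)

    def test_unknown_gene_rejected(self):
        matrix = ExpressionMatrix("rnaseq", ["g1"], ["s1"], np.array([[1.0]]))
        with pytest.raises(KeyError):
            relative_expression(matrix, "nope", "g1")
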