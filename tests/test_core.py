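"""Comparison-matrix validation, sum-product weights and consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swotahp import (RANDOM_INDEX, ComparisonMatrix, MatrixValidationError,
                     compute_aw, compute_weights, consistency,
                     principal_eigenvector, validate_matrix)
from swotahp.core import parse_judgment

from conftest import FACTOR_IDS, MATRIX_ROWS, consistent_matrix

positive_weights = st.lists(
    st.floats(min_value=0.02, max_value=1.0), min_size=2, max_size=7
).map(lambda ws: np.array(ws) / np.sum(ws))


class TestParsing:
    @pytest.mark.parametrize("raw,expected", [
        ("1/7", 1 / 7), ("3", 3.0), (0.5, 0.5), (" 1/2 ", 0.5), (4, 4.0),
    ])
    def test_fractions_and_decimals(self, raw, expected):
        assert parse_judgment(raw) == pytest.approx(expected, rel=1e-15)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_judgment("one half")


class TestValidation:
    def test_worked_example_matrices_valid_and_on_grid(self, example_matrices):
        for m in example_matrices.values():
            assert validate_matrix(m, strict_saaty=True) == []

    def test_all_ones_matrix_valid(self):
        m = ComparisonMatrix("X", ("a", "b", "c"), np.ones((3, 3)))
        assert validate_matrix(m) == []

    def test_reciprocity_violation_located(self):
        vals = np.array([[1.0, 2.0, 1.0], [3.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        m = ComparisonMatrix("X", ("a", "b", "c"), vals)
        codes = {(v.code, v.row, v.col) for v in validate_matrix(m)}
        assert ("reciprocity", 1, 0) in codes

    def test_nonpositive_entry_flagged(self):
        vals = np.array([[1.0, -2.0], [-0.5, 1.0]])
        m = ComparisonMatrix("X", ("a", "b"), vals)
        assert any(v.code == "nonpositive" for v in validate_matrix(m))

    def test_off_scale_only_in_strict_mode(self):
        vals = np.array([[1.0, 2.7], [1 / 2.7, 1.0]])
        m = ComparisonMatrix("X", ("a", "b"), vals)
        assert validate_matrix(m, strict_saaty=False) == []
        assert any(v.code == "off_scale" for v in validate_matrix(m, strict_saaty=True))

    def test_non_square_rejected(self):
        with pytest.raises(MatrixValidationError) as exc:
            ComparisonMatrix("X", ("a", "b"), np.ones((2, 3)))
        assert exc.value.code == "not_square"

    def test_order_above_nine_rejected(self):
        m = ComparisonMatrix("X", tuple(f"f{i}" for i in range(10)), np.ones((10, 10)))
        with pytest.raises(MatrixValidationError) as exc:
            validate_matrix(m)
        assert exc.value.code == "unsupported_order"

    def test_upper_triangle_construction_reciprocal(self):
        m = ComparisonMatrix.from_upper_triangle(
            {("a", "b"): 3, ("a", "c"): "1/5", ("b", "c"): 2}, ("a", "b", "c"))
        assert validate_matrix(m) == []
        assert m.values[2, 0] == pytest.approx(5.0)

    def test_upper_triangle_missing_pair_rejected(self):
        with pytest.raises(MatrixValidationError) as exc:
            ComparisonMatrix.from_upper_triangle({("a", "b"): 3}, ("a", "b", "c"))
        assert exc.value.code == "missing_pairs"


class TestWeights:
    @pytest.mark.parametrize("group,expected", [
        ("S", (0.0672, 0.0942, 0.2429, 0.5956)),
        ("O", (0.2840, 0.1715, 0.4708, 0.0736)),
        ("W", (0.0978, 0.7151, 0.1871)),
        ("T", (0.2298, 0.1221, 0.6479)),
    ])
    def test_worked_example_weights(self, example_matrices, group, expected):
        w = compute_weights(example_matrices[group])
        assert w == pytest.approx(expected, abs=5e-4)

    def test_equal_importance_gives_uniform_weights(self):
        m = ComparisonMatrix("X", tuple("abcde"), np.ones((5, 5)))
        assert compute_weights(m) == pytest.approx([0.2] * 5, abs=1e-12)

    def test_consistent_matrix_recovers_generator_exactly(self):
        m = consistent_matrix([0.6, 0.3, 0.1])
        assert compute_weights(m) == pytest.approx([0.6, 0.3, 0.1], abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(positive_weights)
    def test_weights_sum_to_one_and_recover(self, w):
        m = consistent_matrix(w)
        got = compute_weights(m)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(got > 0)
        assert got == pytest.approx(w, abs=1e-9)

    def test_permutation_invariance(self, example_matrices):
        m = example_matrices["O"]
        order = [2, 0, 3, 1]
        w = compute_weights(m)
        wp = compute_weights(m.permuted(order))
        assert wp == pytest.approx(w[order], abs=1e-12)


class TestAw:
    def test_worked_example_aw(self, example_matrices):
        m = example_matrices["W"]
        aw = compute_aw(m, compute_weights(m))
        assert aw == pytest.approx((0.2935, 2.1483, 0.5615), abs=5e-4)

    def test_all_ones_aw_is_unity(self):
        m = ComparisonMatrix("X", ("a", "b", "c"), np.ones((3, 3)))
        assert compute_aw(m, np.full(3, 1 / 3)) == pytest.approx([1, 1, 1], abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(positive_weights)
    def test_consistent_aw_equals_n_times_weights(self, w):
        m = consistent_matrix(w)
        assert compute_aw(m, w) == pytest.approx(len(w) * np.asarray(w), rel=1e-9)

    def test_dimension_mismatch(self, example_matrices):
        with pytest.raises(ValueError):
            compute_aw(example_matrices["W"], np.ones(4))


class TestConsistency:
    def test_worked_example_lambda_max(self, example_matrices):
        assert consistency(example_matrices["W"]).lambda_max == pytest.approx(
            3.00198, abs=2e-3)

    def test_hand_checked_consistent_3x3(self):
        # [[1,2,6],[1/2,1,3],[1/6,1/3,1]] satisfies a_ik = a_ij a_jk (2 x 3 = 6),
        # so its characteristic polynomial has lambda = n = 3 as top root.
        m = ComparisonMatrix.from_rows(
            [[1, 2, 6], ["1/2", 1, 3], ["1/6", "1/3", 1]], ("a", "b", "c"))
        r = consistency(m)
        assert r.lambda_max == pytest.approx(3.0, abs=1e-12)
        assert r.ci == pytest.approx(0.0, abs=1e-12)
        assert r.cr == 0.0 and r.consistent

    @settings(max_examples=50, derandomize=True)
    @given(positive_weights)
    def test_consistent_matrix_has_lambda_n_ci_zero(self, w):
        r = consistency(consistent_matrix(w))
        assert r.lambda_max == pytest.approx(len(w), abs=1e-9)
        assert r.ci == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(positive_weights, st.integers(0, 2**31 - 1))
    def test_lambda_max_at_least_n(self, w, seed):
        """Perturbed reciprocal matrices keep lambda_max >= n."""
        from swotahp import perturb_matrix
        m = perturb_matrix(consistent_matrix(w), sigma=0.5, seed=seed)
        r = consistency(m)
        assert r.lambda_max >= len(w) - 1e-9

    def test_cr_boundary_exactly_point_one_fails(self, example_matrices):
        # choose an RI override that lands CR exactly on the 0.1 threshold
        ci = consistency(example_matrices["S"]).ci
        r = consistency(example_matrices["S"], ri_table={4: ci / 0.1})
        assert r.cr == pytest.approx(0.1, abs=1e-12)
        assert not r.consistent

    def test_order_two_defined_consistent(self):
        m = ComparisonMatrix.from_rows([[1, 5], ["1/5", 1]], ("a", "b"))
        r = consistency(m)
        assert r.cr == 0.0 and r.consistent
        assert r.lambda_max == pytest.approx(2.0, abs=1e-9)

    def test_order_one_degenerate(self):
        m = ComparisonMatrix("X", ("a",), np.ones((1, 1)))
        r = consistency(m)
        assert r.weights == pytest.approx([1.0]) and r.consistent

    def test_ri_table_matches_lookup(self, example_matrices):
        assert consistency(example_matrices["S"]).ri == RANDOM_INDEX[4]
        assert consistency(example_matrices["W"]).ri == RANDOM_INDEX[3]

    def test_eigenvector_oracle_close_for_consistent_ish_matrices(self, example_matrices):
        """Sum-product weights track the principal eigenvector (independent
        numpy.linalg.eig route) within 0.05 per component when CR < 0.1 —
        a sanity band; the two estimators differ by design."""
        for m in example_matrices.values():
            r = consistency(m)
            assert r.consistent
            assert r.weights == pytest.approx(principal_eigenvector(m), abs=0.05)

    def test_result_json_fields(self, example_matrices):
        import json
        d = json.loads(consistency(example_matrices["S"]).to_json())
        assert {"weights", "aw", "lambda_max", "ci", "ri", "cr",
                "consistent"} <= set(d)


class TestCsvRoundTrip:
    def test_csv_round_trip(self, tmp_path, example_matrices):
        m = example_matrices["S"]
        p = tmp_path / "m.csv"
        m.to_csv(p)
        back = ComparisonMatrix.from_csv(p, group_id="S")
        assert back.factor_ids == m.factor_ids
        assert back.values == pytest.approx(m.values, rel=1e-12)

    def test_fixture_csv_parses_fractions_exactly(self):
        from swotahp import EXAMPLE_DIR
        m = ComparisonMatrix.from_csv(EXAMPLE_DIR / "matrix_S.csv", group_id="S")
        assert m.values[0, 3] == pytest.approx(1 / 7, rel=1e-15)
        expected = np.array([[parse_judgment(c) for c in row] for row in MATRIX_ROWS["S"]])
        assert m.values == pytest.approx(expected, rel=1e-15)
        assert m.factor_ids == FACTOR_IDS["S"]
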