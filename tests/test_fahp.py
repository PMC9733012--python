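"""Expert judgment matrices and the row-geometric-mean priority vector."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import gohidi as g

from conftest import consistent_matrix


def responses_from_matrix(values, indicators, expert="E1", group="1"):
    out = []
    for i in range(len(indicators)):
        for e in range(i + 1, len(indicators)):
            out.append(
                g.ComparisonResponse(expert, group, indicators[i],
                                     indicators[e], float(values[i][e]))
            )
    return out


positive_weights = st.lists(
    st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=7
).map(lambda v: np.array(v) / np.sum(v))


class TestBuildJudgmentMatrix:
    def test_all_neutral_gives_all_ones(self):
        codes = [f"1.{k}" for k in range(1, 7)]
        resp = responses_from_matrix(np.ones((6, 6)), codes)
        m = g.build_judgment_matrix(resp, indicators=codes)
        assert np.array_equal(m.values, np.ones((6, 6)))

    def test_ratio_construction(self):
        # preferences from w = (0.5, 0.3, 0.2): r_12 = 5/3, r_13 = 2.5, r_23 = 1.5
        w = np.array([0.5, 0.3, 0.2])
        codes = ["a", "b", "c"]
        resp = responses_from_matrix(np.outer(w, 1 / w), codes)
        m = g.build_judgment_matrix(resp, indicators=codes)
        assert m.values[0, 1] == pytest.approx(5 / 3)
        assert m.values[0, 2] == pytest.approx(2.5)
        assert m.values[1, 2] == pytest.approx(1.5)
        assert np.allclose(m.values * m.values.T, 1.0)

    def test_missing_pair_is_completeness_error(self):
        resp = [
            g.ComparisonResponse("E1", "1", "a", "b", 2.0),
            g.ComparisonResponse("E1", "1", "b", "c", 3.0),
        ]
        with pytest.raises(g.CompletenessError, match="missing"):
            g.build_judgment_matrix(resp, indicators=["a", "b", "c"])

    def test_duplicate_pair_rejected(self):
        resp = [
            g.ComparisonResponse("E1", "1", "a", "b", 2.0),
            g.ComparisonResponse("E1", "1", "b", "a", 3.0),
        ]
        with pytest.raises(g.CompletenessError, match="duplicate"):
            g.build_judgment_matrix(resp, indicators=["a", "b"])

    def test_value_outside_scale_rejected(self):
        resp = [g.ComparisonResponse("E1", "1", "a", "b", 12.0)]
        with pytest.raises(ValueError, match="scale bounds"):
            g.build_judgment_matrix(resp, indicators=["a", "b"])

    def test_complementary_scale_mirrors_to_one(self):
        resp = [g.ComparisonResponse("E1", "1", "a", "b", 0.7)]
        m = g.build_judgment_matrix(resp, indicators=["a", "b"],
                                    scale="complementary")
        assert m.values[1, 0] == pytest.approx(0.3)
        assert np.allclose(np.diag(m.values), 0.5)


class TestAggregate:
    def test_identical_matrices_idempotent(self):
        m = consistent_matrix([0.5, 0.3, 0.2])
        agg = g.aggregate_judgments([m, m, m])
        assert np.allclose(agg.values, m.values)

    def test_geometric_mean_of_two(self):
        def mat(r12):
            return g.JudgmentMatrix("1", ["a", "b"],
                                    np.array([[1, r12], [1 / r12, 1]]))
        agg = g.aggregate_judgments([mat(2.0), mat(8.0)])
        assert agg.values[0, 1] == pytest.approx(4.0)  # sqrt(2 * 8)

    def test_dimension_mismatch(self):
        with pytest.raises(g.AggregationError):
            g.aggregate_judgments(
                [consistent_matrix([0.5, 0.5]), consistent_matrix([0.4, 0.3, 0.3])]
            )

    def test_empty_list(self):
        with pytest.raises(g.AggregationError):
            g.aggregate_judgments([])


class TestWeights:
    def test_consistent_matrix_recovery(self):
        wv = g.fahp_weights(consistent_matrix([0.5, 0.3, 0.2]))
        assert np.allclose(wv.weights, [0.5, 0.3, 0.2], atol=1e-12)

    def test_neutral_matrix_uniform(self):
        m = g.JudgmentMatrix("1", list("abcde"), np.ones((5, 5)))
        assert np.allclose(g.fahp_weights(m).weights, 0.2)

    def test_two_by_two(self):
        m = g.JudgmentMatrix("1", ["a", "b"], np.array([[1.0, 4.0], [0.25, 1.0]]))
        assert np.allclose(g.fahp_weights(m).weights, [0.8, 0.2])

    def test_complementary_matrix_weights(self):
        # b_ie = r_ie / r_ei turns 0.8 into ratio 4 -> weights (0.8, 0.2)
        m = g.JudgmentMatrix("1", ["a", "b"],
                             np.array([[0.5, 0.8], [0.2, 0.5]]),
                             scale="complementary")
        assert np.allclose(g.fahp_weights(m).weights, [0.8, 0.2])

    def test_second_normalization_is_idempotent(self):
        wv = g.fahp_weights(consistent_matrix([0.4, 0.35, 0.25]))
        assert np.allclose(wv.raw, wv.weights)
        assert wv.weights.sum() == pytest.approx(1.0, abs=1e-12)

    @given(positive_weights)
    def test_exact_recovery_property(self, w):
        wv = g.fahp_weights(consistent_matrix(w))
        assert np.allclose(wv.weights, w, atol=1e-12)

    @given(positive_weights, st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, w, rnd):
        perm = list(range(len(w)))
        rnd.shuffle(perm)
        m = consistent_matrix(w)
        permuted = g.JudgmentMatrix(
            m.group_code,
            [m.indicators[p] for p in perm],
            m.values[np.ix_(perm, perm)],
        )
        assert np.allclose(
            g.fahp_weights(permuted).weights,
            g.fahp_weights(m).weights[perm],
            atol=1e-12,
        )

    @given(positive_weights)
    def test_consensus_of_consistent_matrices_recovers_truth(self, w):
        agg = g.aggregate_judgments([consistent_matrix(w)] * 3)
        assert np.allclose(g.fahp_weights(agg).weights, w, atol=1e-12)


class TestConsistencyRatio:
    def test_consistent_matrix_is_zero(self):
        assert g.consistency_ratio(consistent_matrix([0.5, 0.2, 0.2, 0.1])) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_two_by_two_always_zero(self):
        m = g.JudgmentMatrix("1", ["a", "b"], np.array([[1.0, 7.0], [1 / 7, 1.0]]))
        assert g.consistency_ratio(m) == 0.0

    def test_against_characteristic_polynomial_root(self):
        # r_12 = 2, r_13 = 4, r_23 = 4: find lambda_max independently as the
        # largest root of det(A - lambda I) by bracketed root search
        A = np.array([[1, 2, 4], [0.5, 1, 4], [0.25, 0.25, 1]])

        def det(lam):
            M = A - lam * np.eye(3)
            return (
                M[0, 0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
                - M[0, 1] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
                + M[0, 2] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0])
            )

        lam_max = brentq(det, 3.0, 4.0)
        expected = ((lam_max - 3) / 2) / 0.58
        m = g.JudgmentMatrix("1", ["a", "b", "c"], A)
        assert g.consistency_ratio(m) == pytest.approx(expected, rel=1e-9)

    def test_complementary_unsupported(self):
        m = g.JudgmentMatrix("1", ["a", "b"],
                             np.array([[0.5, 0.6], [0.4, 0.5]]),
                             scale="complementary")
        with pytest.raises(g.ScaleError):
            g.consistency_ratio(m)


class TestQuestionnaireIO:
    def test_round_trip(self, tmp_path):
        spec = g.ExpertPanelSpec(group_sizes=(3, 2), n_experts=2, noise_sd=0.05,
                                 seed=3)
        resp = g.simulate_expert_responses(spec)
        path = g.write_questionnaire(resp, tmp_path / "q.csv")
        again = g.read_questionnaire(path)
        assert again == resp

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("expert_id,value\nE1,2\n")
        with pytest.raises(g.FormatError, match="missing columns"):
            g.read_questionnaire(p)

    def test_panel_weights_two_routes_agree_when_consistent(self):
        spec = g.ExpertPanelSpec(noise_sd=0.0, seed=5)
        resp = g.simulate_expert_responses(spec)
        pooled = g.panel_weights(resp)
        averaged = g.panel_weights(resp, per_expert_average=True)
        for grp in pooled:
            assert np.allclose(pooled[grp].weights, averaged[grp].weights,
                               atol=1e-12)
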