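"""CCR/BCC envelopment solver, decomposition, classification, projection."""

import numpy as np
import pytest

from caredea._vertex import brute_force_theta
from caredea.dea import (
    DEAEfficiency,
    DMUPanel,
    classify_efficiency,
    classify_rts,
    efficiency_decomposition,
    evaluate_panel,
    projection_targets,
    solve_envelopment,
    summarize_results,
)
from caredea.datasets import load_efficiency_results
from caredea.exceptions import ConsistencyError, InvalidInputError


def random_positive_panel(rng, n, m, s, low=1.0, high=10.0):
    """Unstructured positive panel for property-style checks."""
    return rng.uniform(low, high, size=(n, m)), rng.uniform(low, high, size=(n, s))


class TestSolver:
    def test_single_ratio_closed_form(self):
        X = np.array([[1.0], [2.0]])
        Y = np.array([[1.0], [1.0]])
        fit = DEAEfficiency(model="ccr").fit(X, Y)
        assert fit.efficiency_ == pytest.approx([1.0, 0.5], abs=1e-9)

    def test_identical_dmus_all_efficient(self):
        X = np.tile([3.0, 4.0], (4, 1))
        Y = np.tile([2.0], (4, 1))
        fit = DEAEfficiency(model="ccr").fit(X, Y)
        assert fit.efficiency_ == pytest.approx(np.ones(4), abs=1e-9)
        assert np.all(np.abs(fit.input_slacks_) < 1e-7)

    def test_three_dmu_instance_matches_vertex_oracle(self):
        X = np.array([[2.0, 4.0], [4.0, 2.0], [4.0, 4.0]])
        Y = np.array([[1.0], [1.0], [1.0]])
        sol = solve_envelopment(X, Y, 2, model="ccr")
        assert sol.theta < 1.0
        assert sol.theta == pytest.approx(brute_force_theta(X, Y, 2, "ccr"), abs=1e-8)
        assert sol.theta == pytest.approx(0.75, abs=1e-9)

    @pytest.mark.parametrize("model", ["ccr", "bcc"])
    def test_random_panels_match_vertex_oracle(self, model, rng):
        for _ in range(15):
            n = int(rng.integers(3, 6))
            X, Y = random_positive_panel(rng, n, int(rng.integers(1, 3)), int(rng.integers(1, 3)))
            o = int(rng.integers(n))
            sol = solve_envelopment(X, Y, o, model=model)
            assert sol.theta == pytest.approx(brute_force_theta(X, Y, o, model), abs=1e-7)

    def test_epsilon_mode_agrees_with_two_phase(self, rng):
        X, Y = random_positive_panel(rng, 6, 2, 2)
        for o in range(6):
            a = solve_envelopment(X, Y, o, model="ccr", slack_mode="two_phase")
            b = solve_envelopment(X, Y, o, model="ccr", slack_mode="epsilon", epsilon=1e-8)
            assert a.theta == pytest.approx(b.theta, abs=1e-6)

    def test_ccr_never_exceeds_bcc(self, rng):
        for _ in range(8):
            X, Y = random_positive_panel(rng, int(rng.integers(3, 8)), 2, 2)
            ccr = DEAEfficiency(model="ccr").fit(X, Y)
            bcc = DEAEfficiency(model="bcc").fit(X, Y)
            assert np.all(ccr.efficiency_ <= bcc.efficiency_ + 1e-7)

    def test_units_invariance(self, rng):
        X, Y = random_positive_panel(rng, 6, 3, 2)
        base = DEAEfficiency(model="ccr").fit(X, Y)
        X2 = X.copy()
        X2[:, 1] *= 40.0
        scaled = DEAEfficiency(model="ccr").fit(X2, Y)
        assert scaled.efficiency_ == pytest.approx(base.efficiency_, abs=1e-7)
        assert scaled.input_slacks_[:, 1] == pytest.approx(40.0 * base.input_slacks_[:, 1], abs=1e-5)

    def test_dominated_dmu_leaves_frontier_unchanged(self, rng):
        X, Y = random_positive_panel(rng, 5, 2, 1)
        base = DEAEfficiency(model="ccr").fit(X, Y)
        X2 = np.vstack([X, X[0] * 2.0])  # radially dominated copy of DMU 0
        Y2 = np.vstack([Y, Y[0]])
        ext = DEAEfficiency(model="ccr").fit(X2, Y2)
        assert ext.efficiency_[:5] == pytest.approx(base.efficiency_, abs=1e-7)
        assert ext.efficiency_[5] == pytest.approx(base.efficiency_[0] / 2.0, abs=1e-7)

    def test_bcc_lambdas_sum_to_one(self, rng):
        X, Y = random_positive_panel(rng, 6, 2, 1)
        fit = DEAEfficiency(model="bcc").fit(X, Y)
        assert fit.lambda_.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-7)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(InvalidInputError):
            DMUPanel(["a", "b"], np.array([[1.0], [0.0]]), np.array([[1.0], [1.0]]))
        with pytest.raises(InvalidInputError):
            solve_envelopment(np.array([[1.0], [2.0]]), np.array([[1.0], [1.0]]), 5)


class TestDecompositionAndLabels:
    @pytest.mark.parametrize(
        "oe,te,se", [(0.883, 0.911, 0.969), (1.0, 1.0, 1.0), (0.835, 0.857, 0.974)]
    )
    def test_scale_efficiency_from_printed_pairs(self, oe, te, se):
        assert efficiency_decomposition(oe, te) == pytest.approx(se)

    def test_decomposition_rejects_oe_above_te(self):
        with pytest.raises(InvalidInputError):
            efficiency_decomposition(0.95, 0.90)
        with pytest.raises(InvalidInputError):
            efficiency_decomposition(0.5, 0.0)

    @pytest.mark.parametrize(
        "lam,expected", [(1.0, "crs"), (0.80, "irs"), (1.30, "drs")]
    )
    def test_rts_from_lambda_sum(self, lam, expected):
        assert classify_rts(lam) == expected

    def test_rts_alternative_optima_bracket(self):
        assert classify_rts(0.8, lambda_sum_range=(0.7, 1.1)) == "crs"
        assert classify_rts(0.8, lambda_sum_range=(0.6, 0.9)) == "irs"

    @pytest.mark.parametrize(
        "oe,te,se,slacks,expected",
        [
            (1.0, 1.0, 1.0, [0.0, 0.0], "efficient"),
            (0.858, 1.0, 0.858, [0.0, 6.102], "scale_inefficient"),
            (0.835, 0.857, 0.974, [19.396], "tech_and_scale_inefficient"),
        ],
    )
    def test_efficiency_classification(self, oe, te, se, slacks, expected):
        assert classify_efficiency(oe, te, se, slacks) == expected

    def test_inconsistent_triple_raises(self):
        with pytest.raises(ConsistencyError):
            classify_efficiency(0.9, 1.0, 0.5, [0.0])


class TestProjection:
    def test_efficient_dmu_projects_to_itself(self):
        t = projection_targets([5.0, 7.0], [3.0], 1.0, [0.0, 0.0], [0.0])
        assert t.x_target == pytest.approx([5.0, 7.0])
        assert t.y_target == pytest.approx([3.0])

    def test_literal_mode_subtracts_slack_only(self):
        t = projection_targets([100.0], [50.0], 0.835, [19.396], [2.194], mode="literal")
        assert t.x_target == pytest.approx([80.604])
        assert t.y_target == pytest.approx([52.194])

    def test_standard_mode_contracts_then_subtracts(self):
        t = projection_targets([100.0], [50.0], 0.835, [19.396], [2.194], mode="standard")
        assert t.x_target == pytest.approx([0.835 * 100 - 19.396])

    def test_negative_target_flagged(self):
        t = projection_targets([10.0], [5.0], 0.5, [8.0], [0.0], mode="standard")
        assert t.warnings


class TestSummary:
    def test_printed_rows_reproduce_means_and_counts(self):
        t6 = load_efficiency_results()
        table = t6.rename(columns={"dmu": "dmu"}).set_index("dmu")
        table["classification"] = [
            classify_efficiency(o, t, s, [sm, sp])
            for o, t, s, sm, sp in zip(
                table.oe, table.te, table.se, table.s_minus, table.s_plus
            )
        ]
        summary = summarize_results(table)
        assert (summary["mean_oe"], summary["mean_te"], summary["mean_se"]) == (
            0.935,
            0.972,
            0.963,
        )
        assert summary["n_efficient"] == 5
        assert summary["n_inefficient"] == 7
        assert summary["n_drs"] == 5

    def test_singleton_summary(self):
        import pandas as pd

        table = pd.DataFrame(
            {"oe": [1.0], "te": [1.0], "se": [1.0], "classification": ["efficient"]}
        )
        s = summarize_results(table)
        assert (s["mean_oe"], s["n_efficient"], s["n_inefficient"]) == (1.0, 1, 0)

    def test_empty_results_rejected(self):
        import pandas as pd

        with pytest.raises(InvalidInputError):
            summarize_results(pd.DataFrame())


def test_evaluate_panel_end_to_end(small_panel):
    panel, truth = small_panel
    result = evaluate_panel(panel)
    assert result.table.loc[
        result.table["classification"] == "efficient"
    ].shape[0] == int(np.sum(truth == 1.0))
    # planted CCR efficiencies shine through the rounded OE column
    assert result.table["oe"].to_numpy() == pytest.approx(truth, abs=5e-4)
    assert np.all(result.table["oe"] <= result.table["te"] + 1e-9)
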