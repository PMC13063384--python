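"""Delphi round statistics: enthusiasm, authority, consensus, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from caredea.delphi import (
    DelphiScreener,
    RatingMatrix,
    ScreeningThresholds,
    authority_coefficient,
    item_statistics,
    judgment_basis,
    kendalls_w,
    response_rate,
    screen_delphi_items,
)
from caredea.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

likert_matrices = st.integers(2, 8).flatmap(
    lambda m: st.integers(3, 10).flatmap(
        lambda n: st.lists(
            st.lists(st.integers(1, 5), min_size=n, max_size=n),
            min_size=m,
            max_size=m,
        )
    )
)


@pytest.mark.parametrize(
    "sent,returned,expected",
    [(17, 17, 100.0), (17, 16, 94.1), (10, 0, 0.0)],
)
def test_response_rate(sent, returned, expected):
    assert response_rate(sent, returned) == expected


def test_response_rate_rejects_bad_counts():
    with pytest.raises(InvalidInputError):
        response_rate(0, 0)
    with pytest.raises(InvalidInputError):
        response_rate(5, 6)


@pytest.mark.parametrize(
    "practical,theoretical,expected",
    [("high", "high", 1.0), ("low", "low", 0.6), ("medium", "high", 0.9)],
)
def test_judgment_basis_weight_table(practical, theoretical, expected):
    levels = {
        "practical_experience": practical,
        "theoretical_analysis": theoretical,
        "literature": "high",
        "intuition": "low",
    }
    assert judgment_basis(levels) == pytest.approx(expected)


def test_judgment_basis_rejects_unknowns():
    with pytest.raises(InvalidInputError):
        judgment_basis({"practical_experience": "high"})
    with pytest.raises(InvalidInputError):
        judgment_basis(
            {
                "practical_experience": "extreme",
                "theoretical_analysis": "low",
                "literature": "low",
                "intuition": "low",
            }
        )


@pytest.mark.parametrize(
    "ca,cs,expected",
    [(0.98, 0.86, 0.92), (0.94, 0.85, 0.90), (1.0, 1.0, 1.0)],
)
def test_authority_coefficient_half_up(ca, cs, expected):
    # (0.94 + 0.85)/2 = 0.895 must round *up* to 0.90, not to 0.89
    assert authority_coefficient(ca, cs) == pytest.approx(expected)


def test_authority_coefficient_range_check():
    with pytest.raises(InvalidInputError):
        authority_coefficient(1.2, 0.5)


@pytest.mark.parametrize(
    "scores,mean,cv,fsr",
    [
        ([5, 5, 5, 5], 5.0, 0.0, 1.0),
        ([5, 5, 4, 4], 4.5, 0.5773502691896257 / 4.5, 0.5),
        ([1, 5], 3.0, None, 0.5),
    ],
)
def test_item_statistics(scores, mean, cv, fsr):
    st_ = item_statistics(scores)
    assert st_.mean == pytest.approx(mean)
    assert st_.full_score_rate == pytest.approx(fsr)
    if cv is not None:
        assert st_.cv == pytest.approx(cv)
    assert st_.sd == pytest.approx(np.std(scores, ddof=1))


def test_item_statistics_needs_two_scores():
    with pytest.raises(InsufficientDataError):
        item_statistics([5])


class TestKendallsW:
    def test_identical_rankings_give_unity(self):
        scores = np.tile([1, 2, 4, 5], (3, 1))
        assert kendalls_w(scores).w == pytest.approx(1.0)

    def test_reversed_pair_matches_rank_variance_formula(self):
        scores = np.array([[1, 2, 3], [3, 2, 1]])
        res = kendalls_w(scores, tie_correction=False)
        # direct evaluation: column rank sums all equal -> S = 0 -> W = 0
        ranks = np.vstack([sps.rankdata(r) for r in scores])
        col = ranks.sum(axis=0)
        s = ((col - col.mean()) ** 2).sum()
        expected = 12 * s / (2**2 * (3**3 - 3))
        assert res.w == pytest.approx(expected) == 0.0

    @given(likert_matrices)
    @settings(max_examples=60, deadline=None)
    def test_chi2_identity_and_bounds(self, rows):
        scores = np.array(rows)
        try:
            res = kendalls_w(scores, tie_correction=False)
        except DegenerateDataError:
            return
        m, n = scores.shape
        assert 0.0 <= res.w <= 1.0 + 1e-12
        assert res.chi2 == pytest.approx(m * (n - 1) * res.w)
        assert res.df == n - 1

    def test_tie_corrected_matches_scipy_friedman(self, rng):
        scores = rng.integers(1, 6, size=(9, 6))
        res = kendalls_w(scores, tie_correction=True)
        stat, p = sps.friedmanchisquare(*scores.T)
        assert res.chi2 == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_invariant_to_expert_relabeling_and_monotone_rescoring(self, rng):
        scores = rng.integers(1, 6, size=(6, 8))
        base = kendalls_w(scores).w
        shuffled = scores[rng.permutation(6)]
        assert kendalls_w(shuffled).w == pytest.approx(base)
        # a rank-preserving transform of one expert's row leaves W unchanged
        mono = scores.astype(float).copy()
        mono[0] = mono[0] * 10 + 3
        assert kendalls_w(mono).w == pytest.approx(base)

    def test_all_tied_raises_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kendalls_w(np.full((4, 5), 3), tie_correction=True)

    def test_round1_shape_chi2_near_printed(self):
        # reconstructing chi2 from the rounded printed W must land within
        # the rounding band m(n-1)*0.0005 of the printed statistic
        for m, n, w, printed in [(17, 76, 0.471, 600.13), (16, 67, 0.348, 367.92)]:
            chi2 = m * (n - 1) * w
            assert abs(chi2 - printed) <= m * (n - 1) * 0.0005


class TestScreening:
    def test_boundary_item_removed_for_mean(self):
        out = screen_delphi_items(
            pd.DataFrame(
                {"mean": [3.4], "sd": [0.3], "cv": [0.1], "full_score_rate": [0.9]},
                index=["a"],
            )
        )
        assert not out.loc["a", "retained"]
        assert out.loc["a", "reasons"] == "mean"

    def test_passing_item_retained(self):
        out = screen_delphi_items(
            pd.DataFrame(
                {"mean": [4.9], "sd": [0.2], "cv": [0.05], "full_score_rate": [0.9]},
                index=["a"],
            )
        )
        assert out.loc["a", "retained"]
        assert out.loc["a", "reasons"] == ""

    def test_planted_violations_counted(self):
        # 10 items, 3 violate exactly one criterion each
        stats = pd.DataFrame(
            {
                "mean": [4.5] * 7 + [3.0, 4.5, 4.5],
                "sd": [0.3] * 10,
                "cv": [0.10] * 8 + [0.40, 0.10],
                "full_score_rate": [0.9] * 9 + [0.5],
            },
            index=[f"i{k}" for k in range(10)],
        )
        out = screen_delphi_items(stats)
        assert int(out["retained"].sum()) == 7
        assert out.loc["i7", "reasons"] == "mean"
        assert out.loc["i8", "reasons"] == "cv"
        assert out.loc["i9", "reasons"] == "full_score_rate"

    def test_relaxing_thresholds_is_monotone(self, rng):
        stats = pd.DataFrame(
            {
                "mean": rng.uniform(2.5, 5.0, 30),
                "sd": rng.uniform(0.1, 1.2, 30),
                "cv": rng.uniform(0.02, 0.5, 30),
                "full_score_rate": rng.uniform(0.0, 1.0, 30),
            },
            index=[f"i{k}" for k in range(30)],
        )
        strict = screen_delphi_items(stats, ScreeningThresholds(4.0, 0.20, 0.80))
        loose = screen_delphi_items(stats, ScreeningThresholds(3.5, 0.30, 0.60))
        assert set(strict.index[strict["retained"]]) <= set(loose.index[loose["retained"]])

    def test_empty_input_yields_empty_output(self):
        assert screen_delphi_items({}).empty

    def test_screener_transform_drops_failed_columns(self, rng):
        strong = rng.choice([4, 5], size=(10, 2), p=[0.2, 0.8])
        weak = rng.integers(1, 4, size=(10, 1))
        frame = pd.DataFrame(
            np.hstack([strong, weak]), columns=["good1", "good2", "bad"]
        )
        sc = DelphiScreener().fit(frame)
        kept = sc.transform(frame)
        assert "bad" not in kept.columns
        assert not sc.item_stats_.loc["bad", "retained"]

    def test_full_score_rate_permutation_invariant(self, rng):
        col = rng.integers(1, 6, size=25)
        a = item_statistics(col).full_score_rate
        b = item_statistics(rng.permutation(col)).full_score_rate
        assert a == b


def test_rating_matrix_validation():
    items = 3 * [None]
    from caredea.delphi import ItemMeta

    items = [ItemMeta(str(i + 1), f"item {i}", 1, "S") for i in range(3)]
    with pytest.raises(InvalidInputError):
        RatingMatrix(items=items, scores=np.array([[1, 2, 6], [1, 2, 3]]))
    with pytest.raises(InvalidInputError):
        RatingMatrix(items=items, scores=np.array([[1, 2, 3]]))  # one expert
    with pytest.raises(InvalidInputError):
        ItemMeta("1.1", "mismatch", 3, "S")
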