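"""Delphi expert-consultation statistics and item screening.

A Delphi round yields a matrix of Likert importance scores (one row per
expert, one column per candidate indicator) plus each expert's
self-assessment of judgment basis and topic familiarity.  This module
computes the round-level quality statistics used to defend such a panel —
response rate (enthusiasm), authority coefficient Cr = (Ca + Cs)/2, and
consensus via the coefficient of variation and Kendall's coefficient of
concordance W — and applies the item-level retention rules
(mean, CV, full-score-rate thresholds).

Kendall's W is computed from within-expert ranks with average ranks for
ties; the tie-correction term is subtracted from the denominator by
default, which is the standard convention for heavily tied ordinal data.
An uncorrected mode is provided because the associated chi-square statistic
then satisfies the exact identity chi2 = m(n-1)W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import round_half_up
from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "ItemMeta",
    "RatingMatrix",
    "ExpertAuthority",
    "ItemStats",
    "ConcordanceResult",
    "ScreeningThresholds",
    "TABLE_PRESET_THRESHOLDS",
    "DelphiScreener",
    "response_rate",
    "judgment_basis",
    "familiarity_score",
    "authority_coefficient",
    "item_statistics",
    "kendalls_w",
    "screen_delphi_items",
]

# Pre-assigned weights for the judgment-basis (Ca) self-assessment: each
# expert rates how much each of four sources influenced their answers.
# Literature and intuition carry a fixed weight regardless of level.
_CA_WEIGHTS: dict[str, dict[str, float]] = {
    "practical_experience": {"high": 0.5, "medium": 0.4, "low": 0.3},
    "theoretical_analysis": {"high": 0.3, "medium": 0.2, "low": 0.1},
    "literature": {"high": 0.1, "medium": 0.1, "low": 0.1},
    "intuition": {"high": 0.1, "medium": 0.1, "low": 0.1},
}

_CS_SCORES: dict[str, float] = {
    "very_familiar": 1.0,
    "familiar": 0.8,
    "moderate": 0.6,
    "unfamiliar": 0.4,
    "very_unfamiliar": 0.2,
}


@dataclass(frozen=True)
class ItemMeta:
    """One candidate indicator: hierarchical code, label, level, S-P-O tag.

    The hierarchical code encodes the level: ``"1"`` is first-level,
    ``"1.1"`` second, ``"1.1.1"`` third (Donabedian structure/process/
    outcome tag alongside).
    """

    id: str
    label: str
    level: int
    spo: str

    def __post_init__(self) -> None:
        depth = len(str(self.id).split("."))
        if depth != self.level:
            raise InvalidInputError(
                f"item {self.id!r}: code depth {depth} != declared level {self.level}"
            )
        if self.spo not in {"S", "P", "O"}:
            raise InvalidInputError(f"item {self.id!r}: spo tag must be S, P or O, got {self.spo!r}")


@dataclass
class RatingMatrix:
    """Likert scores for one consultation round: experts x items.

    Experts who did not return the questionnaire are excluded as whole
    rows before construction; partially answered rows are invalid.
    """

    items: list[ItemMeta]
    scores: np.ndarray
    round_id: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise InvalidInputError("scores must be a 2-D experts x items matrix")
        m, n = self.scores.shape
        if m < 2 or n < 2:
            raise InvalidInputError(f"need >= 2 experts and >= 2 items, got {m} x {n}")
        if n != len(self.items):
            raise InvalidInputError(
                f"{len(self.items)} item descriptors for {n} score columns"
            )
        if not np.issubdtype(self.scores.dtype, np.number) or np.any(
            ~np.isin(self.scores, [1, 2, 3, 4, 5])
        ):
            raise InvalidInputError("all scores must be integers in 1..5")
        self.scores = self.scores.astype(int)

    @property
    def n_experts(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.item_ids())


@dataclass(frozen=True)
class ExpertAuthority:
    """One expert's authority self-assessment.

    ``judgment_levels`` maps each of the four judgment sources to
    high/medium/low; ``familiarity`` is the five-point familiarity level.
    """

    judgment_levels: dict
    familiarity: str

    @property
    def ca(self) -> float:
        return judgment_basis(self.judgment_levels)

    @property
    def cs(self) -> float:
        return familiarity_score(self.familiarity)

    @property
    def cr(self) -> float:
        return authority_coefficient(self.ca, self.cs)


@dataclass(frozen=True)
class ItemStats:
    """Per-item consensus statistics for one Delphi round."""

    mean: float
    sd: float
    cv: float
    full_score_rate: float


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its chi-square significance test."""

    w: float
    chi2: float
    df: int
    p_value: float
    tie_corrected: bool
    n_experts: int
    n_items: int


def response_rate(n_sent: int, n_returned: int) -> float:
    """Percentage of distributed questionnaires that came back, to 1 dp.

    The Delphi enthusiasm coefficient; above 70% is conventionally taken
    as adequate engagement.
    """
    if n_sent < 1:
        raise InvalidInputError("n_sent must be >= 1")
    if not 0 <= n_returned <= n_sent:
        raise InvalidInputError(f"n_returned must be in [0, {n_sent}], got {n_returned}")
    return round_half_up(100.0 * n_returned / n_sent, 1)


def judgment_basis(levels: dict) -> float:
    """Judgment-basis coefficient Ca from the four-source weight table.

    Practical experience contributes 0.5/0.4/0.3 (high/medium/low),
    theoretical analysis 0.3/0.2/0.1, literature and intuition 0.1 each
    regardless of level; Ca is the sum, ranging 0.6 to the theoretical
    maximum of 1.0.
    """
    missing = set(_CA_WEIGHTS) - set(levels)
    if missing:
        raise InvalidInputError(f"judgment levels missing for: {sorted(missing)}")
    total = 0.0
    for source, level in levels.items():
        try:
            total += _CA_WEIGHTS[source][level]
        except KeyError:
            raise InvalidInputError(
                f"unknown judgment source/level: {source!r}={level!r}"
            ) from None
    return round_half_up(total, 2)


def familiarity_score(familiarity: str) -> float:
    """Familiarity coefficient Cs on the five-point 0.2..1.0 scale."""
    try:
        return _CS_SCORES[familiarity]
    except KeyError:
        raise InvalidInputError(f"unknown familiarity level: {familiarity!r}") from None


def authority_coefficient(ca: float, cs: float) -> float:
    """Authority coefficient Cr = (Ca + Cs) / 2, reported to 2 dp (half-up).

    Cr >= 0.7 is the conventional reliability threshold for an expert
    panel.
    """
    for name, v in (("ca", ca), ("cs", cs)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
    return round_half_up((ca + cs) / 2.0, 2)


def item_statistics(column) -> ItemStats:
    """Mean, sample SD, CV and full-score rate for one item's scores.

    The SD uses the n-1 denominator; CV = sd / mean; the full-score rate
    is the proportion of experts awarding the maximum score of 5.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("expected a 1-D score column")
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 scores, got {x.size}")
    if np.any(~np.isin(x, [1, 2, 3, 4, 5])):
        raise InvalidInputError("scores must be in 1..5")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return ItemStats(mean=mean, sd=sd, cv=sd / mean, full_score_rate=float(np.mean(x == 5)))


def _tie_term(row_ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups in one expert's ranks."""
    _, counts = np.unique(row_ranks, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def kendalls_w(ratings, tie_correction: bool = True) -> ConcordanceResult:
    """Kendall's coefficient of concordance W over a raters x items matrix.

    Parameters
    ----------
    ratings : RatingMatrix or array-like
        Scores with one row per expert, one column per item.
    tie_correction : bool
        Subtract the tie term ``m * sum_j T_j`` (``T_j = sum(t^3 - t)``
        over expert ``j``'s tie groups) from the denominator.  With the
        correction, identical raters give W = 1 even when each rates
        several items equally; without it the exact identity
        ``chi2 = m (n-1) W`` holds against the rank-variance definition.

    Returns
    -------
    ConcordanceResult
        W in [0, 1], chi2 = m(n-1)W on n-1 degrees of freedom, and the
        upper-tail chi-square p-value.
    """
    scores = ratings.scores if isinstance(ratings, RatingMatrix) else np.asarray(ratings, dtype=float)
    if scores.ndim != 2:
        raise InvalidInputError("ratings must be a 2-D experts x items matrix")
    m, n = scores.shape
    if m < 2:
        raise InsufficientDataError(f"need >= 2 experts, got {m}")
    if n < 3:
        raise InsufficientDataError(f"need >= 3 items for concordance, got {n}")

    ranks = stats.rankdata(scores, axis=1)  # average ranks within each expert
    col_sums = ranks.sum(axis=0)
    s = float(np.sum((col_sums - col_sums.mean()) ** 2))

    denom = m**2 * (n**3 - n) / 12.0
    if tie_correction:
        denom -= m * sum(_tie_term(ranks[i]) for i in range(m)) / 12.0
    if denom <= 0:
        raise DegenerateDataError(
            "every expert rated all items identically; W is undefined under tie correction"
        )

    w = s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    return ConcordanceResult(
        w=float(w),
        chi2=float(chi2),
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        tie_corrected=tie_correction,
        n_experts=m,
        n_items=n,
    )


@dataclass(frozen=True)
class ScreeningThresholds:
    """Item-retention thresholds; set a field to ``None`` to disable it.

    Defaults follow the common first-stage rule: mean importance >= 3.5,
    CV < 0.25, full-score rate > 70%.
    """

    mean_min: float | None = 3.5
    cv_max: float | None = 0.25
    fsr_min: float | None = 0.70


#: Stricter preset used when the screening step demands a mean score of 4.
TABLE_PRESET_THRESHOLDS = ScreeningThresholds(mean_min=4.0, cv_max=0.25, fsr_min=0.70)


def screen_delphi_items(
    stats_by_item: dict | pd.DataFrame,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> pd.DataFrame:
    """Apply retention thresholds to per-item statistics.

    An item is retained iff every enabled criterion passes: mean >=
    ``mean_min``, cv < ``cv_max``, full-score rate > ``fsr_min``.  Returns
    a DataFrame indexed by item id with the statistics, a ``retained``
    flag and a ``reasons`` column listing the failed criteria
    (comma-separated; empty when retained).
    """
    if isinstance(stats_by_item, pd.DataFrame):
        records = {
            idx: ItemStats(row["mean"], row.get("sd", np.nan), row["cv"], row["full_score_rate"])
            for idx, row in stats_by_item.iterrows()
        }
    else:
        records = dict(stats_by_item)

    rows = []
    for item_id, st in records.items():
        reasons = []
        if thresholds.mean_min is not None and not st.mean >= thresholds.mean_min:
            reasons.append("mean")
        if thresholds.cv_max is not None and not st.cv < thresholds.cv_max:
            reasons.append("cv")
        if thresholds.fsr_min is not None and not st.full_score_rate > thresholds.fsr_min:
            reasons.append("full_score_rate")
        rows.append(
            {
                "item": item_id,
                "mean": st.mean,
                "sd": st.sd,
                "cv": st.cv,
                "full_score_rate": st.full_score_rate,
                "retained": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["item", "mean", "sd", "cv", "full_score_rate", "retained", "reasons"]
        ).set_index("item")
    return out.set_index("item")


class DelphiScreener(BaseEstimator, TransformerMixin):
    """Feature-selector-style screener for Delphi rating matrices.

    Fits on an experts x items score matrix, computes per-item statistics
    (mean, sample SD, CV, full-score rate) and marks items that pass all
    enabled thresholds; ``transform`` keeps only the retained columns.

    Parameters
    ----------
    mean_min, cv_max, fsr_min : float or None
        Retention thresholds (item kept iff mean >= mean_min, cv < cv_max,
        full-score rate > fsr_min); ``None`` disables a criterion.

    Attributes
    ----------
    item_stats_ : pandas.DataFrame
        Statistics, retained flag and failure reasons per item.
    support_ : ndarray of bool, shape (n_items,)
        Mask of retained items.
    retained_ids_ : list of str
    """

    def __init__(
        self,
        mean_min: float | None = 3.5,
        cv_max: float | None = 0.25,
        fsr_min: float | None = 0.70,
    ):
        self.mean_min = mean_min
        self.cv_max = cv_max
        self.fsr_min = fsr_min

    def _thresholds(self) -> ScreeningThresholds:
        return ScreeningThresholds(self.mean_min, self.cv_max, self.fsr_min)

    def fit(self, X, y=None):
        if isinstance(X, RatingMatrix):
            frame = X.to_frame()
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X)
            frame = pd.DataFrame(arr, columns=[f"item_{j}" for j in range(arr.shape[1])])
        stats_map = {col: item_statistics(frame[col].to_numpy()) for col in frame.columns}
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.item_stats_ = screen_delphi_items(stats_map, self._thresholds())
        self.support_ = self.item_stats_["retained"].to_numpy(dtype=bool)
        self.retained_ids_ = [str(i) for i in self.item_stats_.index[self.support_]]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, RatingMatrix):
            X = X.to_frame()
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


@dataclass
class DelphiRoundReport:
    """Round-level summary: engagement, authority, consensus, screening."""

    round_id: int
    response_rate: float
    cr: float | None
    concordance: ConcordanceResult
    mean_cv: float
    item_stats: pd.DataFrame = field(repr=False)


def summarize_round(
    ratings: RatingMatrix,
    n_sent: int,
    authorities: list[ExpertAuthority] | None = None,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    tie_correction: bool = True,
) -> DelphiRoundReport:
    """Full statistics for one consultation round.

    Cr is computed from the panel-mean Ca and Cs when authority
    self-assessments are supplied (the convention used when a round is
    reported with a single authority coefficient).
    """
    conc = kendalls_w(ratings, tie_correction=tie_correction)
    screener = DelphiScreener(thresholds.mean_min, thresholds.cv_max, thresholds.fsr_min)
    screener.fit(ratings)
    cr = None
    if authorities:
        ca = float(np.mean([a.ca for a in authorities]))
        cs = float(np.mean([a.cs for a in authorities]))
        cr = authority_coefficient(round_half_up(ca, 2), round_half_up(cs, 2))
    return DelphiRoundReport(
        round_id=ratings.round_id,
        response_rate=response_rate(n_sent, ratings.n_experts),
        cr=cr,
        concordance=conc,
        mean_cv=float(screener.item_stats_["cv"].mean()),
        item_stats=screener.item_stats_,
    )
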