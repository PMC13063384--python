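"""DEA dimensionality rules and correlation-based indicator selection.

DEA loses discriminatory power when the indicator count is large relative
to the number of decision-making units (DMUs).  Two rule-of-thumb
constraints are enforced here: the total number of input and output
indicators must not exceed half the number of DMUs, and the number of
DMUs must be at least the product of the input and output counts.  A
third, looser convention (DMUs >= twice the indicator total) is reported
alongside for reference.

The third screening stage ranks the surviving candidate indicators by
their strongest cross-role Pearson correlation (an input is judged by how
strongly it correlates with some output, and vice versa), eliminates
indicators with no significant strong pair, and keeps the top-k subject
to the dimensionality rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import EmptySelectionError, InvalidInputError

__all__ = [
    "RuleOfThumbVerdict",
    "rule_of_thumb",
    "correlation_matrix",
    "SelectionResult",
    "CorrelationSelector",
    "select_top_k",
]


@dataclass(frozen=True)
class RuleOfThumbVerdict:
    """Per-rule booleans for a (n_dmu, n_inputs, n_outputs) configuration.

    ``feasible`` combines the half-of-DMUs and product rules; the
    twice-the-total rule is reported separately because it is a distinct
    (and weaker) convention.
    """

    n_dmu: int
    n_inputs: int
    n_outputs: int
    half_rule: bool
    product_rule: bool
    twice_rule: bool

    @property
    def feasible(self) -> bool:
        return self.half_rule and self.product_rule


def rule_of_thumb(n_dmu: int, n_inputs: int, n_outputs: int) -> RuleOfThumbVerdict:
    """Check DEA dimensionality rules for a candidate model shape."""
    for name, v in (("n_dmu", n_dmu), ("n_inputs", n_inputs), ("n_outputs", n_outputs)):
        if v < 1:
            raise InvalidInputError(f"{name} must be >= 1, got {v}")
    total = n_inputs + n_outputs
    return RuleOfThumbVerdict(
        n_dmu=n_dmu,
        n_inputs=n_inputs,
        n_outputs=n_outputs,
        half_rule=total <= n_dmu / 2.0,
        product_rule=n_inputs * n_outputs <= n_dmu,
        twice_rule=n_dmu >= 2 * total,
    )


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Pearson r and two-tailed p over indicator columns.

    Returns (r, p, excluded): symmetric r with unit diagonal, p-values
    from the t-distribution on n-2 df, and the list of zero-variance
    columns that were flagged and excluded from pairing.
    """
    if table.shape[0] < 3:
        raise InvalidInputError(f"need >= 3 DMUs for correlation, got {table.shape[0]}")
    if table.isna().any().any():
        raise InvalidInputError("indicator table has missing values")
    excluded = [c for c in table.columns if np.isclose(table[c].std(ddof=0), 0.0)]
    cols = [c for c in table.columns if c not in excluded]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        res = stats.pearsonr(table[a], table[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p, excluded


@dataclass
class SelectionResult:
    """Outcome of the correlation-based selection stage."""

    selected: list[str]
    n_inputs: int
    n_outputs: int
    r: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)
    max_cross_r: pd.Series = field(repr=False)
    trace: list[str] = field(default_factory=list, repr=False)
    verdict: RuleOfThumbVerdict | None = None


class CorrelationSelector(BaseEstimator):
    """Select input/output indicators for DEA by cross-role correlation.

    Procedure: flag and drop zero-variance columns; compute pairwise
    Pearson r and p; eliminate indicators whose every cross-role pair
    fails |r| > ``r_min`` with p < ``alpha``; rank survivors by their
    maximum cross-role |r| (ties broken by indicator id); keep the top
    ``cap`` (default: half the DMU count), shrinking further if the
    dimensionality rules reject the shape.  Both roles are always
    represented: if the capped prefix is single-role, the best indicator
    of the missing role replaces the weakest selected one.

    Parameters
    ----------
    cap : int or None
        Maximum indicators to keep; ``None`` means ``floor(n_dmu / 2)``.
    r_min : float
        Minimum |r| for a pair to count as strong (default 0.7).
    alpha : float
        Two-tailed significance level for a pair to count (0.05 or 0.01).

    Attributes
    ----------
    result_ : SelectionResult
    selected_ids_ : list of str
    """

    def __init__(self, cap: int | None = None, r_min: float = 0.7, alpha: float = 0.05):
        self.cap = cap
        self.r_min = r_min
        self.alpha = alpha

    def fit(self, table: pd.DataFrame, roles: dict):
        if self.cap is not None and self.cap < 2:
            raise InvalidInputError(f"cap must be >= 2, got {self.cap}")
        missing = set(table.columns) - set(roles)
        if missing:
            raise InvalidInputError(f"no role tag for indicators: {sorted(missing)}")
        bad = {c: roles[c] for c in table.columns if roles[c] not in ("input", "output")}
        if bad:
            raise InvalidInputError(f"roles must be 'input' or 'output': {bad}")

        n_dmu = table.shape[0]
        cap = self.cap if self.cap is not None else n_dmu // 2
        trace: list[str] = []

        r, p, excluded = correlation_matrix(table)
        for c in excluded:
            trace.append(f"excluded {c}: zero variance")

        cols = list(r.columns)
        # strongest significant cross-role correlation per indicator
        max_cross = {}
        for c in cols:
            partners = [d for d in cols if roles[d] != roles[c]]
            vals = [
                abs(r.loc[c, d])
                for d in partners
                if abs(r.loc[c, d]) > self.r_min and p.loc[c, d] < self.alpha
            ]
            max_cross[c] = max(vals) if vals else np.nan
        max_cross = pd.Series(max_cross, dtype=float)

        survivors = [c for c in cols if np.isfinite(max_cross[c])]
        for c in cols:
            if c not in survivors:
                trace.append(
                    f"eliminated {c}: no cross-role pair with |r| > {self.r_min} and p < {self.alpha}"
                )
        if not survivors:
            raise EmptySelectionError(
                f"no indicator has a significant cross-role correlation above {self.r_min}"
            )
        roles_left = {roles[c] for c in survivors}
        if roles_left != {"input", "output"}:
            raise EmptySelectionError(
                f"only {sorted(roles_left)} indicators survive; need both roles"
            )

        # deterministic ranking: strongest max cross-role |r| first, id order on ties
        ranked = sorted(survivors, key=lambda c: (-max_cross[c], str(c)))
        trace.append("ranking: " + ", ".join(f"{c}={max_cross[c]:.3f}" for c in ranked))

        k = min(cap, len(ranked))
        while k >= 2:
            chosen = ranked[:k]
            sel_roles = [roles[c] for c in chosen]
            if "input" not in sel_roles or "output" not in sel_roles:
                missing_role = "input" if "input" not in sel_roles else "output"
                best_missing = next(c for c in ranked if roles[c] == missing_role)
                trace.append(
                    f"swapped in {best_missing} for {chosen[-1]} to cover role {missing_role}"
                )
                chosen = chosen[:-1] + [best_missing]
            ni = sum(roles[c] == "input" for c in chosen)
            no = sum(roles[c] == "output" for c in chosen)
            verdict = rule_of_thumb(n_dmu, ni, no)
            if verdict.feasible:
                break
            trace.append(f"k={k} rejected by rule of thumb ({ni} inputs, {no} outputs)")
            k -= 1
        else:
            raise EmptySelectionError(
                f"no feasible selection of >= 2 indicators for {n_dmu} DMUs"
            )

        self.result_ = SelectionResult(
            selected=chosen,
            n_inputs=ni,
            n_outputs=no,
            r=r,
            p=p,
            max_cross_r=max_cross,
            trace=trace,
            verdict=verdict,
        )
        self.selected_ids_ = list(chosen)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table.loc[:, self.selected_ids_]


def select_top_k(
    table: pd.DataFrame,
    roles: dict,
    k: int | None = None,
    r_min: float = 0.7,
    alpha: float = 0.05,
) -> SelectionResult:
    """Functional wrapper around :class:`CorrelationSelector`."""
    sel = CorrelationSelector(cap=k, r_min=r_min, alpha=alpha).fit(table, roles)
    return sel.result_
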