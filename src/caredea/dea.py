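"""Input-oriented CCR/BCC data envelopment analysis.

The envelopment program for decision-making unit (DMU) ``o`` with inputs
``x0`` and outputs ``y0`` is

    min  theta - eps * (e S- + e S+)
    s.t. sum_j X_j lambda_j + S- = theta * x0
         sum_j Y_j lambda_j - S+ = y0
         (BCC only)  sum_j lambda_j = 1
         lambda, S-, S+ >= 0

The non-Archimedean eps is handled by the standard two-phase procedure:
phase 1 minimizes the radial factor theta alone, phase 2 fixes theta at
its optimum and maximizes the total slack.  A literal small-eps
single-LP mode is available for comparison (``slack_mode="epsilon"``).

The CCR score (constant returns to scale) is overall efficiency OE; the
BCC score (convexity constraint added, variable returns) is pure
technical efficiency TE; scale efficiency SE = OE / TE.  Returns to
scale are read off the CCR intensity weights: sum(lambda*) below 1 means
increasing, above 1 decreasing returns; because the optimal lambda need
not be unique, the sum is bracketed by two auxiliary LPs and a unit is
classified constant-returns whenever 1 lies in the bracket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from ._utils import round_half_up, validate_positive_matrix
from .exceptions import ConsistencyError, InvalidInputError, SolverError

__all__ = [
    "DMUPanel",
    "EnvelopmentSolution",
    "DEAEfficiency",
    "DEAResult",
    "ProjectionTarget",
    "solve_envelopment",
    "efficiency_decomposition",
    "classify_rts",
    "classify_efficiency",
    "projection_targets",
    "evaluate_panel",
    "summarize_results",
]

_EFF_TOL = 1e-6


@dataclass
class DMUPanel:
    """Inputs/outputs panel: one row per DMU, strictly positive data."""

    dmu_ids: list[str]
    X: np.ndarray  # (n, m) inputs
    Y: np.ndarray  # (n, s) outputs
    input_names: list[str] | None = None
    output_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = validate_positive_matrix(self.X, "X")
        self.Y = validate_positive_matrix(self.Y, "Y")
        n = self.X.shape[0]
        if self.Y.shape[0] != n:
            raise InvalidInputError("X and Y must have the same number of DMU rows")
        if n < 2:
            raise InvalidInputError(f"need >= 2 DMUs, got {n}")
        if len(self.dmu_ids) != n:
            raise InvalidInputError(f"{len(self.dmu_ids)} ids for {n} DMUs")
        if self.input_names is None:
            self.input_names = [f"input_{i + 1}" for i in range(self.X.shape[1])]
        if self.output_names is None:
            self.output_names = [f"output_{r + 1}" for r in range(self.Y.shape[1])]

    @property
    def n_dmu(self) -> int:
        return self.X.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, roles: dict) -> "DMUPanel":
        inputs = [c for c in frame.columns if roles.get(c) == "input"]
        outputs = [c for c in frame.columns if roles.get(c) == "output"]
        if not inputs or not outputs:
            raise InvalidInputError("panel needs at least one input and one output column")
        return cls(
            dmu_ids=[str(i) for i in frame.index],
            X=frame[inputs].to_numpy(float),
            Y=frame[outputs].to_numpy(float),
            input_names=inputs,
            output_names=outputs,
        )


@dataclass(frozen=True)
class EnvelopmentSolution:
    """Optimal solution of one envelopment program."""

    theta: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    lambda_sum: float
    lambda_sum_range: tuple[float, float]


def _lp(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    return res


def solve_envelopment(
    X: np.ndarray,
    Y: np.ndarray,
    o: int,
    model: str = "ccr",
    slack_mode: str = "two_phase",
    epsilon: float = 1e-6,
) -> EnvelopmentSolution:
    """Solve the input-oriented envelopment program for DMU ``o``.

    Parameters
    ----------
    X, Y : ndarray
        Positive input (n, m) and output (n, s) matrices.
    o : int
        Row index of the evaluated DMU.
    model : {"ccr", "bcc"}
        Constant or variable returns to scale (BCC adds sum(lambda) = 1).
    slack_mode : {"two_phase", "epsilon"}
        Two-phase slack maximization (default) or the literal
        non-Archimedean single LP with a small finite ``epsilon``.
    """
    X = validate_positive_matrix(X, "X")
    Y = validate_positive_matrix(Y, "Y")
    n, m = X.shape
    s = Y.shape[1]
    if not 0 <= o < n:
        raise InvalidInputError(f"DMU index {o} outside panel of {n}")
    if model not in ("ccr", "bcc"):
        raise InvalidInputError(f"model must be 'ccr' or 'bcc', got {model!r}")
    if slack_mode not in ("two_phase", "epsilon"):
        raise InvalidInputError(f"unknown slack_mode {slack_mode!r}")

    x0, y0 = X[o], Y[o]
    n_eq = m + s + (1 if model == "bcc" else 0)
    nv = 1 + n + m + s  # theta, lambda, S-, S+

    A = np.zeros((n_eq, nv))
    b = np.zeros(n_eq)
    # input rows: -theta*x0 + X' lambda + S- = 0
    A[:m, 0] = -x0
    A[:m, 1 : 1 + n] = X.T
    A[:m, 1 + n : 1 + n + m] = np.eye(m)
    # output rows: Y' lambda - S+ = y0
    A[m : m + s, 1 : 1 + n] = Y.T
    A[m : m + s, 1 + n + m :] = -np.eye(s)
    b[m : m + s] = y0
    if model == "bcc":
        A[-1, 1 : 1 + n] = 1.0
        b[-1] = 1.0
    bounds = [(0, None)] * nv

    if slack_mode == "epsilon":
        c = np.zeros(nv)
        c[0] = 1.0
        c[1 + n :] = -epsilon
        res = _lp(c, A, b, bounds)
        theta = float(res.x[0])
        lam = res.x[1 : 1 + n]
        s_minus = res.x[1 + n : 1 + n + m]
        s_plus = res.x[1 + n + m :]
    else:
        c = np.zeros(nv)
        c[0] = 1.0
        res1 = _lp(c, A, b, bounds)
        theta = float(res1.x[0])
        # phase 2: fix theta, maximize total slack
        A2 = A[:, 1:].copy()
        b2 = b.copy()
        b2[:m] = theta * x0
        c2 = np.zeros(nv - 1)
        c2[n:] = -1.0
        res2 = _lp(c2, A2, b2, bounds[1:])
        lam = res2.x[:n]
        s_minus = res2.x[n : n + m]
        s_plus = res2.x[n + m :]

    # bracket sum(lambda) over the optimal face (alternative optima)
    A3 = A[:, 1:]
    b3 = b.copy()
    b3[:m] = theta * X[o]
    c3 = np.zeros(nv - 1)
    c3[:n] = 1.0
    lo = float(_lp(c3, A3, b3, bounds[1:]).fun)
    hi = float(-_lp(-c3, A3, b3, bounds[1:]).fun)

    return EnvelopmentSolution(
        theta=theta,
        lambdas=lam.copy(),
        input_slacks=s_minus.copy(),
        output_slacks=s_plus.copy(),
        lambda_sum=float(lam.sum()),
        lambda_sum_range=(lo, hi),
    )


class DEAEfficiency(BaseEstimator):
    """Input-oriented DEA efficiency scorer in estimator form.

    ``fit(X, Y)`` solves the envelopment program for every DMU in the
    panel (the panel is both the sample and the reference technology,
    as in any DEA study).

    Parameters
    ----------
    model : {"ccr", "bcc"}
        Returns-to-scale assumption.
    slack_mode : {"two_phase", "epsilon"}
        Slack treatment; see :func:`solve_envelopment`.
    epsilon : float
        Non-Archimedean constant for ``slack_mode="epsilon"``.
    tol : float
        Efficiency equality tolerance: a DMU counts as radially efficient
        when ``theta >= 1 - tol``, and as fully efficient when its slacks
        are also below ``tol`` times the data scale.

    Attributes
    ----------
    efficiency_ : ndarray (n,)
        Radial scores theta in (0, 1].
    lambda_ : ndarray (n, n)
        Intensity weights; row j gives DMU j's peer weights.
    input_slacks_, output_slacks_ : ndarray
        Phase-2 maximal slacks.
    lambda_sum_ : ndarray (n,)
        sum(lambda*) at the reported optimum.
    lambda_sum_range_ : ndarray (n, 2)
        Min/max of sum(lambda) over the optimal face.
    is_efficient_ : ndarray of bool (n,)
        theta = 1 and all slacks zero, within tolerance.
    """

    def __init__(
        self,
        model: str = "ccr",
        slack_mode: str = "two_phase",
        epsilon: float = 1e-6,
        tol: float = _EFF_TOL,
    ):
        self.model = model
        self.slack_mode = slack_mode
        self.epsilon = epsilon
        self.tol = tol

    def fit(self, X, Y=None):
        if isinstance(X, DMUPanel):
            panel = X
        else:
            if Y is None:
                raise InvalidInputError("Y (outputs) required when X is not a DMUPanel")
            X = np.asarray(X, dtype=float)
            Y = np.asarray(Y, dtype=float)
            if X.ndim == 1:
                X = X.reshape(-1, 1)
            if Y.ndim == 1:
                Y = Y.reshape(-1, 1)
            panel = DMUPanel([str(i) for i in range(len(X))], X, Y)
        n = panel.n_dmu
        sols = [
            solve_envelopment(
                panel.X, panel.Y, j, model=self.model, slack_mode=self.slack_mode, epsilon=self.epsilon
            )
            for j in range(n)
        ]
        self.panel_ = panel
        self.efficiency_ = np.array([s.theta for s in sols])
        self.lambda_ = np.vstack([s.lambdas for s in sols])
        self.input_slacks_ = np.vstack([s.input_slacks for s in sols])
        self.output_slacks_ = np.vstack([s.output_slacks for s in sols])
        self.lambda_sum_ = np.array([s.lambda_sum for s in sols])
        self.lambda_sum_range_ = np.array([s.lambda_sum_range for s in sols])
        scale = max(panel.X.max(), panel.Y.max())
        slack_ok = (
            np.max(np.abs(self.input_slacks_), axis=1, initial=0.0) <= self.tol * scale
        ) & (np.max(np.abs(self.output_slacks_), axis=1, initial=0.0) <= self.tol * scale)
        self.is_efficient_ = (self.efficiency_ >= 1 - self.tol) & slack_ok
        self.n_features_in_ = panel.n_inputs
        return self

    def projection(self, mode: str = "standard") -> tuple[np.ndarray, np.ndarray]:
        """Frontier targets for every DMU; see :func:`projection_targets`."""
        xs, ys = [], []
        for j in range(self.panel_.n_dmu):
            t = projection_targets(
                self.panel_.X[j],
                self.panel_.Y[j],
                self.efficiency_[j],
                self.input_slacks_[j],
                self.output_slacks_[j],
                mode=mode,
            )
            xs.append(t.x_target)
            ys.append(t.y_target)
        return np.vstack(xs), np.vstack(ys)


@dataclass(frozen=True)
class ProjectionTarget:
    """Frontier projection for one DMU.

    ``standard`` mode applies the radial contraction before removing the
    residual input slack (x* = theta x0 - S-); ``literal`` mode subtracts
    the slack from the *original* inputs (x* = x0 - S-), the reading in
    which the slack alone measures the input reduction.  Outputs are
    y* = y0 + S+ in both modes.
    """

    x_target: np.ndarray
    y_target: np.ndarray
    mode: str
    warnings: tuple[str, ...] = ()


def projection_targets(
    x0, y0, theta: float, input_slacks, output_slacks, mode: str = "standard"
) -> ProjectionTarget:
    """Compute input/output targets from a solved envelopment program."""
    if mode not in ("standard", "literal", "paper_literal"):  # legacy alias accepted
        raise InvalidInputError(f"unknown projection mode {mode!r}")
    x0 = np.asarray(x0, float)
    y0 = np.asarray(y0, float)
    s_minus = np.asarray(input_slacks, float)
    s_plus = np.asarray(output_slacks, float)
    if mode == "standard":
        x_t = theta * x0 - s_minus
    else:
        x_t = x0 - s_minus
    y_t = y0 + s_plus
    warns = tuple(
        f"negative input target at component {i}: {v:.6g} (mode/data mismatch?)"
        for i, v in enumerate(x_t)
        if v < 0
    )
    return ProjectionTarget(x_target=x_t, y_target=y_t, mode=mode, warnings=warns)


def efficiency_decomposition(theta_ccr: float, theta_bcc: float, tol: float = 1e-6) -> float:
    """Scale efficiency SE = OE / TE, reported to 3 decimals (half-up)."""
    if theta_bcc <= 0:
        raise InvalidInputError("technical efficiency must be positive")
    if not (0 < theta_ccr <= theta_bcc + max(tol, 5e-4)):
        raise InvalidInputError(
            f"need 0 < OE <= TE (within tolerance), got OE={theta_ccr}, TE={theta_bcc}"
        )
    return round_half_up(theta_ccr / theta_bcc, 3)


def classify_rts(
    lambda_sum: float,
    theta_ccr: float | None = None,
    theta_bcc: float | None = None,
    tol: float = _EFF_TOL,
    lambda_sum_range: tuple[float, float] | None = None,
) -> str:
    """Returns-to-scale label from the CCR intensity-weight sum.

    constant (``crs``) when sum(lambda*) = 1 within tolerance — or when
    the DMU is efficient under both models; increasing (``irs``) when the
    sum falls below 1, decreasing (``drs``) above.  When the bracket of
    sum(lambda) over alternative optima is supplied, ``crs`` is returned
    whenever 1 lies inside it.
    """
    if lambda_sum < 0:
        raise InvalidInputError("lambda_sum must be nonnegative")
    if (
        theta_ccr is not None
        and theta_bcc is not None
        and abs(theta_ccr - 1) <= tol
        and abs(theta_bcc - 1) <= tol
    ):
        return "crs"
    if lambda_sum_range is not None:
        lo, hi = lambda_sum_range
        if lo - tol <= 1.0 <= hi + tol:
            return "crs"
        return "irs" if hi < 1.0 else "drs"
    if abs(lambda_sum - 1.0) <= tol:
        return "crs"
    return "irs" if lambda_sum < 1.0 else "drs"


def classify_efficiency(
    oe: float,
    te: float,
    se: float,
    slacks=None,
    tol: float = 2e-3,
) -> str:
    """Efficiency-pattern label from the OE = TE x SE decomposition.

    ``efficient`` (all three equal 1 with zero slacks),
    ``scale_inefficient`` (TE = 1, SE < 1),
    ``tech_and_scale_inefficient`` (TE < 1, SE < 1) or
    ``tech_inefficient`` (TE < 1, SE = 1).  The triple must satisfy
    SE x TE = OE within ``tol`` (printed 3-dp values round-trip within
    about 0.001).
    """
    if abs(se * te - oe) > tol:
        raise ConsistencyError(
            f"inconsistent decomposition: SE*TE = {se * te:.6f} vs OE = {oe:.6f}"
        )
    slack_arr = np.asarray([] if slacks is None else slacks, dtype=float).ravel()
    zero_slack = bool(np.all(np.abs(slack_arr) <= tol)) if slack_arr.size else True
    one = lambda v: abs(v - 1.0) <= tol  # noqa: E731
    if one(oe) and one(te) and one(se) and zero_slack:
        return "efficient"
    if one(te) and se < 1.0:
        return "scale_inefficient"
    if te < 1.0 and se < 1.0:
        return "tech_and_scale_inefficient"
    if te < 1.0:
        return "tech_inefficient"
    # theta = 1 but nonzero slack: weakly efficient, scale pattern intact
    return "scale_inefficient" if se < 1.0 else "efficient" if zero_slack else "scale_inefficient"


@dataclass
class DEAResult:
    """Combined CCR + BCC results for a panel, Table-style."""

    table: pd.DataFrame = field(repr=False)
    ccr: DEAEfficiency | None = None
    bcc: DEAEfficiency | None = None
    input_slacks: pd.DataFrame | None = field(default=None, repr=False)
    output_slacks: pd.DataFrame | None = field(default=None, repr=False)


def evaluate_panel(
    panel: DMUPanel,
    tol: float = _EFF_TOL,
    slack_mode: str = "two_phase",
) -> DEAResult:
    """Run CCR and BCC on a panel and assemble the per-DMU results table.

    Columns: OE (CCR theta), TE (BCC theta), SE = OE/TE, returns-to-scale
    label, total input slack S- and total output slack S+ (from the CCR
    phase-2 optimum, the model whose slacks quantify the distance to the
    constant-returns frontier), and the efficiency classification.
    """
    ccr = DEAEfficiency(model="ccr", slack_mode=slack_mode, tol=tol).fit(panel)
    bcc = DEAEfficiency(model="bcc", slack_mode=slack_mode, tol=tol).fit(panel)
    rows = []
    for j, dmu in enumerate(panel.dmu_ids):
        oe = float(ccr.efficiency_[j])
        te = float(bcc.efficiency_[j])
        oe_r = round_half_up(oe, 3)
        te_r = round_half_up(te, 3)
        se_r = efficiency_decomposition(oe, te)
        slacks = np.concatenate([ccr.input_slacks_[j], ccr.output_slacks_[j]])
        scale = max(panel.X.max(), panel.Y.max())
        rel_slacks = slacks / scale
        label = classify_efficiency(
            1.0 if abs(oe - 1) <= tol else oe,
            1.0 if abs(te - 1) <= tol else te,
            1.0 if abs(oe / te - 1) <= tol else oe / te,
            rel_slacks,
            tol=max(2e-3, 10 * tol),
        )
        rows.append(
            {
                "dmu": dmu,
                "oe": oe_r,
                "te": te_r,
                "se": se_r,
                "rts": classify_rts(
                    ccr.lambda_sum_[j],
                    theta_ccr=oe,
                    theta_bcc=te,
                    tol=tol,
                    lambda_sum_range=tuple(ccr.lambda_sum_range_[j]),
                ),
                "s_minus": round_half_up(float(ccr.input_slacks_[j].sum()), 3),
                "s_plus": round_half_up(float(ccr.output_slacks_[j].sum()), 3),
                "classification": label,
            }
        )
    table = pd.DataFrame(rows).set_index("dmu")
    in_sl = pd.DataFrame(ccr.input_slacks_, index=panel.dmu_ids, columns=panel.input_names)
    out_sl = pd.DataFrame(ccr.output_slacks_, index=panel.dmu_ids, columns=panel.output_names)
    return DEAResult(table=table, ccr=ccr, bcc=bcc, input_slacks=in_sl, output_slacks=out_sl)


def summarize_results(table: pd.DataFrame) -> dict:
    """Column means and classification/RTS counts for a results table.

    Expects columns ``oe``, ``te``, ``se``, ``classification`` and
    optionally ``rts``; means are reported to 3 decimals.
    """
    if table is None or len(table) == 0:
        raise InvalidInputError("results table is empty")
    out = {
        "n_dmu": int(len(table)),
        "mean_oe": round_half_up(float(table["oe"].mean()), 3),
        "mean_te": round_half_up(float(table["te"].mean()), 3),
        "mean_se": round_half_up(float(table["se"].mean()), 3),
        "n_efficient": int((table["classification"] == "efficient").sum()),
        "n_inefficient": int((table["classification"] != "efficient").sum()),
        "n_scale_inefficient": int((table["classification"] == "scale_inefficient").sum()),
        "n_tech_and_scale_inefficient": int(
            (table["classification"] == "tech_and_scale_inefficient").sum()
        ),
    }
    if "rts" in table.columns:
        for label in ("crs", "irs", "drs"):
            out[f"n_{label}"] = int((table["rts"] == label).sum())
    return out
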