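"""Seeded synthetic-data generators for every pipeline stage.

Three generators mirror the three kinds of study data:

* expert rating matrices with a tunable degree of consensus, for the
  Delphi statistics;
* input/output panels built from a known efficient frontier with planted
  radial inefficiency factors, for the DEA solver (the planted factor is
  the true input-oriented efficiency, enabling exact recovery tests);
* positive indicator tables with a prescribed correlation structure
  (Gaussian copula), for the correlation-based selection stage.

All randomness flows through an explicit integer seed; identical
specifications produce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea import DMUPanel
from .delphi import ItemMeta, RatingMatrix
from .exceptions import InvalidInputError

__all__ = [
    "RatingSimSpec",
    "PanelSimSpec",
    "generate_rating_matrix",
    "generate_dmu_panel",
    "generate_correlated_indicators",
]


@dataclass(frozen=True)
class RatingSimSpec:
    """Specification for a synthetic Likert rating matrix.

    ``consensus_strength`` in [0, 1] interpolates between independent
    raters (0: each expert scores from a private latent value, Kendall's
    W near 1/m) and perfect agreement (1: all experts identical, W = 1).
    ``full_score_bias`` is the probability that any given cell is forced
    to the maximum score of 5, mimicking ceiling effects in importance
    ratings.
    """

    n_experts: int
    n_items: int
    consensus_strength: float = 0.8
    full_score_bias: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_experts < 2:
            raise InvalidInputError(f"n_experts must be >= 2, got {self.n_experts}")
        if self.n_items < 3:
            raise InvalidInputError(f"n_items must be >= 3, got {self.n_items}")
        if not 0.0 <= self.consensus_strength <= 1.0:
            raise InvalidInputError("consensus_strength must be in [0, 1]")
        if not 0.0 <= self.full_score_bias <= 1.0:
            raise InvalidInputError("full_score_bias must be in [0, 1]")


@dataclass(frozen=True)
class PanelSimSpec:
    """Specification for a synthetic DMU panel with planted inefficiency.

    Frontier DMUs are placed on a Cobb-Douglas technology (constant
    returns for ``frontier_kind="crs"``; exponent 0.8 for ``"vrs"``) with
    distinct input mixes and proportional output mixes, which makes every
    frontier point an extreme point of the DEA hull.  A DMU with
    inefficiency factor ``c`` < 1 is a radially inflated copy of one of
    the panel's frontier DMUs (inputs divided by ``c``, outputs kept), so
    its radial projection lands on a point that is itself in the
    reference set and its true input-oriented efficiency is exactly
    ``c`` — under CCR for a CRS frontier, under BCC for VRS.  At least
    one factor must equal 1 to anchor the frontier.  ``noise_sd`` adds
    multiplicative lognormal noise to the inputs (default 0 = exact
    frontier geometry).
    """

    n_dmu: int
    n_inputs: int = 3
    n_outputs: int = 2
    frontier_kind: str = "crs"
    inefficiency_factors: tuple | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_dmu < 2 or self.n_inputs < 1 or self.n_outputs < 1:
            raise InvalidInputError("need n_dmu >= 2 and at least one input and output")
        if self.frontier_kind not in ("crs", "vrs"):
            raise InvalidInputError(f"frontier_kind must be 'crs' or 'vrs', got {self.frontier_kind!r}")
        if self.inefficiency_factors is not None:
            if len(self.inefficiency_factors) != self.n_dmu:
                raise InvalidInputError("need one inefficiency factor per DMU")
            for c in self.inefficiency_factors:
                if not 0.0 < c <= 1.0:
                    raise InvalidInputError(f"inefficiency factor {c} outside (0, 1]")
            if all(c < 1.0 for c in self.inefficiency_factors):
                raise InvalidInputError(
                    "at least one DMU must have factor 1 to anchor the frontier"
                )
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def generate_rating_matrix(spec: RatingSimSpec) -> RatingMatrix:
    """Draw a synthetic experts x items Likert matrix.

    Each item has a common latent importance mu_i ~ U(1, 5); expert e
    perceives ``c * mu_i + (1 - c) * eps_ei`` with private eps_ei ~
    U(1, 5) and c = consensus_strength, rounded and clipped to 1..5.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mu = rng.uniform(1.0, 5.0, size=spec.n_items)
    eps = rng.uniform(1.0, 5.0, size=(spec.n_experts, spec.n_items))
    latent = spec.consensus_strength * mu + (1.0 - spec.consensus_strength) * eps
    scores = np.clip(np.rint(latent), 1, 5).astype(int)
    if spec.full_score_bias > 0:
        force = rng.random(scores.shape) < spec.full_score_bias
        scores[force] = 5
    items = [ItemMeta(id=f"{j + 1}", label=f"synthetic item {j + 1}", level=1, spo="S") for j in range(spec.n_items)]
    return RatingMatrix(items=items, scores=scores, round_id=1)


def generate_dmu_panel(spec: PanelSimSpec) -> tuple[DMUPanel, np.ndarray]:
    """Build a panel on a known frontier and return it with the true thetas.

    Returns
    -------
    (panel, true_theta)
        ``true_theta[j]`` is the planted input-oriented efficiency of DMU
        j under the matching returns-to-scale assumption (CCR for a CRS
        frontier, BCC for VRS) when ``noise_sd`` is 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m, s = spec.n_dmu, spec.n_inputs, spec.n_outputs

    # Cobb-Douglas technology: aggregate input g(x) = prod x_i^w_i, sum w = 1
    w = rng.dirichlet(np.ones(m) * 5.0)
    a = rng.uniform(0.5, 2.0, size=s)  # fixed output mix across DMUs

    X = rng.uniform(1.0, 10.0, size=(n, m))
    g = np.prod(X**w, axis=1)
    scale = g if spec.frontier_kind == "crs" else g**0.8
    Y = np.outer(scale, a)

    factors = (
        np.ones(n)
        if spec.inefficiency_factors is None
        else np.asarray(spec.inefficiency_factors, dtype=float)
    )
    # Inefficient DMUs replicate a frontier anchor radially so their
    # projection point stays inside the reference set (exact planted theta).
    anchors = np.flatnonzero(factors >= 1.0)
    for j in np.flatnonzero(factors < 1.0):
        k = int(rng.choice(anchors))
        X[j] = X[k] / factors[j]
        Y[j] = Y[k]
    if spec.noise_sd > 0:
        X = X * np.exp(rng.normal(0.0, spec.noise_sd, size=X.shape))

    panel = DMUPanel(dmu_ids=[f"DMU{j + 1}" for j in range(n)], X=X, Y=Y)
    return panel, factors.copy()


def generate_correlated_indicators(
    n_dmu: int,
    target_corr: np.ndarray,
    seed: int = 0,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Positive indicator table with approximately the given correlations.

    A Gaussian copula draw Z ~ N(0, target_corr) is mapped to positive
    values via ``100 * exp(0.25 Z)``; the monotone map attenuates Pearson
    r only slightly, keeping the empirical correlations within about
    0.15 of the target for n_dmu >= 50.
    """
    if n_dmu < 3:
        raise InvalidInputError(f"need n_dmu >= 3, got {n_dmu}")
    C = np.asarray(target_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T):
        raise InvalidInputError("target_corr must be a symmetric square matrix")
    eigs = np.linalg.eigvalsh(C)
    if eigs.min() < -1e-8:
        raise InvalidInputError(f"target_corr is not positive semi-definite (min eig {eigs.min():.3g})")
    k = C.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(k))
    Z = rng.standard_normal((n_dmu, k)) @ L.T
    values = 100.0 * np.exp(0.25 * Z)
    cols = names if names is not None else [f"ind_{j + 1}" for j in range(k)]
    return pd.DataFrame(values, columns=cols, index=[f"DMU{i + 1}" for i in range(n_dmu)])
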