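# Methods

## Delphi consensus statistics

A consultation round is an experts × items matrix of Likert scores in
1–5; experts who did not return the round are excluded as whole rows
(no imputation; partially answered rows are rejected as schema errors).

* **Enthusiasm** — response rate 100·returned/sent, reported to 1 dp.
* **Authority** — judgment basis Ca sums the pre-assigned source weights
  (practical experience 0.5/0.4/0.3 for high/medium/low, theoretical
  analysis 0.3/0.2/0.1, literature 0.1, intuition 0.1; range 0.6–1.0);
  familiarity Cs maps the five verbal levels onto 1.0/0.8/0.6/0.4/0.2;
  Cr = (Ca + Cs)/2. When a whole round is summarized by one Cr, the
  panel-mean Ca and Cs are combined.
* **Consensus** — per-item CV = sample SD (n−1 denominator) / mean, and
  Kendall's W over within-expert ranks (average ranks at ties):
  W = 12·S / (m²(n³−n) − m·ΣTⱼ) with S the variance of column rank sums
  and Tⱼ = Σ(t³−t) over expert j's tie groups. Tie correction is the
  default because Likert data is heavily tied and identical raters should
  score W = 1; the uncorrected mode exists because only there does the
  χ² = m(n−1)W identity hold exactly against the rank-variance
  definition. A matrix in which every expert rates all items identically
  has a zero corrected denominator and raises a degeneracy error.
  Significance uses the χ² upper tail on n−1 df.
* **Item screening** — an item is retained iff mean ≥ `mean_min` (default
  3.5), CV < `cv_max` (0.25) and full-score rate > `fsr_min` (0.70); any
  threshold can be disabled or tightened (a stricter preset with
  mean ≥ 4.0 is provided, since both conventions appear in screening
  protocols). Failure reasons are recorded per item, and screening is
  monotone: relaxing a threshold never removes a retained item.

Reported precision follows the field's tables — 2 dp for coefficients,
3 dp elsewhere — rounded half-up via decimal arithmetic (binary-float
`round` would turn 0.895 into 0.89). Full precision is kept internally.

## Indicator screening for DEA

Discriminatory power requires few indicators relative to DMUs. Two rules
gate feasibility: inputs + outputs ≤ n_dmu/2, and inputs·outputs ≤ n_dmu;
the weaker convention n_dmu ≥ 2·(inputs + outputs) is reported separately
but not enforced. The correlation stage computes pairwise Pearson r with
two-tailed p from the t-distribution on n−2 df (zero-variance columns are
flagged and excluded), eliminates indicators with no cross-role pair
satisfying |r| > `r_min` (0.7) at significance `alpha` (0.05 or 0.01),
ranks survivors by their maximum significant cross-role |r| — a
per-indicator statistic chosen because the selection outcome is a set of
indicators, not of pairs — and keeps the top `cap` (default ⌊n_dmu/2⌋),
shrinking until the feasibility rules pass. Ties break on indicator id;
every decision is appended to a trace. Both roles are always represented:
if the capped prefix is single-role, the strongest indicator of the
missing role replaces the weakest selected one (traced). The second-stage
expert-panel refinement between threshold screening and correlation
screening is human judgment and is represented only as user-supplied
include/exclude lists, never computed.

## DEA core

Input-oriented envelopment, CCR (constant returns) and BCC (variable
returns, Σλ = 1):

    min θ    s.t.  Xᵀλ + S⁻ = θx₀,   Yᵀλ − S⁺ = y₀,   λ, S⁻, S⁺ ≥ 0.

The non-Archimedean ε that keeps slacks in the objective is realized as
the standard two-phase procedure — phase 1 minimizes θ, phase 2 fixes θ*
and maximizes eᵀS⁻ + eᵀS⁺ — which is robust and equivalent in the ε→0
limit; a literal finite-ε single LP is provided for comparison
(`slack_mode="epsilon"`). LPs are solved with HiGHS via
`scipy.optimize.linprog`.

* **Decomposition** — OE = CCR θ, TE = BCC θ, SE = OE/TE; OE ≤ TE always
  (the BCC feasible set is smaller). SE·TE = OE exactly at full
  precision; on 3-dp printed values the identity holds within ~0.001, so
  the classification consistency check uses a 0.002 default tolerance.
* **Returns to scale** — from Σλ* at the CCR optimum: <1 increasing, >1
  decreasing, =1 constant (tolerance 1e−6). Because λ* need not be
  unique, two auxiliary LPs bracket Σλ over the optimal face and a DMU is
  labeled constant-returns whenever 1 lies in the bracket.
* **Classification** — efficient (OE = TE = SE = 1, zero slacks),
  scale-inefficient (TE = 1, SE < 1), tech-and-scale-inefficient
  (TE < 1, SE < 1), plus tech-inefficient (TE < 1, SE = 1), a pattern
  synthetic constant-returns data produces even though three-way
  taxonomies omit it. Radially efficient units with nonzero slack are
  weakly efficient and grouped with the scale-inefficient pattern.
* **Projection** — standard targets x* = θx₀ − S⁻, y* = y₀ + S⁺. A
  literal mode x* = x₀ − S⁻ is exposed as well, because published slack
  tables are sometimes read that way; it is an explicit alternative, not
  a silent correction, and negative targets are flagged.
* **Tolerances** — efficiency equality |θ−1| ≤ 1e−6; slack-zero tests are
  relative to the data scale. Zeros and negatives are rejected at
  ingestion (DEA requires positive data); no automatic substitution.

An independent brute-force oracle (`caredea._vertex`) enumerates every
basic solution of the equality system and takes the minimal feasible θ.
It shares no algorithmic machinery with the LP path and is used in tests
and the acceptance script on panels of ≤ 5 DMUs, where enumeration is
cheap.

## Synthetic generators

All generators take mandatory seeds (numpy `default_rng`; no global
state) and are bit-reproducible.

* **Ratings** — item latent importances μᵢ ~ U(1,5); expert e sees
  c·μᵢ + (1−c)·εₑᵢ with private εₑᵢ ~ U(1,5) and c the consensus
  strength, rounded and clipped to 1..5. c = 1 gives identical experts
  (W = 1); c = 0 gives independent experts (W ≈ 1/m); expected W is
  monotone in c. `full_score_bias` forces cells to 5 with the given
  probability, mimicking ceiling effects.
* **Panels** — frontier DMUs on a Cobb-Douglas technology: inputs
  X ~ U(1,10)ᵐ, aggregate g(x) = Πxᵢ^wᵢ with Dirichlet weights, outputs
  proportional to g (constant returns) or g^0.8 (variable returns).
  Distinct input mixes on a strictly concave isoquant make every frontier
  point an extreme point of the DEA hull. An inefficient DMU with factor
  c < 1 is a radially inflated copy of a frontier DMU that remains in the
  panel (inputs divided by c, outputs kept), so its projection point is
  in the reference set and its true radial efficiency is exactly c — the
  construction that makes machine-precision recovery tests possible. At
  least one unit factor is required as an anchor. Optional multiplicative
  lognormal input noise (default off) breaks the exactness deliberately.
  What this generator does **not** emulate: realistic magnitudes of
  admissions or care-hours, correlated inefficiency across units, or
  measurement error structure — so passing recovery tests demonstrates
  solver correctness on known geometry, not robustness to real survey
  data.
* **Indicator tables** — Gaussian copula: Z ~ N(0, target correlation)
  mapped through 100·exp(0.25·Z) to positive values; the monotone map
  attenuates Pearson r slightly (empirical r within ~0.15 of target for
  n ≥ 50). Non-PSD targets are rejected.

## Problem sizes

The test suite and acceptance script use panels of 3–10 DMUs with ≤ 3
inputs and ≤ 2–3 outputs, 100 panels per property — comfortably past the
regime where enumeration oracles are exact, and representative of the
12-institution, 3-input/2-output shape the screening rules produce. The
full suite runs in well under a minute on one core.

## Known limitations

* Output orientation, super-efficiency, Malmquist indices and
  second-stage regressions are out of scope.
* The published per-DMU efficiencies cannot be recomputed because the
  underlying institution data were never released; they are used as
  fixtures for the decomposition/classification/reporting paths only.
  (The published slack tables are internally inconsistent for two DMUs
  and omit a third; the fixtures transcribe them verbatim.)
* The correlation stage is pairwise Pearson only — no multivariate
  collinearity diagnostics.
* DEA efficiency is relative to the observed panel: adding a dominated
  DMU changes nothing (tested), but adding a dominating one rescales
  every score.
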