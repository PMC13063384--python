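# caredea

Delphi expert-consultation statistics and input-oriented CCR/BCC data
envelopment analysis (DEA), built for health-services efficiency studies —
the motivating application is benchmarking nursing human-resource
configuration across integrated medical and elderly-care institutions, but
every component is generic over raters, indicators and decision-making
units (DMUs).

The package implements the full indicator-to-efficiency workflow:

1. **Delphi consensus** (`caredea.delphi`) — response rate (enthusiasm),
   expert authority Cr = (Ca + Cs)/2 from the judgment-basis weight table
   and the five-level familiarity scale, per-item mean/SD/CV/full-score
   rate, Kendall's coefficient of concordance *W* (tie-corrected or not)
   with its χ² = m(n−1)W test, and threshold-based item screening
   (mean ≥ 3.5, CV < 0.25, full-score rate > 70%, all configurable).
2. **Indicator screening for DEA** (`caredea.screening`) — the
   dimensionality rules of thumb (inputs + outputs ≤ half the DMUs;
   inputs × outputs ≤ DMUs) and correlation-based selection: rank
   surviving indicators by their strongest significant cross-role Pearson
   correlation and keep the top *k*.
3. **DEA core** (`caredea.dea`) — the input-oriented envelopment programs

   ```
   min  θ − ε(eᵀS⁻ + eᵀS⁺)
   s.t. Σⱼ Xⱼλⱼ + S⁻ = θx₀,   Σⱼ Yⱼλⱼ − S⁺ = y₀,   λ, S⁻, S⁺ ≥ 0
   ```

   with Σλⱼ = 1 added for the BCC (variable-returns) model, solved by the
   standard two-phase procedure (radial θ first, then slack maximization).
   Overall efficiency OE (CCR), technical efficiency TE (BCC), scale
   efficiency SE = OE/TE, returns-to-scale labels from the CCR intensity
   weights, slack-based projection targets, and peer benchmarking.
4. **Synthetic data** (`caredea.simulate`) — seeded generators for rating
   matrices with tunable consensus, frontier panels with *exactly* planted
   radial efficiencies, and correlated indicator tables (Gaussian copula).
5. **I/O and orchestration** (`caredea.io`, `caredea.cli`) — CSV/JSON
   readers and report writers in the published table layouts, plus a
   `caredea` command-line umbrella (`delphi-stats`, `screen-indicators`,
   `dea-run`, `simulate`, `run`) with a hashed artifact manifest.

The main entry points are sklearn-style estimators — `DEAEfficiency`,
`DelphiScreener`, `CorrelationSelector` — with plain functions
(`solve_envelopment`, `kendalls_w`, `rule_of_thumb`, …) as thin wrappers.

## Worked example

Twelve synthetic institutions on a variable-returns frontier, five of them
with planted radial inefficiency (factors 0.85, 0.9, 0.7, 0.95 and one
slightly off-scale anchor), three inputs and two outputs:

```python
from caredea import evaluate_panel
from caredea.simulate import PanelSimSpec, generate_dmu_panel
from caredea.io import peer_summary_text

panel, truth = generate_dmu_panel(
    PanelSimSpec(n_dmu=12, n_inputs=3, n_outputs=2, frontier_kind="vrs",
                 inefficiency_factors=(1,1,0.85,1,0.9,1,1,0.7,1,1,0.95,1),
                 seed=42))
result = evaluate_panel(panel)
print(result.table)
print(peer_summary_text(result))
```

```
          oe    te     se  rts  s_minus  s_plus              classification
dmu
DMU1   0.972  1.00  0.972  drs    0.000     0.0           scale_inefficient
DMU2   0.982  1.00  0.982  drs    1.255     0.0           scale_inefficient
DMU3   0.850  0.85  1.000  crs    0.000     0.0            tech_inefficient
DMU4   0.944  1.00  0.944  drs    0.000     0.0           scale_inefficient
DMU5   0.900  0.90  1.000  crs    0.000     0.0            tech_inefficient
DMU6   1.000  1.00  1.000  crs    0.000     0.0                   efficient
DMU7   1.000  1.00  1.000  crs    0.000     0.0                   efficient
DMU8   0.689  0.70  0.985  drs    0.000     0.0  tech_and_scale_inefficient
DMU9   1.000  1.00  1.000  crs    0.000     0.0                   efficient
DMU10  1.000  1.00  1.000  crs    0.000     0.0                   efficient
DMU11  0.897  0.95  0.944  drs    0.000     0.0  tech_and_scale_inefficient
DMU12  0.985  1.00  0.985  drs    0.000     0.0           scale_inefficient

12 DMUs: 4 efficient, 8 inefficient (mean OE 0.935, TE 0.950, SE 0.984)
  DMU1: benchmark peers DMU6 (λ=0.827), DMU7 (λ=0.634), DMU10 (λ=0.080)
  DMU2: benchmark peers DMU6 (λ=0.338), DMU9 (λ=1.161)
  ...
```

Reading the table: `oe` is the CCR radial score (how far all inputs could
be contracted proportionally under constant returns), `te` the BCC score
(same, against the variable-returns frontier — note DMU8 recovers its
planted factor 0.70 exactly), `se = oe/te` isolates the scale component,
`rts` labels returns to scale from the CCR intensity-weight sum, and the
slack columns give the residual non-radial input excess / output
shortfall. The peer list names the efficient units each inefficient
institution should emulate, with their intensity weights λ.

## Data notes

The raw institution-level inputs and outputs behind the published
efficiency table were never deposited, so those per-DMU efficiencies and
slacks ship as worked-example fixtures (`caredea.datasets`) exercising the
decomposition, classification and reporting paths; fresh DEA runs use
user-supplied panels or the synthetic generators. See `docs/methods.md`
for the model details and design choices.
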