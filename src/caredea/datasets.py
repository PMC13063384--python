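"""Packaged fixtures transcribed from the study's printed tables.

The raw institution-level input/output data behind the efficiency results
were never deposited, so the printed per-DMU efficiencies and slacks act
as worked-example fixtures for the decomposition, classification and
reporting operations — not as recomputable ground truth.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("caredea") / "data"

#: Round-level Delphi bookkeeping: questionnaires sent/returned and the
#: panel-mean judgment-basis (Ca) and familiarity (Cs) coefficients.
DELPHI_ROUNDS: dict[int, dict[str, float]] = {
    1: {"n_sent": 17, "n_returned": 17, "ca": 0.94, "cs": 0.85},
    2: {"n_sent": 17, "n_returned": 16, "ca": 0.98, "cs": 0.86},
}


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, **kw)


def load_consensus_rounds() -> pd.DataFrame:
    """Per-round Kendall's W, df, mean CV, chi-square and p label."""
    return _read("consensus_rounds.csv")


def load_indicator_system() -> pd.DataFrame:
    """The 68-item hierarchical indicator system with S-P-O tags.

    Columns: hierarchical ``code`` (depth = level), ``label``, ``spo``
    (Structure/Process/Outcome), round-2 ``mean``, ``sd``, ``cv`` and
    ``full_score_rate`` (percent).  A ``level`` column is derived from
    the code depth.
    """
    df = _read("indicator_system.csv", dtype={"code": str})
    df["level"] = df["code"].str.split(".").str.len()
    return df


def load_efficiency_results() -> pd.DataFrame:
    """Printed per-DMU OE/TE/SE, RTS labels, total slacks and labels."""
    return _read("efficiency_results.csv", dtype={"dmu": str})


def load_slack_detail() -> pd.DataFrame:
    """Printed per-indicator slacks for the DMUs itemized as inefficient."""
    return _read("slack_detail.csv", dtype={"dmu": str})
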