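"""Readers, writers, report rendering and pipeline orchestration.

All tables are UTF-8 comma-separated files with a mandatory header row
and dot decimals.  Efficiencies and slacks are rendered to 3 decimals,
coefficients to 2, rounding half-up; everything is computed at full
precision internally, so write-then-read round-trips preserve values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .dea import DEAResult, DMUPanel, evaluate_panel, summarize_results
from .delphi import (
    DelphiScreener,
    ExpertAuthority,
    ItemMeta,
    RatingMatrix,
    authority_coefficient,
    kendalls_w,
)
from .exceptions import InvalidInputError, SchemaError
from .screening import CorrelationSelector, rule_of_thumb
from .simulate import (
    PanelSimSpec,
    RatingSimSpec,
    generate_correlated_indicators,
    generate_dmu_panel,
    generate_rating_matrix,
)

__all__ = [
    "read_ratings_csv",
    "read_authority_csv",
    "read_panel_csv",
    "read_indicator_table",
    "write_item_stats_csv",
    "write_concordance_json",
    "render_efficiency_report",
    "render_slack_report",
    "peer_summary_text",
    "PipelineConfig",
    "run_pipeline",
]

_RTS_DISPLAY = {"crs": "—", "irs": "irs", "drs": "drs"}
_CLASS_DISPLAY = {
    "efficient": "Efficient",
    "scale_inefficient": "Inefficient",
    "tech_and_scale_inefficient": "Inefficient",
    "tech_inefficient": "Inefficient",
}


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_ratings_csv(path, items_csv=None, round_id: int = 1) -> RatingMatrix:
    """Read an experts x items rating table (header row = item codes).

    Rows that are entirely empty (an expert who did not respond) are
    dropped; partially answered rows are rejected — the whole-row
    exclusion policy, no imputation.  ``items_csv`` may supply item
    metadata (columns code, label, spo); otherwise structure tags default
    to "S" and levels derive from the code depth.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"{path}: cannot parse ({exc})") from exc
    if df.empty or df.shape[1] == 0:
        raise SchemaError(f"{path}: no rating data")
    if df.columns[0].lower() in ("expert", "expert_id", "id"):
        df = df.set_index(df.columns[0])
    all_na = df.isna().all(axis=1)
    df = df.loc[~all_na]
    partial = df.isna().any(axis=1)
    if partial.any():
        row = df.index[partial][0]
        col = df.columns[df.loc[row].isna()][0]
        raise SchemaError(f"{path}: partial response at row {row!r}, column {col!r}")

    meta: dict[str, tuple[str, str]] = {}
    if items_csv is not None:
        items_df = pd.read_csv(items_csv, dtype=str)
        _require_columns(items_df, ["code", "label", "spo"], items_csv)
        meta = {r.code: (r.label, r.spo) for r in items_df.itertuples()}
    items = []
    for code in df.columns:
        label, spo = meta.get(str(code), (str(code), "S"))
        items.append(ItemMeta(id=str(code), label=label, level=len(str(code).split(".")), spo=spo))
    return RatingMatrix(items=items, scores=df.to_numpy(), round_id=round_id)


def read_authority_csv(path) -> list[ExpertAuthority]:
    """Read per-expert authority self-assessments.

    Expected columns: expert id, ``practical_experience``,
    ``theoretical_analysis``, ``literature``, ``intuition`` (levels
    high/medium/low) and ``familiarity``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sources = ["practical_experience", "theoretical_analysis", "literature", "intuition"]
    _require_columns(df, sources + ["familiarity"], path)
    return [
        ExpertAuthority(
            judgment_levels={s: str(row[s]) for s in sources},
            familiarity=str(row["familiarity"]),
        )
        for _, row in df.iterrows()
    ]


def _roles_from_sidecar(roles_path) -> dict:
    with open(roles_path) as fh:
        roles = json.load(fh)
    if not isinstance(roles, dict):
        raise SchemaError(f"{roles_path}: roles JSON must map indicator -> input/output")
    return {str(k): str(v) for k, v in roles.items()}


def read_panel_csv(path, roles_path=None) -> DMUPanel:
    """Read a DMU panel (one row per institution, positive values only).

    Column roles come from a sidecar JSON (indicator -> "input"/"output")
    or from ``input_*`` / ``output_*`` column-name prefixes.  The first
    column is treated as the DMU id when non-numeric.  Nonpositive or
    non-numeric cells are rejected with the offending row and column
    named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty panel file")
    first = df.columns[0]
    if df[first].dtype == object or first.lower() in ("dmu", "dmu_id", "id"):
        df = df.set_index(first)
    if roles_path is not None:
        roles = _roles_from_sidecar(roles_path)
    else:
        roles = {}
        for c in df.columns:
            if str(c).startswith("input"):
                roles[c] = "input"
            elif str(c).startswith("output"):
                roles[c] = "output"
            else:
                raise SchemaError(
                    f"{path}: column {c!r} has no role; use input_*/output_* names or a roles JSON"
                )
    for c in df.columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() | (col <= 0)
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(
                f"{path}: nonpositive or non-numeric value at row {row!r}, column {c!r}"
            )
        df[c] = col
    return DMUPanel.from_frame(df, roles)


def read_indicator_table(path, roles_path) -> tuple[pd.DataFrame, dict]:
    """Read a candidate-indicator table plus its sidecar role map."""
    df = pd.read_csv(path)
    first = df.columns[0]
    if df[first].dtype == object or first.lower() in ("dmu", "dmu_id", "id"):
        df = df.set_index(first)
    roles = _roles_from_sidecar(roles_path)
    missing = [c for c in df.columns if c not in roles]
    if missing:
        raise SchemaError(f"{path}: no role for columns {missing}")
    return df, roles


def write_item_stats_csv(item_stats: pd.DataFrame, path) -> Path:
    """Write per-item statistics in the printed-table layout.

    Columns: importance mean +/- SD (2 dp), CV (2 dp) and full-score
    rate in percent (1 dp), plus the retention flag and reasons.
    """
    out = pd.DataFrame(index=item_stats.index)
    out["importance_score"] = [
        f"{round_half_up(m, 2):.2f} ± {round_half_up(s, 2):.2f}"
        for m, s in zip(item_stats["mean"], item_stats["sd"])
    ]
    out["cv"] = [f"{round_half_up(v, 2):.2f}" for v in item_stats["cv"]]
    out["full_score_rate_pct"] = [
        f"{round_half_up(100 * v, 1):.1f}" for v in item_stats["full_score_rate"]
    ]
    if "retained" in item_stats.columns:
        out["retained"] = item_stats["retained"].to_numpy()
        out["reasons"] = item_stats["reasons"].to_numpy()
    path = Path(path)
    out.to_csv(path, index_label="item")
    return path


def write_concordance_json(result, path) -> Path:
    path = Path(path)
    payload = {
        "w": round_half_up(result.w, 3),
        "chi2": round_half_up(result.chi2, 2),
        "df": result.df,
        "p_value": float(result.p_value),
        "tie_corrected": bool(result.tie_corrected),
        "n_experts": result.n_experts,
        "n_items": result.n_items,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def render_efficiency_report(table: pd.DataFrame, path) -> Path:
    """Write the per-DMU efficiency table with an appended Average row.

    Mirrors the published layout: OE/TE/SE to 3 dp, constant returns
    rendered as an em dash, classifications as Efficient/Inefficient.
    """
    if table is None or len(table) == 0:
        raise InvalidInputError("results table is empty")
    disp = pd.DataFrame(index=[str(i) for i in table.index])
    for col, src in (("OE", "oe"), ("TE", "te"), ("SE", "se")):
        disp[col] = [f"{round_half_up(v, 3):.3f}" for v in table[src]]
    disp["Returns to scale"] = [_RTS_DISPLAY.get(v, v) for v in table["rts"]]
    disp["S-"] = [f"{round_half_up(v, 3):.3f}" for v in table["s_minus"]]
    disp["S+"] = [f"{round_half_up(v, 3):.3f}" for v in table["s_plus"]]
    disp["Efficiency"] = [_CLASS_DISPLAY.get(v, v) for v in table["classification"]]
    avg = {
        "OE": f"{round_half_up(float(table['oe'].mean()), 3):.3f}",
        "TE": f"{round_half_up(float(table['te'].mean()), 3):.3f}",
        "SE": f"{round_half_up(float(table['se'].mean()), 3):.3f}",
        "Returns to scale": "",
        "S-": "",
        "S+": "",
        "Efficiency": "",
    }
    disp.loc["Average"] = avg
    path = Path(path)
    disp.to_csv(path, index_label="DMU")
    return path


def render_slack_report(result: DEAResult, path) -> Path:
    """Per-indicator slack table for the inefficient DMUs."""
    ineff = result.table.index[result.table["classification"] != "efficient"]
    rows = result.input_slacks.loc[ineff].add_prefix("s_minus_").join(
        result.output_slacks.loc[ineff].add_prefix("s_plus_")
    )
    rows = rows.map(lambda v: f"{round_half_up(float(v), 3):.3f}")
    path = Path(path)
    rows.to_csv(path, index_label="dmu")
    return path


def peer_summary_text(result: DEAResult, tol: float = 1e-6) -> str:
    """Human-readable summary naming efficient peers per inefficient DMU."""
    lines = []
    summary = summarize_results(result.table)
    lines.append(
        f"{summary['n_dmu']} DMUs: {summary['n_efficient']} efficient, "
        f"{summary['n_inefficient']} inefficient "
        f"(mean OE {summary['mean_oe']:.3f}, TE {summary['mean_te']:.3f}, "
        f"SE {summary['mean_se']:.3f})"
    )
    ids = result.ccr.panel_.dmu_ids
    for j, dmu in enumerate(ids):
        if result.table.iloc[j]["classification"] == "efficient":
            continue
        lam = result.ccr.lambda_[j]
        peers = [f"{ids[k]} (λ={lam[k]:.3f})" for k in np.nonzero(lam > tol)[0] if k != j]
        lines.append(f"  {dmu}: benchmark peers " + (", ".join(peers) if peers else "none"))
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run.

    File inputs take precedence; any stage whose inputs are absent falls
    back to the seeded synthetic generator, so a bare config with only a
    seed still produces a complete, reproducible run.
    """

    out_dir: str
    seed: int = 0
    # delphi stage
    run_delphi: bool = True
    ratings_csv: str | None = None
    authority_csv: str | None = None
    n_experts: int = 17
    n_items: int = 20
    consensus_strength: float = 0.8
    mean_min: float | None = 3.5
    cv_max: float | None = 0.25
    fsr_min: float | None = 0.70
    tie_correction: bool = True
    # screening stage
    run_screening: bool = True
    indicator_csv: str | None = None
    roles_json: str | None = None
    cap: int | None = 5
    r_min: float = 0.7
    alpha: float = 0.05
    # dea stage
    run_dea: bool = True
    panel_csv: str | None = None
    panel_roles_json: str | None = None
    n_dmu: int = 12
    n_inputs: int = 3
    n_outputs: int = 2
    tol: float = 1e-6
    projection_mode: str = "standard"
    artifacts: list = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute Delphi statistics -> indicator screening -> DEA in order.

    Every stage writes its outputs under ``config.out_dir``; the returned
    manifest lists each artifact with its SHA-256 hash next to the
    resolved configuration, so a rerun with the same config and seed is
    byte-identical and verifiable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    if config.run_delphi:
        if config.ratings_csv:
            ratings = read_ratings_csv(config.ratings_csv)
        else:
            ratings = generate_rating_matrix(
                RatingSimSpec(
                    n_experts=config.n_experts,
                    n_items=config.n_items,
                    consensus_strength=config.consensus_strength,
                    seed=config.seed,
                )
            )
        conc = kendalls_w(ratings, tie_correction=config.tie_correction)
        screener = DelphiScreener(config.mean_min, config.cv_max, config.fsr_min).fit(ratings)
        artifacts.append(write_item_stats_csv(screener.item_stats_, out / "item_stats.csv"))
        artifacts.append(write_concordance_json(conc, out / "concordance.json"))
        if config.authority_csv:
            experts = read_authority_csv(config.authority_csv)
            ca = round_half_up(float(np.mean([e.ca for e in experts])), 2)
            cs = round_half_up(float(np.mean([e.cs for e in experts])), 2)
            (out / "authority.json").write_text(
                json.dumps({"ca": ca, "cs": cs, "cr": authority_coefficient(ca, cs)}, indent=2)
                + "\n"
            )
            artifacts.append(out / "authority.json")

    if config.run_screening:
        if config.indicator_csv:
            table, roles = read_indicator_table(config.indicator_csv, config.roles_json)
        else:
            k = config.n_inputs + config.n_outputs + 1
            target = np.full((k, k), 0.85)
            np.fill_diagonal(target, 1.0)
            table = generate_correlated_indicators(
                max(config.n_dmu, 12), target, seed=config.seed + 1
            )
            roles = {
                c: ("input" if i < config.n_inputs + 1 else "output")
                for i, c in enumerate(table.columns)
            }
        sel = CorrelationSelector(cap=config.cap, r_min=config.r_min, alpha=config.alpha)
        sel.fit(table, roles)
        res = sel.result_
        payload = {
            "selected": res.selected,
            "n_inputs": res.n_inputs,
            "n_outputs": res.n_outputs,
            "trace": res.trace,
            "r": res.r.round(6).to_dict(),
            "p": res.p.round(6).to_dict(),
        }
        (out / "selection.json").write_text(json.dumps(payload, indent=2) + "\n")
        artifacts.append(out / "selection.json")
        pairs = res.r.where(np.triu(np.ones(res.r.shape, bool), 1)).stack()
        long = pd.DataFrame(
            {
                "pair": [f"{a}|{b}" for a, b in pairs.index],
                "r": pairs.to_numpy(),
                "p": [res.p.loc[a, b] for a, b in pairs.index],
            }
        )
        long.to_csv(out / "correlation_long.csv", index=False)
        artifacts.append(out / "correlation_long.csv")

    if config.run_dea:
        if config.panel_csv:
            panel = read_panel_csv(config.panel_csv, config.panel_roles_json)
        else:
            rng = np.random.default_rng(config.seed + 2)
            factors = tuple(np.where(rng.random(config.n_dmu) < 0.5, 1.0, rng.uniform(0.6, 1.0, config.n_dmu)))
            panel, _ = generate_dmu_panel(
                PanelSimSpec(
                    n_dmu=config.n_dmu,
                    n_inputs=config.n_inputs,
                    n_outputs=config.n_outputs,
                    inefficiency_factors=factors,
                    seed=config.seed + 2,
                )
            )
        verdict = rule_of_thumb(panel.n_dmu, panel.n_inputs, panel.n_outputs)
        if not verdict.feasible:
            raise InvalidInputError(
                f"panel shape violates the DEA rule of thumb: {panel.n_dmu} DMUs with "
                f"{panel.n_inputs} inputs and {panel.n_outputs} outputs"
            )
        result = evaluate_panel(panel, tol=config.tol)
        artifacts.append(render_efficiency_report(result.table, out / "efficiency.csv"))
        artifacts.append(render_slack_report(result, out / "slack_detail.csv"))
        (out / "peers.txt").write_text(peer_summary_text(result))
        artifacts.append(out / "peers.txt")

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if k != "artifacts"},
        "outputs": [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in artifacts
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
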