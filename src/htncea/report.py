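"""Canonical result files: arm tables, traces, CEAC/tornado/scatter CSVs, manifests.

Monetary values are computed and stored at full precision and rounded to two
decimals only at serialisation (rounding earlier would corrupt ICERs built
from near-cancelling differences).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .economics import CATEGORIES, ArmResult, CEComparison
from .engine import EXPANDED_STATES
from .sensitivity import PSAResult, ScenarioResult, TornadoEntry

__all__ = [
    "comparison_table",
    "write_comparison",
    "write_cohort_trace",
    "tornado_to_frame",
    "write_manifest",
]

_MONEY_DECIMALS = 2
_QALY_DECIMALS = 4


def comparison_table(drug: ArmResult, non_drug: ArmResult) -> pd.DataFrame:
    """Per-arm outcome table with a changes column (drug minus non-drug)."""
    rows = [("discounted_qalys", drug.discounted_qalys, non_drug.discounted_qalys),
            ("discounted_cost", drug.discounted_cost, non_drug.discounted_cost)]
    for cat in CATEGORIES:
        rows.append(
            (f"cost_{cat}", drug.cost_by_category[cat], non_drug.cost_by_category[cat])
        )
    df = pd.DataFrame(rows, columns=["outcome", "drug", "non_drug"])
    df["change"] = df["drug"] - df["non_drug"]
    return df


def _round_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    money = out["outcome"].str.startswith("cost") | out["outcome"].str.contains("icer")
    for col in ("drug", "non_drug", "change"):
        out[col] = np.where(money, out[col].round(_MONEY_DECIMALS),
                            out[col].round(_QALY_DECIMALS))
    return out


def write_comparison(
    drug: ArmResult,
    non_drug: ArmResult,
    comparison: CEComparison,
    outdir: Path,
    stem: str,
) -> list[Path]:
    """Write one horizon's comparison as CSV (rounded) and JSON (full precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    json_path = outdir / f"{stem}.json"
    _round_table(comparison_table(drug, non_drug)).to_csv(csv_path, index=False)
    payload = {
        "drug": drug.to_dict(),
        "non_drug": non_drug.to_dict(),
        "comparison": comparison.to_dict(),
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return [csv_path, json_path]


def write_cohort_trace(occ: np.ndarray, path: Path) -> Path:
    """Per-cycle deterministic state occupancy (cycle x expanded state) to CSV."""
    cols = [
        f"{state.name.lower()}" + (f"_attr{attr}" if attr else "")
        for state, attr in EXPANDED_STATES
    ]
    df = pd.DataFrame(occ, columns=cols)
    df.insert(0, "cycle", range(len(df)))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(e) for e in entries])
    df["range_width"] = [e.range_width for e in entries]
    return df


def scenarios_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.name,
                "horizon_years": r.horizon_years,
                "include_productivity": r.include_productivity,
                "drug_qalys": r.drug.discounted_qalys,
                "drug_cost": r.drug.discounted_cost,
                "non_drug_qalys": r.non_drug.discounted_qalys,
                "non_drug_cost": r.non_drug.discounted_cost,
                "delta_qaly": r.comparison.delta_qaly,
                "delta_cost": r.comparison.delta_cost,
                "icer": r.comparison.icer,
                "verdict": r.comparison.verdict,
            }
        )
    return pd.DataFrame(rows)


def write_manifest(
    outdir: Path,
    command: str,
    config: dict,
    seed: int | None,
    outputs: list[Path],
    params_path: str | None = None,
) -> Path:
    """Record what produced a result set; re-running from it reproduces the
    results per their determinism class (bit-identical for deterministic
    paths, draw-identical for seeded stochastic paths)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params_path": params_path,
        "config": config,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = outdir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
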