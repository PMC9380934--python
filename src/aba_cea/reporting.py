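"""Report writers: result tables, tornado, PSA draws and CEAC as CSV/JSON.

Every report directory gets a run log carrying the configuration hash and
any random seed, so a report can always be traced back to the exact inputs
that produced it.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .parameters import ParameterSet, save_parameters
from .pipeline import EconomicResult
from .sensitivity import CEACPoint, DSARow, PSAOutput

__all__ = ["config_hash", "write_reports"]


def config_hash(params: ParameterSet) -> str:
    """Stable short hash of the full configuration."""
    import tempfile

    with tempfile.NamedTemporaryFile("w+", suffix=".yaml") as fh:
        save_parameters(params, fh.name)
        fh.seek(0)
        return hashlib.sha256(fh.read().encode()).hexdigest()[:16]


def write_reports(
    results: list[EconomicResult],
    outdir,
    params: ParameterSet | None = None,
    psa: PSAOutput | None = None,
    dsa: list[DSARow] | None = None,
    ceac_points: list[CEACPoint] | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the result tables and figure data; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    res_df = pd.DataFrame([r.as_dict() for r in results])
    if res_df.empty:
        res_df = pd.DataFrame(
            columns=["scenario", "perspective", "durability", "cost_aba",
                     "cost_tau", "qaly_aba", "qaly_tau", "inc_cost",
                     "inc_qaly", "icer", "icer_flag"])
    written["results"] = outdir / "results.csv"
    res_df.to_csv(written["results"], index=False)
    written["results_json"] = outdir / "results.json"
    written["results_json"].write_text(
        json.dumps(res_df.to_dict(orient="records"), indent=2, default=float)
    )

    if dsa is not None:
        tor = pd.DataFrame(
            [{"parameter": r.parameter, "lower": r.lower, "upper": r.upper,
              "icer_at_lower": r.icer_at_lower, "icer_at_upper": r.icer_at_upper,
              "range": r.range} for r in dsa]
        )
        written["tornado"] = outdir / "tornado.csv"
        tor.to_csv(written["tornado"], index=False)

    if psa is not None:
        written["psa_iterations"] = outdir / "psa_iterations.csv"
        psa.iterations.to_csv(written["psa_iterations"], index=False)
        written["psa_summary"] = outdir / "psa_summary.json"
        written["psa_summary"].write_text(
            json.dumps(psa.summary(), indent=2, default=float))

    if ceac_points is not None:
        written["ceac"] = outdir / "ceac.csv"
        pd.DataFrame(
            [{"wtp": p.wtp, "p_cost_effective": p.p_cost_effective}
             for p in ceac_points]
        ).to_csv(written["ceac"], index=False)

    log = {
        "config_hash": config_hash(params) if params is not None else None,
        "seed": seed,
        "n_results": len(results),
    }
    written["run_log"] = outdir / "run_log.json"
    written["run_log"].write_text(json.dumps(log, indent=2))
    return written
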