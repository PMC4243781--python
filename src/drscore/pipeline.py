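"""End-to-end pipeline: score → eligibility → predict → analyze, plus the
reproduction report for the derivation study's printed aggregates.

Outputs are computed fully in memory and only then written, so a
validation failure never leaves partial outputs behind.  Every report
carries a provenance block (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__, published
from .core import Procedure
from .io import read_patients, score_frame
from .outcome import OutcomeModel, load_default_model
from .reconstruct import (
    default_constraints,
    reconstruct_score_distribution,
    solution_to_cohort,
)
from .rules import check_eligibility
from .stats import compare_remission_groups, t_test_from_summary

__all__ = ["RunConfig", "run_pipeline", "reproduce_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str
    out_dir: str
    procedure: Optional[str] = None  # overrides/filled in when the CSV lacks a procedure column
    seed: int = 0
    model_config_path: Optional[str] = None
    t_test_variant: str = "welch"

    def config_hash(self) -> str:
        # analysis-relevant settings only: identical analyses hash equal
        # regardless of where inputs/outputs live on disk
        payload = {
            "procedure": self.procedure,
            "seed": self.seed,
            "model_config_path": self.model_config_path,
            "t_test_variant": self.t_test_variant,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "drscore",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def _load_model(config: RunConfig) -> OutcomeModel:
    if config.model_config_path is None:
        return load_default_model()
    return OutcomeModel.from_config(json.loads(Path(config.model_config_path).read_text()))


def predictions_frame(scored: pd.DataFrame, model: OutcomeModel) -> pd.DataFrame:
    """Append remission_prob and recommended_procedure to a scored frame."""
    out = scored.copy()
    probs, recs = [], []
    for _, row in out.iterrows():
        total = int(row["drs_total"])
        rec = model.recommend_procedure(total)
        recs.append(rec.value if rec else "neither")
        proc = row.get("procedure")
        if isinstance(proc, str) and proc:
            probs.append(model.predict_remission(total, proc, warn_extrapolation=False))
        else:
            probs.append(math.nan)
    out["remission_prob"] = probs
    out["recommended_procedure"] = recs
    return out


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run score → eligibility → predict → analyze over one CSV.

    Writes ``scored.csv``, ``predictions.csv``, ``eligibility.csv``
    (when HbA1c is available) and ``report.json`` into ``out_dir`` and
    returns the report dict.
    """
    records = read_patients(config.input_path)
    if config.procedure is not None:
        proc = Procedure.coerce(config.procedure)
        records = [
            r if r.procedure is not None else _with_procedure(r, proc) for r in records
        ]

    scored = score_frame(records)
    model = _load_model(config)
    predictions = predictions_frame(scored, model)

    eligibility: Optional[pd.DataFrame] = None
    if all(r.hba1c is not None for r in records) and all(
        r.procedure is not None for r in records
    ):
        rows = []
        for r in records:
            verdict = check_eligibility(r, r.procedure)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "procedure": r.procedure.value,
                    "eligible": verdict.eligible,
                    "failed_criteria": ";".join(verdict.failed_criteria),
                }
            )
        eligibility = pd.DataFrame(rows)

    report: Dict[str, object] = {"provenance": _provenance(config)}
    report["n_patients"] = len(records)
    report["drs_totals"] = {
        str(k): int(v) for k, v in scored["drs_total"].value_counts().sort_index().items()
    }
    if all(r.observed_remission is not None for r in records):
        report["analysis"] = compare_remission_groups(
            predictions, variant=config.t_test_variant
        )
    else:
        report["analysis"] = None

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scored.to_csv(out_dir / "scored.csv", index=False)
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    if eligibility is not None:
        eligibility.to_csv(out_dir / "eligibility.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _with_procedure(record, procedure: Procedure):
    from dataclasses import replace

    return replace(record, procedure=procedure)


def _json_default(obj):
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def reproduce_report(seed: int = 0) -> Dict[str, object]:
    """Recompute the derivation study's in-scope printed aggregates.

    Returns a machine-readable report with, per procedure: the
    remission-probability band table, the remission rate recomputed via
    :func:`compare_remission_groups` on a reconstructed cohort, and the
    between/within-group t-tests recomputed from the printed summaries;
    plus the documented irreproducible values with what the package
    computes instead.
    """
    model = load_default_model()
    report: Dict[str, object] = {
        "provenance": {"package": "drscore", "version": __version__, "seed": seed},
        "procedures": {},
    }
    for proc in (Procedure.IISG, Procedure.IIDSG):
        agg = published.COHORTS[proc]
        bands = {
            str(s): model.predict_remission(s, proc, warn_extrapolation=False)
            for s in range(7, 15)
        }
        solutions = reconstruct_score_distribution(default_constraints(proc))
        entry: Dict[str, object] = {
            "bands": bands,
            "n_reconstruction_solutions": len(solutions),
            "printed": {
                "remission_rate_percent": agg["remission_rate_percent"],
                "drs_mean": agg["drs_mean"],
                "drs_sd": agg["drs_sd"],
            },
        }
        if solutions:
            cohort = solution_to_cohort(solutions[0], proc)
            analysis = compare_remission_groups(cohort)
            stratum = analysis["strata"][proc.value]
            entry["computed"] = {
                "remission_rate_percent": stratum["remission_rate_percent"],
                "drs_mean": round(solutions[0].mean, 4),
                "drs_sd": round(solutions[0].sd_n1, 4),
                "remitter_vs_non_remitter_p": stratum["t_test"]["p_value"],
            }
        report["procedures"][proc.value] = entry

    welch = t_test_from_summary(
        published.BETWEEN_PROCEDURES[Procedure.IISG],
        published.BETWEEN_PROCEDURES[Procedure.IIDSG],
        "welch",
    )
    report["between_procedures"] = {
        "printed_p": published.BETWEEN_PROCEDURES["printed_p"],
        "computed_p_welch": welch.p_value,
        "computed_p_rounded": round(welch.p_value, 4),
    }
    irre = published.IRREPRODUCIBLE["iisg_nonremit_vs_iidsg_remit_p"]
    report["irreproducible"] = {
        "iisg_nonremit_vs_iidsg_remit": {
            "printed_p": irre["printed"],
            "computed_p_welch": t_test_from_summary(irre["g1"], irre["g2"], "welch").p_value,
            "computed_p_pooled": t_test_from_summary(irre["g1"], irre["g2"], "pooled").p_value,
            "note": irre["note"],
        },
        "bmi_ge_35_subgroup_p": published.IRREPRODUCIBLE["bmi_ge_35_subgroup_p"],
        "table4_drs_rows": published.IRREPRODUCIBLE["table4_drs_rows"],
    }
    return report
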