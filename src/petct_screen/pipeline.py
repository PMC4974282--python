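"""Assembled end-to-end runs: cohort -> analysis set -> reports.

`run_accuracy` chains reading, reference-standard adjudication, set
selection, the combined PET+CT rule and the accuracy statistics into the
report files; `run_roc` does the same for the ordinal-score ROC analysis.
Report files are deterministic (no timestamps), so identical input and
configuration give byte-identical output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import __version__
from .accuracy import METRICS, ProportionEstimate, accuracy_profile, build_table, render_table
from .adjudicate import (
    AnalysisSet,
    SetLabel,
    all_patients_set,
    dm_truth,
    evaluable_set,
    locoregional_set,
)
from .cohort import Call, Cohort, Modality, read_cohort
from .combine import classify_patient
from .roc import auc_inference, empirical_roc, patient_scores

__all__ = ["RunConfig", "select_set", "modality_tables", "run_accuracy", "run_roc"]


class RunConfig(BaseModel):
    input: Path
    format: str = "csv"
    selector: SetLabel = SetLabel.EVALUABLE
    confidence: float = Field(default=0.95, gt=0, lt=1)
    out: Path = Path("run_output")
    make_plot: bool = False


def select_set(cohort: Cohort, selector: SetLabel) -> AnalysisSet:
    selector = SetLabel(selector)
    if selector is SetLabel.ALL:
        return all_patients_set(cohort)
    evaluable = evaluable_set(cohort)
    if selector is SetLabel.EVALUABLE:
        return evaluable
    return locoregional_set(evaluable)


def modality_tables(analysis_set: AnalysisSet):
    """Per-test calls, truths and 2x2 tables for CT, PET and the combination.

    Returns (tables, audit_rows): ``tables`` maps test label -> ContingencyTable;
    the audit rows record, per patient, each call, the truth, and which
    branch of the combined rule fired.
    """
    truths = [dm_truth(p.outcome) for p in analysis_set.patients]
    combined = [classify_patient(p.ct, p.pet) for p in analysis_set.patients]
    calls = {
        "CT": [p.ct.call for p in analysis_set.patients],
        "PET": [p.pet.call for p in analysis_set.patients],
        "PET and CT": [c.call for c in combined],
    }
    tables = {name: build_table(c, truths) for name, c in calls.items()}
    audit_rows = [
        {
            "patient_id": p.patient_id,
            "ct_call": p.ct.call.value,
            "pet_call": p.pet.call.value,
            "combined_call": comb.call.value,
            "rule_fired": comb.rule_fired.value,
            "dm_truth": truth.value,
        }
        for p, comb, truth in zip(analysis_set.patients, combined, truths)
    ]
    return tables, audit_rows


def _estimate_json(est: Optional[ProportionEstimate]) -> Optional[dict]:
    return None if est is None else asdict(est)


def run_accuracy(config: RunConfig, cohort: Optional[Cohort] = None) -> dict:
    """Accuracy pipeline; writes report.txt, report.json, audit.csv, manifest.json."""
    if cohort is None:
        cohort = read_cohort(config.input, config.format)
    analysis_set = select_set(cohort, config.selector)
    if len(analysis_set) == 0:
        raise ValueError(f"analysis set {config.selector.value!r} is empty")
    tables, audit_rows = modality_tables(analysis_set)
    profiles = {
        name: accuracy_profile(table, config.confidence) for name, table in tables.items()
    }

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    n_label = f"n = {len(analysis_set)} patients"
    (out / "report.txt").write_text(render_table(profiles, n_label))

    report = {
        "selector": config.selector.value,
        "n": len(analysis_set),
        "confidence": config.confidence,
        "excluded": [list(e) for e in analysis_set.excluded],
        "tables": {
            name: {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
            for name, t in tables.items()
        },
        "profiles": {
            name: {m: _estimate_json(profile[m]) for m in METRICS}
            for name, profile in profiles.items()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")

    with (out / "audit.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "patient_id", "ct_call", "pet_call", "combined_call", "rule_fired", "dm_truth",
            ],
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(audit_rows)

    _write_manifest(out, config)
    return report


def run_roc(config: RunConfig, cohort: Optional[Cohort] = None) -> dict:
    """ROC pipeline; writes roc.json (and optionally roc.png)."""
    if cohort is None:
        cohort = read_cohort(config.input, config.format)
    analysis_set = select_set(cohort, config.selector)
    results = {}
    scores = {}
    for modality in (Modality.CT, Modality.PET):
        s, truths = patient_scores(analysis_set, modality)
        if truths.all() or (~truths).all():
            raise ValueError(
                f"analysis set {config.selector.value!r} has only one truth class; "
                "ROC analysis is undefined"
            )
        scores[modality] = s
        roc = empirical_roc(s, truths)
        q = roc.q_point
        results[modality.value] = {
            "auc": roc.auc,
            "auc_se": roc.auc_se,
            "p_vs_half": roc.p_vs_half,
            "q_point": {
                "threshold": q.threshold,
                "sensitivity": q.sensitivity,
                "specificity": q.specificity,
            },
            "operating_points": [
                {"threshold": pt.threshold, "sensitivity": pt.sensitivity,
                 "specificity": pt.specificity}
                for pt in roc.operating_points
            ],
        }
    comparison = auc_inference(scores[Modality.CT], scores[Modality.PET], truths)
    report = {
        "selector": config.selector.value,
        "n": len(analysis_set),
        "modalities": results,
        "comparison": {
            "auc_ct": comparison.auc_a,
            "auc_pet": comparison.auc_b,
            "p_ct_vs_half": comparison.p_a_vs_half,
            "p_pet_vs_half": comparison.p_b_vs_half,
            "p_ct_vs_pet": comparison.p_a_vs_b,
        },
    }
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "roc.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    if config.make_plot:
        _plot_roc(results, out / "roc.png")
    _write_manifest(out, config)
    return report


def _plot_roc(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for modality, res in results.items():
        fpr = [1 - pt["specificity"] for pt in res["operating_points"]]
        tpr = [pt["sensitivity"] for pt in res["operating_points"]]
        ax.plot(fpr, tpr, marker="o", label=f"{modality} (AUC {res['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_manifest(out: Path, config: RunConfig) -> None:
    manifest = {
        "package": "petct-screen",
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
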