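"""End-to-end orchestration: simulate -> quantify -> stats -> train ->
evaluate -> impact -> triage, with one root seed and a machine-readable
report.

All randomness flows from the root seed through named child streams
(cohort, reads, training), so each stage is independently reproducible and
rerunning with the same configuration and seed yields a byte-identical
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, SignalModel, config_to_dict
from .quantitation import (
    LABEL_CANCER,
    build_feature_matrix,
    intra_assay_cv,
    write_features_csv,
)
from .stats import (
    classification_metrics,
    clopper_pearson,
    hotelling_t2,
    precision_from_replicates,
    timepoint_tests,
)
from .synthetic import (
    generate_cohort,
    generate_plate_reads,
    write_donors_csv,
    write_reads_csv,
)
from .evo import EvolutionConfig, train_model, relative_impact
from .evo.model import subset_rows, assert_no_leakage
from .triage import (
    TriageParams,
    fold_increase,
    simulate_ldct_only,
    simulate_leap_triage,
    triage_result_to_dict,
)

log = logging.getLogger("leap")

#: the seven highest-separation sensor_time features examined jointly
TOP_FEATURES = [
    "BM01_40",
    "BM10_40",
    "BM13_50",
    "BM14_50",
    "BM17_20",
    "BM18_30",
    "BM19_20",
]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    signal: SignalModel = field(default_factory=SignalModel)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    triage: TriageParams = field(default_factory=TriageParams)

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        self.signal.validate()
        self.evolution.validate()
        self.triage.validate()
        return self

    def to_dict(self) -> dict:
        return {
            "cohort": config_to_dict(self.cohort),
            "signal": config_to_dict(self.signal),
            "evolution": config_to_dict(self.evolution),
            "triage": config_to_dict(self.triage),
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def child_seeds(seed: int, n: int = 3) -> list[int]:
    """Named child streams derived from one root seed (all below 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def stage_stratified_metrics(truth, calls, stages) -> dict:
    """Sensitivity per cancer stage with exact CIs.

    Stages with zero cancer cases are reported as undefined (None), never 0.
    """
    truth = np.asarray(truth, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    stages = np.asarray(stages, dtype=object)
    out = {}
    for stage in ("I", "II", "III", "IV", "Unknown"):
        mask = truth & (stages == stage)
        n = int(mask.sum())
        if n == 0:
            out[stage] = {"sensitivity": None, "n": 0, "ci": None}
            continue
        x = int(calls[mask].sum())
        ci = clopper_pearson(x, n)
        out[stage] = {
            "sensitivity": x / n,
            "n": n,
            "ci": [ci.lower, ci.upper],
        }
    return out


def _metrics_block(truth, calls) -> dict:
    rep = classification_metrics(truth, calls)
    block = {}
    for name, ci in rep.metrics.items():
        block[name] = (
            None
            if ci is None
            else {"value": ci.estimate, "ci": [ci.lower, ci.upper]}
        )
    block["counts"] = {"tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn}
    return block


def run_pipeline(config: RunConfig, seed: int, out_dir) -> dict:
    """Execute every stage, writing intermediate artifacts and report.json."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_cohort, s_reads, s_train = child_seeds(seed)

    log.info("stage simulate: cohort + plate reads")
    donors = generate_cohort(config.cohort, seed=s_cohort)
    reads = generate_plate_reads(donors, config.signal, seed=s_reads)
    write_donors_csv(donors, out / "donors.csv")
    write_reads_csv(reads, out / "reads.csv")

    log.info("stage quantify: feature matrix")
    features = build_feature_matrix(reads, donors, lloq=config.signal.lloq)
    write_features_csv(features, out / "features.csv")

    log.info("stage stats: cohort statistics")
    comparisons, frac_sig = timepoint_tests(features)
    pdiffs = [c.percent_difference for c in comparisons if c.percent_difference is not None]
    labels = (features["label"] == LABEL_CANCER).to_numpy()
    top = [f for f in TOP_FEATURES if f in features.columns]
    hot = hotelling_t2(
        features.loc[labels, top].to_numpy(dtype=float),
        features.loc[~labels, top].to_numpy(dtype=float),
    )
    cv = intra_assay_cv(features)
    stats_block = {
        "fraction_significant_p01": frac_sig,
        "mean_percent_difference": float(np.mean(pdiffs)),
        "top_features": top,
        "top_mean_percent_difference": float(
            np.mean([c.percent_difference for c in comparisons if c.feature in top])
        ),
        "hotelling_top_features": {
            "t2": hot.t2,
            "f": hot.f_statistic,
            "df": [hot.df1, hot.df2],
            "p": hot.p_value,
        },
        "intra_assay_cv_pct": cv,
    }
    (out / "stats.json").write_text(
        json.dumps(_jsonify(stats_block), sort_keys=True, indent=1)
    )

    log.info("stage train: evolutionary classifier")
    model = train_model(features, config.evolution, seed=s_train)
    assert_no_leakage(model.split)
    model.save(out / "model.json")

    log.info("stage evaluate: operating points, stages, precision")
    evaluation = {}
    scopes = {
        "entire": features,
        "test": subset_rows(features, model.split, "Test"),
    }
    for scope, rows in scopes.items():
        truth = (rows["label"] == LABEL_CANCER).to_numpy()
        votes = model.vote_fraction(rows)
        evaluation[scope] = {
            op: _metrics_block(truth, votes >= thr)
            for op, thr in model.thresholds.items()
        }

    test_rows = scopes["test"]
    truth = (test_rows["label"] == LABEL_CANCER).to_numpy()
    calls = model.predict(test_rows, "ensemble")
    stage_block = stage_stratified_metrics(truth, calls, test_rows["stage"])

    precision_block = {}
    trip = test_rows.groupby("donor_id").filter(lambda g: len(g) == 3)
    if not trip.empty:
        for op in model.thresholds:
            grouped = {
                d: list(model.predict(g, op))
                for d, g in trip.groupby("donor_id")
            }
            precision_block[op] = precision_from_replicates(grouped)

    log.info("stage impact: sensor relative impact")
    sel_rows = subset_rows(features, model.split, "Selection")
    impact = relative_impact(model, sel_rows)

    log.info("stage triage: screening arithmetic")
    ldct = simulate_ldct_only(config.triage)
    triaged = simulate_leap_triage(config.triage)
    triage_block = {
        "ldct_only": triage_result_to_dict(ldct),
        "leap_triage": triage_result_to_dict(triaged),
        "fold_increase": fold_increase(ldct, triaged),
    }

    report = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": seed,
            "child_seeds": {
                "cohort": s_cohort,
                "reads": s_reads,
                "train": s_train,
            },
            "package_version": _package_version(),
        },
        "cohort": {
            "n_donors": int(len(donors)),
            "n_cancer": int((donors["diagnosis"] == "lung cancer").sum()),
            "n_assays": int(donors["n_assays"].sum()),
            "n_features": len(model.feature_names),
        },
        "stats": stats_block,
        "evaluation": evaluation,
        "stage_sensitivity_test": stage_block,
        "precision_test_pct": precision_block,
        "relative_impact": impact.to_dict(orient="records"),
        "triage": triage_block,
    }
    report = _jsonify(report)
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    log.info("pipeline complete: %s", out / "report.json")
    return report


def _package_version() -> str:
    from . import __version__

    return __version__
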