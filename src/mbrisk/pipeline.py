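"""End-to-end pipeline: simulate (or load) -> CNV calling -> stratify ->
survival curves -> model comparison.

Every run persists the effective configuration (with its hash and seed)
next to the outputs and logs a consort-style count at each filter step
(input n, eligible n, classified n), so reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .cnv import CallingThresholds, call_sample, calls_to_frame
from .evaluate import PRESET_SPECS, ModelSpec, compare_models
from .genome import load_default_genome
from .simulate import CohortConfig, generate_cohort, render_profile, cohort_to_frame, \
    labels_to_frame
from .stratify import MissingDataError, MolecularLabels, StratificationOptions, \
    assign_strata
from .survival import km_estimate, logrank_test

log = logging.getLogger("mbrisk")

__all__ = ["PipelineConfig", "run_pipeline", "stratify_cohort", "analysis_frame"]


@dataclass
class PipelineConfig:
    out_dir: str = "mbrisk_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    options: StratificationOptions = field(default_factory=StratificationOptions)
    models: tuple[str, ...] = ("clinical", "cm")
    horizon: float = 5.0
    bootstrap: int = 50
    seed: int = 17
    chromosomes: tuple[str, ...] | None = None  # restrict rendering/calling

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def stratify_cohort(cohort: pd.DataFrame, labels: pd.DataFrame, calls: pd.DataFrame,
                    options: StratificationOptions = StratificationOptions()
                    ) -> pd.DataFrame:
    """Per-patient risk assignment table from the three input tables."""
    merged = cohort.merge(labels, on="patient_id").merge(
        calls.rename(columns={"sample_id": "patient_id"}), on="patient_id")
    records = mio.records_from_frame(merged)
    rows = []
    for rec, raw in zip(records, merged.to_dict("records")):
        lab = MolecularLabels(raw.get("group"), raw.get("subgroup"),
                              raw.get("mcf_score"), raw.get("group_score"),
                              raw.get("subgroup_score"))
        from .cnv import MolecularCalls
        calls_obj = MolecularCalls(rec.patient_id, {},
                                   _nb(raw.get("chr7_gain")), _nb(raw.get("chr8_loss")),
                                   _nb(raw.get("chr11_loss")), _nb(raw.get("i17q")),
                                   _nb(raw.get("myc_amp")), _nb(raw.get("mycn_amp")))
        try:
            a = assign_strata(rec, lab, calls_obj, options)
            rows.append({"patient_id": rec.patient_id, "clinical": a.clinical,
                         "cm": a.cm, "reasons": ";".join(a.reasons)})
        except MissingDataError as err:
            rows.append({"patient_id": rec.patient_id, "clinical": "missing",
                         "cm": "missing", "reasons": f"missing_data:{err}"})
    return pd.DataFrame(rows)


def _nb(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return bool(v)


def analysis_frame(cohort: pd.DataFrame, labels: pd.DataFrame, calls: pd.DataFrame,
                   strata: pd.DataFrame) -> pd.DataFrame:
    """Join of all tables used by the survival models, complete cases only."""
    df = (cohort.merge(labels, on="patient_id")
                .merge(calls.rename(columns={"sample_id": "patient_id"}),
                       on="patient_id")
                .merge(strata[["patient_id", "clinical", "cm"]], on="patient_id"))
    return df[~df["cm"].isin(("missing", "unclassifiable"))].reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle as a dict of tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)
    (out / "comparison").mkdir(exist_ok=True)
    digest = config.digest()
    meta = {"config_hash": digest, "seed": config.seed}
    consort: list[tuple[str, int]] = []

    stage = "simulate"
    try:
        patients, labels_obj, truths = generate_cohort(config.cohort)
        cohort = cohort_to_frame(patients)
        labels = labels_to_frame(patients, labels_obj)
        consort.append(("input", len(cohort)))
        log.info("simulated %d patients (hash %s)", len(cohort), digest)

        stage = "call-cnv"
        genome = load_default_genome()
        if config.chromosomes:
            genome = genome.subset(config.chromosomes)
        calls = []
        for truth in truths:
            profile = render_profile(truth, genome, config.cohort)
            calls.append(call_sample(profile, genome, config.thresholds))
        calls_df = calls_to_frame(calls)

        stage = "stratify"
        strata = stratify_cohort(cohort, labels, calls_df, config.options)
        n_eligible = int((strata["clinical"] != "unclassifiable").sum())
        consort.append(("eligible", n_eligible))
        frame = analysis_frame(cohort, labels, calls_df, strata)
        consort.append(("classified", len(frame)))

        stage = "survfit"
        curves = {}
        for stratum, grp in frame.groupby("cm"):
            curves[stratum] = km_estimate(grp["pfs_years"], grp["pfs_event"]).to_frame()
        chi2, df_, p = logrank_test(frame["pfs_years"], frame["cm"], frame["pfs_event"])
        km_summary = pd.DataFrame({"stratum": list(curves),
                                   "n": [int((frame["cm"] == s).sum()) for s in curves]})

        stage = "compare-models"
        specs = [PRESET_SPECS[m] if m in PRESET_SPECS else ModelSpec(m, tuple(m.split("+")))
                 for m in config.models]
        comparison = compare_models(specs, frame, config.horizon, config.bootstrap,
                                    config.seed)
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        (out / "FAILED_STAGE").write_text(stage + "\n")
        raise

    # persist
    mio.write_cohort(cohort, out / "cohort.csv")
    mio.write_labels(labels, out / "labels.csv")
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    strata.to_csv(out / "strata.csv", index=False)
    for stratum, tab in curves.items():
        tab.to_csv(out / "curves" / f"km_pfs_{stratum}.tsv", sep="\t", index=False)
    comparison.metrics.to_csv(out / "comparison" / "metrics.tsv", sep="\t")
    for name, curve in comparison.auc_curves.items():
        curve.to_csv(out / "comparison" / f"auc_{name}.tsv", sep="\t", index=False)
    for name, curve in comparison.brier_curves.items():
        curve.to_csv(out / "comparison" / f"brier_{name}.tsv", sep="\t", index=False)
    config.cohort.to_yaml(out / "cohort_config.yaml")
    with open(out / "run_meta.json", "w") as fh:
        json.dump({**meta, "consort": consort,
                   "logrank": {"chi2": chi2, "df": df_, "p": p},
                   "best_model": comparison.best_model}, fh, indent=2)
    log.info("consort flow: %s", consort)
    return {"cohort": cohort, "labels": labels, "calls": calls_df, "strata": strata,
            "curves": curves, "comparison": comparison, "consort": consort,
            "logrank": (chi2, df_, p), "meta": meta}
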