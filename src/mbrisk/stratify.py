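"""Rule-based clinical and clinico-molecular risk strata.

Clinical standard risk (SR) mirrors the stratification used in current
European Group 3/4 medulloblastoma trials: completely resected (residual
< 1.5 cm^2, "R0"), non-metastatic (M0), non-anaplastic histology, no *MYC*
amplification, no *MYCN* amplification unless the tumor is Group 4, and age
at diagnosis of at least four years. Everything else is clinical high risk
(HR).

The integrated clinico-molecular (CM) strata refine this with methylation
subgroup and WCA phenotype:

* clinical SR with subgroup VII and/or WCA-FR  -> **CM-LR** (low risk)
* clinical SR otherwise                        -> **CM-SR**
* clinical HR with subgroup II, III or V       -> **CM-VHR** (very high risk)
* clinical HR otherwise                        -> **CM-HR**

By construction clinical HR can only flow to CM-HR/VHR and clinical SR only
to CM-LR/SR. Samples whose classifier scores fail the eligibility thresholds
(methylation-class-family score >= 0.9, group score >= 0.8, subgroup score
>= 0.8) are retained with an ``unclassifiable`` sentinel instead of being
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .cnv import MolecularCalls, WCA_MARKERS

__all__ = [
    "PatientRecord",
    "MolecularLabels",
    "RiskAssignment",
    "StratificationOptions",
    "eligibility_filter",
    "classify_clinical",
    "classify_cm",
    "assign_strata",
    "marker_combinations",
    "SUBGROUPS",
    "VHR_SUBGROUPS",
    "LR_SUBGROUP",
]

SUBGROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
VHR_SUBGROUPS = frozenset({"II", "III", "V"})
LR_SUBGROUP = "VII"


class MissingDataError(ValueError):
    """A required covariate is absent; the stratum is undecidable."""


@dataclass
class PatientRecord:
    """Clinical covariates and outcomes for one patient.

    Times are years since first tumor surgery. ``rt_start_years`` is the
    start of craniospinal irradiation, ``None`` if never irradiated; it is
    the time-dependent exposure in the Cox models.
    """

    patient_id: str
    age_years: float
    m_stage: Literal["M0", "M+"]
    resection: Literal["R0", "R+"]
    histology: Literal["CMB", "DMB", "LCA"]
    therapy: Literal["infant_type", "primary_CSI"]
    pfs_years: float
    pfs_event: bool
    os_years: float
    os_event: bool
    rt_start_years: float | None = None

    def __post_init__(self) -> None:
        if self.pfs_years > self.os_years + 1e-12:
            raise ValueError(f"{self.patient_id}: pfs_years exceeds os_years")
        if self.rt_start_years is not None and self.rt_start_years < 0:
            raise ValueError(f"{self.patient_id}: negative rt_start_years")


@dataclass
class MolecularLabels:
    """Externally supplied methylation classification of one sample."""

    group: Literal["Group3", "Group4"] | None
    subgroup: str | None
    mcf_score: float | None = None
    group_score: float | None = None
    subgroup_score: float | None = None


@dataclass
class RiskAssignment:
    clinical: Literal["SR", "HR", "unclassifiable"]
    cm: Literal["LR", "SR", "HR", "VHR", "unclassifiable"]
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StratificationOptions:
    """Tunable rule details. ``age_cutoff_years`` uses a closed (>=) comparison,
    matching the cohort tables' ">= 4 years" age category."""

    age_cutoff_years: float = 4.0
    mcf_score_min: float = 0.9
    group_score_min: float = 0.8
    subgroup_score_min: float = 0.8


def eligibility_filter(labels: MolecularLabels, group_score_mcf: float | None = None,
                       options: StratificationOptions = StratificationOptions()) -> bool | None:
    """Classifier-score eligibility; ``None`` when a score is missing."""
    mcf = labels.mcf_score if group_score_mcf is None else group_score_mcf
    scores = (mcf, labels.group_score, labels.subgroup_score)
    if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in scores):
        return None
    return bool(mcf >= options.mcf_score_min
                and labels.group_score >= options.group_score_min
                and labels.subgroup_score >= options.subgroup_score_min)


def classify_clinical(p: PatientRecord, labels: MolecularLabels, calls: MolecularCalls,
                      options: StratificationOptions = StratificationOptions()
                      ) -> tuple[Literal["SR", "HR"], list[str]]:
    """Clinical SR/HR stratum plus the list of HR triggers that fired."""
    required = {"age_years": p.age_years, "m_stage": p.m_stage, "resection": p.resection,
                "histology": p.histology, "myc_amp": calls.myc_amp,
                "mycn_amp": calls.mycn_amp, "group": labels.group}
    absent = [k for k, v in required.items()
              if v is None or (isinstance(v, float) and np.isnan(v))]
    # group only matters when MYCN is amplified
    if "group" in absent and calls.mycn_amp is False:
        absent.remove("group")
    if absent:
        raise MissingDataError(f"{p.patient_id}: missing {absent}")

    reasons = []
    if p.age_years < options.age_cutoff_years:
        reasons.append("age<4")
    if p.m_stage != "M0":
        reasons.append("metastatic")
    if p.resection != "R0":
        reasons.append("incomplete_resection")
    if p.histology == "LCA":
        reasons.append("anaplastic_histology")
    if calls.myc_amp:
        reasons.append("MYC_amplification")
    if calls.mycn_amp and labels.group != "Group4":
        reasons.append("MYCN_amplification_non_group4")
    return ("HR", reasons) if reasons else ("SR", ["clinical_SR"])


def classify_cm(clinical: Literal["SR", "HR"], labels: MolecularLabels,
                calls: MolecularCalls) -> RiskAssignment:
    """Clinico-molecular stratum from the clinical stratum, subgroup and WCA."""
    subgroup = labels.subgroup
    phenotype = calls.wca_phenotype
    if subgroup is None or phenotype is None:
        raise MissingDataError("subgroup or WCA phenotype unavailable")
    reasons: list[str] = []
    if clinical == "SR":
        if subgroup == LR_SUBGROUP:
            reasons.append("subgroup_VII")
        if phenotype == "FR":
            reasons.append("WCA_FR")
        cm = "LR" if reasons else "SR"
    elif clinical == "HR":
        if subgroup in VHR_SUBGROUPS:
            reasons.append(f"subgroup_{subgroup}")
        cm = "VHR" if reasons else "HR"
    else:
        raise ValueError(f"unknown clinical stratum {clinical!r}")
    return RiskAssignment(clinical, cm, reasons or [f"clinical_{clinical}_no_modifier"])


def assign_strata(p: PatientRecord, labels: MolecularLabels, calls: MolecularCalls,
                  options: StratificationOptions = StratificationOptions()) -> RiskAssignment:
    """Full per-patient assignment including the eligibility gate."""
    eligible = eligibility_filter(labels, options=options)
    if eligible is False:
        return RiskAssignment("unclassifiable", "unclassifiable", ["failed_score_eligibility"])
    clinical, reasons = classify_clinical(p, labels, calls, options)
    assignment = classify_cm(clinical, labels, calls)
    assignment.reasons = reasons + assignment.reasons
    return assignment


def marker_combinations(calls: pd.DataFrame | Iterable[MolecularCalls],
                        markers: Sequence[str]) -> pd.DataFrame:
    """Per-patient "at least k of the selected WCA markers" labels.

    ``markers`` is a non-empty subset of ``{"chr7_gain", "chr8_loss",
    "chr11_loss"}``; the result has one boolean column ``ge_k`` per
    k = 1..len(markers). With all three markers, ``ge_2`` reproduces the
    WCA-FR phenotype.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("markers must be non-empty")
    unknown = set(markers) - set(WCA_MARKERS)
    if unknown:
        raise ValueError(f"unknown markers {sorted(unknown)}; choose from {WCA_MARKERS}")
    if not isinstance(calls, pd.DataFrame):
        from .cnv import calls_to_frame
        calls = calls_to_frame(calls)
    counts = calls[markers].fillna(False).astype(bool).sum(axis=1)
    out = pd.DataFrame(index=calls.index)
    if "sample_id" in calls.columns:
        out["sample_id"] = calls["sample_id"]
    for k in range(1, len(markers) + 1):
        out[f"ge_{k}"] = counts >= k
    return out
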