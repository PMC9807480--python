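"""Synthetic non-WNT/non-SHH medulloblastoma cohorts.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every downstream stage (CNV calling, stratification, survival
modelling, model comparison) is testable without patient data:

* methylation subgroups I-VIII with configurable frequencies and the
  subgroup-to-group mapping (II/III/IV are Group 3; VIII is mostly Group 4);
* clinical covariates (age, M-stage, resection, histology, therapy type)
  with subgroup-conditional metastasis rates;
* MYC/MYCN amplification and whole-chromosome aberration ground truth per
  subgroup, rendered on demand as noisy binned log2-ratio profiles;
* progression and death times from stratum-specific exponential hazards
  calibrated to target 5-year survival probabilities, with independent
  censoring and a radiotherapy start time only for CSI-type therapy.

Defaults reflect a large published German/international (HIT) Group 3/4
cohort: ~66% metastatic, ~20% under four years of age, ~21% WCA
favorable-risk, 5-year PFS from 94% (CM-LR) down to 29% (CM-VHR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .cnv import CopyNumberProfile, MolecularCalls
from .genome import GenomeModel
from .stratify import (MolecularLabels, PatientRecord, StratificationOptions,
                       SUBGROUPS, classify_clinical, classify_cm)

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "render_profile",
           "cohort_to_frame", "labels_to_frame"]


class ConfigError(ValueError):
    pass


def _default_subgroup_freqs() -> dict[str, float]:
    return {"I": 0.024, "II": 0.116, "III": 0.136, "IV": 0.099,
            "V": 0.088, "VI": 0.112, "VII": 0.143, "VIII": 0.282}


def _default_m_plus() -> dict[str, float]:
    return {"I": 0.66, "II": 0.66, "III": 0.725, "IV": 0.483,
            "V": 0.808, "VI": 0.66, "VII": 0.66, "VIII": 0.66}


def _default_myc() -> dict[str, float]:
    return {"I": 0.005, "II": 0.26, "III": 0.33, "IV": 0.02,
            "V": 0.005, "VI": 0.005, "VII": 0.005, "VIII": 0.01}


def _default_mycn() -> dict[str, float]:
    return {"I": 0.02, "II": 0.02, "III": 0.02, "IV": 0.02,
            "V": 0.28, "VI": 0.24, "VII": 0.02, "VIII": 0.02}


def _default_wca() -> dict[str, float]:
    # per-marker Bernoulli rate for each of chr7 gain / chr8 loss / chr11 loss
    return {"I": 0.20, "II": 0.02, "III": 0.12, "IV": 0.45,
            "V": 0.20, "VI": 0.45, "VII": 0.45, "VIII": 0.20}


def _default_group3() -> dict[str, float]:
    return {"I": 0.0, "II": 1.0, "III": 1.0, "IV": 1.0,
            "V": 0.0, "VI": 0.0, "VII": 0.0, "VIII": 0.04}


def _default_surv5_pfs() -> dict[str, float]:
    return {"LR": 0.94, "SR": 0.65, "HR": 0.62, "VHR": 0.29}


def _default_surv5_os() -> dict[str, float]:
    return {"LR": 0.94, "SR": 0.78, "HR": 0.75, "VHR": 0.35}


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults emulate the reference cohort."""

    n_patients: int = 500
    seed: int = 0
    subgroup_freqs: dict[str, float] = field(default_factory=_default_subgroup_freqs)
    group3_rate_by_subgroup: dict[str, float] = field(default_factory=_default_group3)
    m_plus_rate_by_subgroup: dict[str, float] = field(default_factory=_default_m_plus)
    r_plus_rate: float = 0.122
    lca_rate: float = 0.095
    dmb_rate: float = 0.024
    age_lt4_rate: float = 0.197
    myc_amp_rate_by_subgroup: dict[str, float] = field(default_factory=_default_myc)
    mycn_amp_rate_by_subgroup: dict[str, float] = field(default_factory=_default_mycn)
    wca_truth_rates_by_subgroup: dict[str, float] = field(default_factory=_default_wca)
    i17q_rate: float = 0.63
    extra_arm_rate: float = 0.02
    surv5_pfs_by_stratum: dict[str, float] = field(default_factory=_default_surv5_pfs)
    surv5_os_by_stratum: dict[str, float] = field(default_factory=_default_surv5_os)
    censor_rate: float = 0.25
    followup_max_years: float = 12.0
    rt_start_offset_years: float = 0.25
    salvage_rt_rate: float = 0.5
    bin_size_bp: int = 1_000_000
    noise_sd: float = 0.1
    gain_effect: float = 0.35
    loss_effect: float = -0.35
    amp_effect: float = 1.0

    def validate(self) -> None:
        total = sum(self.subgroup_freqs.get(s, 0.0) for s in SUBGROUPS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subgroup_freqs must sum to 1, got {total}")
        probs = {**{f"freq[{k}]": v for k, v in self.subgroup_freqs.items()},
                 **{f"m_plus[{k}]": v for k, v in self.m_plus_rate_by_subgroup.items()},
                 **{f"myc[{k}]": v for k, v in self.myc_amp_rate_by_subgroup.items()},
                 **{f"mycn[{k}]": v for k, v in self.mycn_amp_rate_by_subgroup.items()},
                 **{f"wca[{k}]": v for k, v in self.wca_truth_rates_by_subgroup.items()},
                 **{f"group3[{k}]": v for k, v in self.group3_rate_by_subgroup.items()},
                 "r_plus_rate": self.r_plus_rate, "lca_rate": self.lca_rate,
                 "dmb_rate": self.dmb_rate, "age_lt4_rate": self.age_lt4_rate,
                 "i17q_rate": self.i17q_rate, "censor_rate": self.censor_rate,
                 "extra_arm_rate": self.extra_arm_rate,
                 "salvage_rt_rate": self.salvage_rt_rate}
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {name}={p} outside [0, 1]")
        for d in (self.surv5_pfs_by_stratum, self.surv5_os_by_stratum):
            for s, v in d.items():
                if not (0.0 < v <= 1.0):
                    raise ConfigError(f"5-year survival target for {s} must be in (0, 1]")
        if self.n_patients <= 0 or self.bin_size_bp <= 0:
            raise ConfigError("n_patients and bin_size_bp must be positive")
        if self.noise_sd < 0 or self.followup_max_years <= 0:
            raise ConfigError("noise_sd must be >= 0 and followup_max_years > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator planted for one patient."""

    patient_id: str
    index: int
    subgroup: str
    group: str
    arm_aberrations: set[tuple[str, str]]   # {(arm, "gain"|"loss"), ...}
    myc_amp: bool
    mycn_amp: bool
    cm_stratum: str
    clinical_stratum: str
    event_time_pfs: float
    event_time_os: float
    censor_time: float


def _pfs_rate(s5: float) -> float:
    return -np.log(s5) / 5.0 if s5 < 1.0 else 0.0


def _post_progression_rate(s5_pfs: float, s5_os: float) -> float | None:
    """Rate of the exponential progression-to-death interval such that the
    hypoexponential survival of (progression + interval) hits the OS target
    at five years. ``None`` means death coincides with progression."""
    if s5_os <= s5_pfs + 1e-9:
        return None
    lam_p = _pfs_rate(s5_pfs)

    def os_surv5(lam_e: float) -> float:
        if abs(lam_e - lam_p) < 1e-12:
            return float(np.exp(-lam_p * 5) * (1 + lam_p * 5))
        return float((lam_e * np.exp(-lam_p * 5) - lam_p * np.exp(-lam_e * 5))
                     / (lam_e - lam_p))

    lo, hi = 1e-8, 1e3
    if os_surv5(hi) > s5_os:   # even instant death after progression exceeds target
        return None
    return float(brentq(lambda l: os_surv5(l) - s5_os, lo, hi, xtol=1e-10))


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[PatientRecord], list[MolecularLabels], list[GroundTruth]]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subgroups = list(SUBGROUPS)
    freqs = np.array([config.subgroup_freqs[s] for s in subgroups])
    post_rates = {s: _post_progression_rate(config.surv5_pfs_by_stratum[s],
                                            config.surv5_os_by_stratum[s])
                  for s in config.surv5_pfs_by_stratum}
    options = StratificationOptions()

    patients, labels_list, truths = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        sg = subgroups[rng.choice(len(subgroups), p=freqs)]
        group = "Group3" if rng.random() < config.group3_rate_by_subgroup[sg] else "Group4"
        age = (rng.uniform(0.3, 4.0) if rng.random() < config.age_lt4_rate
               else rng.uniform(4.0, 17.0))
        m_stage = "M+" if rng.random() < config.m_plus_rate_by_subgroup[sg] else "M0"
        resection = "R+" if rng.random() < config.r_plus_rate else "R0"
        u = rng.random()
        histology = ("LCA" if u < config.lca_rate
                     else "DMB" if u < config.lca_rate + config.dmb_rate else "CMB")
        therapy = "infant_type" if age < 4.0 else "primary_CSI"
        myc = rng.random() < config.myc_amp_rate_by_subgroup[sg]
        mycn = rng.random() < config.mycn_amp_rate_by_subgroup[sg]

        # molecular ground truth: WCA markers, i17q, occasional extra whole arms
        p_w = config.wca_truth_rates_by_subgroup[sg]
        chr7 = rng.random() < p_w
        chr8 = rng.random() < p_w
        chr11 = rng.random() < p_w
        aberrations: set[tuple[str, str]] = set()
        if chr7:
            aberrations |= {("7p", "gain"), ("7q", "gain")}
        if chr8:
            aberrations |= {("8p", "loss"), ("8q", "loss")}
        if chr11:
            aberrations |= {("11p", "loss"), ("11q", "loss")}
        if rng.random() < config.i17q_rate:
            aberrations |= {("17p", "loss"), ("17q", "gain")}
        for arm in ("1q", "2p", "4q", "10q", "16q"):
            if rng.random() < config.extra_arm_rate:
                aberrations.add((arm, "gain" if rng.random() < 0.5 else "loss"))

        labels = MolecularLabels(group=group, subgroup=sg,
                                 mcf_score=rng.uniform(0.92, 1.0),
                                 group_score=rng.uniform(0.82, 1.0),
                                 subgroup_score=rng.uniform(0.82, 1.0))
        wca_count = int(chr7) + int(chr8) + int(chr11)
        truth_calls = _truth_calls(pid, chr7, chr8, chr11, myc, mycn)
        clinical, _ = classify_clinical(
            _proto_record(pid, age, m_stage, resection, histology, therapy),
            labels, truth_calls, options)
        cm = classify_cm(clinical, labels, truth_calls).cm

        lam_p = _pfs_rate(config.surv5_pfs_by_stratum[cm])
        t_pfs = rng.exponential(1.0 / lam_p) if lam_p > 0 else np.inf
        lam_e = post_rates[cm]
        t_os = t_pfs if lam_e is None else t_pfs + rng.exponential(1.0 / lam_e)
        censor = (rng.uniform(0.05, config.followup_max_years)
                  if rng.random() < config.censor_rate else config.followup_max_years)

        pfs_years = float(min(t_pfs, censor))
        pfs_event = bool(t_pfs <= censor)
        os_years = float(min(t_os, censor))
        os_event = bool(t_os <= censor)

        if therapy == "primary_CSI":
            rt_start = config.rt_start_offset_years
        elif pfs_event and rng.random() < config.salvage_rt_rate:
            rt_start = pfs_years  # salvage irradiation at progression
        else:
            rt_start = None

        patients.append(PatientRecord(pid, float(age), m_stage, resection, histology,
                                      therapy, pfs_years, pfs_event, os_years, os_event,
                                      rt_start))
        labels_list.append(labels)
        truths.append(GroundTruth(pid, i, sg, group, aberrations, myc, mycn, cm,
                                  clinical, float(t_pfs), float(t_os), float(censor)))
    return patients, labels_list, truths


def _proto_record(pid, age, m_stage, resection, histology, therapy) -> PatientRecord:
    # outcome fields are placeholders; only covariates matter for the rule
    return PatientRecord(pid, age, m_stage, resection, histology, therapy,
                         1.0, False, 1.0, False, None)


def _truth_calls(pid: str, chr7: bool, chr8: bool, chr11: bool,
                 myc: bool, mycn: bool) -> MolecularCalls:
    return MolecularCalls(pid, {}, chr7, chr8, chr11, None, myc, mycn)


def render_profile(truth: GroundTruth, genome: GenomeModel, config: CohortConfig,
                   rng: np.random.Generator | None = None) -> CopyNumberProfile:
    """Binned log2-ratio profile with the planted aberrations.

    Bins tile each non-acrocentric arm at ``bin_size_bp``; bins inside a
    planted aberration are shifted by the gain/loss effect, bins over an
    amplified locus by the amplification effect, and Gaussian noise of sd
    ``noise_sd`` is added everywhere. The per-sample RNG stream is derived
    from (config seed, patient index), so profiles are reproducible
    independent of rendering order.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 7919, truth.index])
    present = set(genome.chromosomes())
    for arm, _ in truth.arm_aberrations:
        # aberrations on chromosomes outside a restricted genome are out of
        # scope; an unknown arm on a covered chromosome is a data error
        if arm not in genome and f"chr{arm[:-1]}" in present:
            raise KeyError(f"{truth.patient_id}: truth references unknown arm {arm!r}")
    chroms, starts, ends, vals = [], [], [], []
    for name, arm in genome.arms.items():
        if arm.acrocentric:
            continue
        edges = np.arange(arm.start, arm.end, config.bin_size_bp)
        b_start = edges
        b_end = np.minimum(edges + config.bin_size_bp, arm.end)
        level = 0.0
        if (name, "gain") in truth.arm_aberrations:
            level = config.gain_effect
        elif (name, "loss") in truth.arm_aberrations:
            level = config.loss_effect
        v = np.full(len(edges), level)
        for locus_name, amp in (("MYC", truth.myc_amp), ("MYCN", truth.mycn_amp)):
            if amp and locus_name in genome.loci:
                locus = genome.loci[locus_name]
                if locus.chrom == arm.chrom:
                    hit = (b_end > locus.start) & (b_start < locus.end)
                    v[hit] += config.amp_effect
        chroms.extend([arm.chrom] * len(edges))
        starts.append(b_start)
        ends.append(b_end)
        vals.append(v)
    bins = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate(starts),
        "end": np.concatenate(ends),
        "log2": np.concatenate(vals),
    })
    if config.noise_sd > 0:
        bins["log2"] = bins["log2"] + rng.normal(0.0, config.noise_sd, len(bins))
    # bins are constructed ordered and non-overlapping; skip re-validation
    return CopyNumberProfile(truth.patient_id, bins, "binned", validate=False)


def cohort_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in patients])


def labels_to_frame(patients: Sequence[PatientRecord],
                    labels: Sequence[MolecularLabels]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(l) for l in labels])
    df.insert(0, "patient_id", [p.patient_id for p in patients])
    return df
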