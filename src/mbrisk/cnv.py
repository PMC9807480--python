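"""Arm-level copy-number calling from binned log2-ratio profiles.

Methylation-array copy-number plots (conumee-style) give a log2 ratio per
genomic bin. The calling scheme here is the deterministic counterpart of the
visual-inspection rules used for Group 3/4 medulloblastoma risk markers:

* an arm is **gained** (lost) when bins at least ``arm_log2`` above (below)
  the sample baseline cover at least ``arm_fraction`` of the profiled arm
  length — defaults 0.2 and 80%;
* *MYC* / *MYCN* are **amplified** when the length-weighted median log2 over
  the locus is at least ``amp_log2`` (default 0.4) above baseline;
* a whole-chromosomal aberration (WCA) requires *both* arms: chr7 gain,
  chr8 loss, chr11 loss; the WCA favorable-risk (FR) phenotype requires at
  least two of the three, otherwise standard risk (SR);
* i17q = 17p loss together with 17q gain.

The per-sample baseline is the length-weighted median log2 over autosomal
bins, which makes every call invariant to a uniform shift of the profile.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .genome import GenomeModel, Locus

__all__ = [
    "CopyNumberProfile",
    "CallingThresholds",
    "ArmCall",
    "MolecularCalls",
    "estimate_baseline",
    "call_arm_status",
    "call_amplification",
    "call_sample",
    "calls_to_frame",
]

WCA_MARKERS = ("chr7_gain", "chr8_loss", "chr11_loss")

BIN_COLUMNS = ["chrom", "start", "end", "log2"]


class ProfileError(ValueError):
    """Malformed or insufficient copy-number data."""


@dataclass
class CopyNumberProfile:
    """One sample's binned log2-ratio profile.

    ``bins`` is a DataFrame with columns chrom, start, end, log2 using
    0-based half-open coordinates; bins must not overlap within a chromosome.
    ``validate=False`` skips sorting and overlap checks for callers that
    construct bins already ordered (the profile renderer).
    """

    sample_id: str
    bins: pd.DataFrame
    provenance: Literal["binned", "segmented"] = "binned"
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        if not validate:
            return
        missing = [c for c in BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ProfileError(f"{self.sample_id}: bins missing columns {missing}")
        b = self.bins
        if len(b) and not np.all(b["end"].to_numpy() > b["start"].to_numpy()):
            raise ProfileError(f"{self.sample_id}: every bin needs end > start")
        if len(b) and not np.all(np.isfinite(b["log2"].to_numpy(float))):
            raise ProfileError(f"{self.sample_id}: non-finite log2 ratios")
        self.bins = b.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            if np.any(grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]):
                raise ProfileError(f"{self.sample_id}: overlapping bins on {chrom}")

    def chromosomes(self) -> set[str]:
        return set(self.bins["chrom"].unique())

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (start, end, log2) numpy views, cached.

        Bins are sorted and non-overlapping, so any interval query reduces to
        a contiguous slice found by binary search.
        """
        cached = getattr(self, "_arrays", None)
        if cached is None:
            cached = {}
            start = self.bins["start"].to_numpy(np.int64)
            end = self.bins["end"].to_numpy(np.int64)
            log2 = self.bins["log2"].to_numpy(float)
            chroms = self.bins["chrom"].to_numpy()
            bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
            for i, j in zip(bounds[:-1], bounds[1:]):
                cached[chroms[i]] = (start[i:j], end[i:j], log2[i:j])
            object.__setattr__(self, "_arrays", cached)
        return cached

    def _slice(self, chrom: str, lo: int, hi: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        """Bins overlapping [lo, hi), clipped to it; None when there are none."""
        arr = self.arrays().get(chrom)
        if arr is None:
            return None
        start, end, log2 = arr
        i = int(np.searchsorted(end, lo, side="right"))
        j = int(np.searchsorted(start, hi, side="left"))
        if i >= j:
            return None
        return (np.clip(start[i:j], lo, None), np.clip(end[i:j], None, hi), log2[i:j])

    def shifted(self, delta: float) -> "CopyNumberProfile":
        b = self.bins.copy()
        b["log2"] = b["log2"] + delta
        return CopyNumberProfile(self.sample_id, b, self.provenance)


@dataclass(frozen=True)
class CallingThresholds:
    """Log2-ratio and arm-coverage thresholds (closed ``>=`` comparisons)."""

    amp_log2: float = 0.4
    arm_log2: float = 0.2
    arm_fraction: float = 0.8
    baseline_estimator: Literal["median", "trimmed_mean"] = "median"

    def __post_init__(self) -> None:
        if not (self.amp_log2 > self.arm_log2 > 0):
            raise ValueError("need amp_log2 > arm_log2 > 0")
        if not (0 < self.arm_fraction <= 1):
            raise ValueError("arm_fraction must be in (0, 1]")


@dataclass
class ArmCall:
    arm: str
    status: Literal["gain", "loss", "neutral", "missing"]
    gain_fraction: float
    loss_fraction: float
    mean_log2: float


@dataclass
class MolecularCalls:
    """All molecular risk-marker calls for one sample.

    WCA flags are ``None`` when the required chromosome was not profiled;
    ``wca_count`` then counts the markers that could be evaluated and
    ``wca_phenotype`` is ``None`` unless already decided (>=2 present).
    """

    sample_id: str
    arm_calls: dict[str, ArmCall]
    chr7_gain: bool | None
    chr8_loss: bool | None
    chr11_loss: bool | None
    i17q: bool | None
    myc_amp: bool | None
    mycn_amp: bool | None
    missing: list[str] = field(default_factory=list)

    @property
    def wca_count(self) -> int:
        return sum(bool(f) for f in (self.chr7_gain, self.chr8_loss, self.chr11_loss))

    @property
    def wca_phenotype(self) -> Literal["FR", "SR"] | None:
        flags = (self.chr7_gain, self.chr8_loss, self.chr11_loss)
        if self.wca_count >= 2:
            return "FR"
        if any(f is None for f in flags):
            return None  # undecidable with missing markers
        return "SR"


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    idx = int(np.searchsorted(cw, half))
    # interpolate at an exact half split for symmetry with the unweighted median
    if np.isclose(cw[idx], half) and idx + 1 < len(v):
        return 0.5 * (v[idx] + v[idx + 1])
    return float(v[idx])


def estimate_baseline(profile: CopyNumberProfile, genome: GenomeModel | None = None,
                      thresholds: CallingThresholds | None = None) -> float:
    """Length-weighted median log2 over autosomal bins.

    Robust to up to half of the genome being aberrant, and a uniform shift of
    the profile moves the baseline by the same amount — so shifted profiles
    yield identical calls.
    """
    arrays = profile.arrays()
    if genome is not None:
        keep = [c for c in genome.autosomes() if c in arrays]
    else:
        keep = [c for c in arrays if c not in ("chrX", "chrY", "X", "Y")]
    if not keep:
        raise ProfileError(f"{profile.sample_id}: no autosomal bins to estimate baseline")
    values = np.concatenate([arrays[c][2] for c in keep])
    weights = np.concatenate([(arrays[c][1] - arrays[c][0]) for c in keep]).astype(float)
    if thresholds is not None and thresholds.baseline_estimator == "trimmed_mean":
        lo, hi = np.quantile(values, [0.25, 0.75])
        keep = (values >= lo) & (values <= hi)
        return float(np.average(values[keep], weights=weights[keep]))
    return _weighted_median(values, weights)


def call_arm_status(profile: CopyNumberProfile, arm: str, baseline: float,
                    thresholds: CallingThresholds, genome: GenomeModel) -> ArmCall:
    """Gain/loss/neutral call for one arm.

    Fractions are length-weighted over the *profiled* part of the arm (array
    bins never tile an arm completely); bins are clipped to arm boundaries.
    """
    a = genome[arm]
    sl = profile._slice(a.chrom, a.start, a.end)
    if sl is None:
        return ArmCall(arm, "missing", np.nan, np.nan, np.nan)
    b_start, b_end, log2 = sl
    lengths = (b_end - b_start).astype(float)
    rel = log2 - baseline
    total = lengths.sum()
    gain_fraction = float(lengths[rel >= thresholds.arm_log2].sum() / total)
    loss_fraction = float(lengths[rel <= -thresholds.arm_log2].sum() / total)
    if gain_fraction >= thresholds.arm_fraction:
        status = "gain"
    elif loss_fraction >= thresholds.arm_fraction:
        status = "loss"
    else:
        status = "neutral"
    mean_log2 = float(np.average(log2, weights=lengths))
    return ArmCall(arm, status, gain_fraction, loss_fraction, mean_log2)


def call_amplification(profile: CopyNumberProfile, locus: Locus, baseline: float,
                       thresholds: CallingThresholds) -> bool | None:
    """Amplified iff the length-weighted median log2 over the locus is
    ``>= baseline + amp_log2``. Returns ``None`` when no bin overlaps."""
    sl = profile._slice(locus.chrom, locus.start, locus.end)
    if sl is None:
        return None
    b_start, b_end, log2 = sl
    med = _weighted_median(log2, (b_end - b_start).astype(float))
    return bool(med >= baseline + thresholds.amp_log2)


def _both(call_p: ArmCall, call_q: ArmCall, status: str) -> bool | None:
    if call_p.status == "missing" or call_q.status == "missing":
        return None
    return call_p.status == status and call_q.status == status


def call_sample(profile: CopyNumberProfile, genome: GenomeModel,
                thresholds: CallingThresholds | None = None) -> MolecularCalls:
    """All arm calls plus WCA / i17q / amplification flags for one sample.

    Chromosomes absent from the profile yield ``None`` flags and are listed
    in ``missing`` rather than silently called neutral.
    """
    thresholds = thresholds or CallingThresholds()
    baseline = estimate_baseline(profile, genome, thresholds)
    arm_calls: dict[str, ArmCall] = {}
    for name, a in genome.arms.items():
        if a.acrocentric:
            continue  # no array coverage on acrocentric p arms
        arm_calls[name] = call_arm_status(profile, name, baseline, thresholds, genome)

    def st(arm: str) -> ArmCall:
        return arm_calls.get(arm, ArmCall(arm, "missing", np.nan, np.nan, np.nan))

    chr7_gain = _both(st("7p"), st("7q"), "gain")
    chr8_loss = _both(st("8p"), st("8q"), "loss")
    chr11_loss = _both(st("11p"), st("11q"), "loss")
    if st("17p").status == "missing" or st("17q").status == "missing":
        i17q = None
    else:
        i17q = st("17p").status == "loss" and st("17q").status == "gain"

    myc_amp = mycn_amp = None
    if "MYC" in genome.loci:
        myc_amp = call_amplification(profile, genome.loci["MYC"], baseline, thresholds)
    if "MYCN" in genome.loci:
        mycn_amp = call_amplification(profile, genome.loci["MYCN"], baseline, thresholds)

    missing = sorted({c.arm for c in arm_calls.values() if c.status == "missing"} |
                     ({"MYC"} if myc_amp is None else set()) |
                     ({"MYCN"} if mycn_amp is None else set()))
    return MolecularCalls(profile.sample_id, arm_calls, chr7_gain, chr8_loss, chr11_loss,
                          i17q, myc_amp, mycn_amp, missing)


def calls_to_frame(calls: Iterable[MolecularCalls]) -> pd.DataFrame:
    """One-row-per-sample summary table of molecular calls."""
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id,
            "chr7_gain": c.chr7_gain,
            "chr8_loss": c.chr8_loss,
            "chr11_loss": c.chr11_loss,
            "wca_count": c.wca_count,
            "wca_phenotype": c.wca_phenotype,
            "i17q": c.i17q,
            "myc_amp": c.myc_amp,
            "mycn_amp": c.mycn_amp,
            "n_missing": len(c.missing),
        })
    return pd.DataFrame(rows)
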