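"""File formats: tidy cohort CSV/TSV, IGV SEG, binned log2 TSV, calls and
strata tables.

Column names and enum spellings are frozen here (M0/M+, R0/R+, CMB/DMB/LCA,
Group3/Group4, subgroups I-VIII, WCA FR/SR, strata LR/SR/HR/VHR). Readers
validate rather than coerce: malformed rows raise with the file, row and
field named. SEG files use 1-based inclusive coordinates and are converted
to the package's 0-based half-open convention on read.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CopyNumberProfile
from .genome import GenomeModel
from .stratify import PatientRecord, SUBGROUPS

__all__ = [
    "COHORT_COLUMNS", "read_cohort", "write_cohort", "read_labels", "write_labels",
    "read_seg", "write_seg", "read_bins", "write_bins", "records_from_frame",
    "SchemaError",
]


class SchemaError(ValueError):
    pass


COHORT_COLUMNS = ["patient_id", "age_years", "m_stage", "resection", "histology",
                  "therapy", "pfs_years", "pfs_event", "os_years", "os_event",
                  "rt_start_years"]

_ENUMS = {
    "m_stage": {"M0", "M+"},
    "resection": {"R0", "R+"},
    "histology": {"CMB", "DMB", "LCA"},
    "therapy": {"infant_type", "primary_CSI"},
}

LABEL_COLUMNS = ["patient_id", "group", "subgroup", "mcf_score", "group_score",
                 "subgroup_score"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".seg", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; returns the typed DataFrame."""
    df = _read_table(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "rt_start_years"]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if "rt_start_years" not in df.columns:
        df["rt_start_years"] = np.nan
    problems = []
    for col, allowed in _ENUMS.items():
        bad = df.loc[~df[col].isin(allowed)]
        for i in bad.index:
            problems.append(f"row {i + 2}: field {col!r} = {df.loc[i, col]!r} "
                            f"not in {sorted(allowed)}")
    for col in ("age_years", "pfs_years", "os_years"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()]:
            problems.append(f"row {i + 2}: field {col!r} = {df.loc[i, col]!r} not numeric")
        df[col] = vals
    for col in ("pfs_event", "os_event"):
        df[col] = df[col].astype(bool)
    bad_t = df.index[(df["pfs_years"] <= 0) | (df["os_years"] <= 0)]
    for i in bad_t:
        problems.append(f"row {i + 2}: non-positive follow-up time")
    bad_order = df.index[df["pfs_years"] > df["os_years"] + 1e-12]
    for i in bad_order:
        problems.append(f"row {i + 2}: os_years < pfs_years")
    bad_rt = df.index[pd.to_numeric(df["rt_start_years"], errors="coerce") < 0]
    for i in bad_rt:
        problems.append(f"row {i + 2}: negative rt_start_years")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df[COHORT_COLUMNS]


def write_cohort(df_or_records, path: str | Path) -> None:
    if not isinstance(df_or_records, pd.DataFrame):
        df_or_records = pd.DataFrame([asdict(p) for p in df_or_records])
    sep = "\t" if str(path).endswith(".tsv") else ","
    df_or_records.to_csv(path, sep=sep, index=False)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for rec in df.to_dict("records"):
        rt = rec.get("rt_start_years")
        rt = None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt)
        out.append(PatientRecord(str(rec["patient_id"]), float(rec["age_years"]),
                                 rec["m_stage"], rec["resection"], rec["histology"],
                                 rec["therapy"], float(rec["pfs_years"]),
                                 bool(rec["pfs_event"]), float(rec["os_years"]),
                                 bool(rec["os_event"]), rt))
    return out


def read_labels(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in ("patient_id", "group", "subgroup") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    problems = []
    bad_g = df.index[~df["group"].isin({"Group3", "Group4"}) & df["group"].notna()]
    for i in bad_g:
        problems.append(f"row {i + 2}: group {df.loc[i, 'group']!r} not Group3/Group4")
    bad_s = df.index[~df["subgroup"].isin(SUBGROUPS) & df["subgroup"].notna()]
    for i in bad_s:
        problems.append(f"row {i + 2}: subgroup {df.loc[i, 'subgroup']!r} not I..VIII")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    for c in ("mcf_score", "group_score", "subgroup_score"):
        if c not in df.columns:
            df[c] = np.nan
    return df[LABEL_COLUMNS]


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# copy-number formats

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_seg(path: str | Path, genome: GenomeModel | None = None,
             strict: bool = False) -> list[CopyNumberProfile]:
    """Read an IGV SEG file into per-sample profiles.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    segments are sorted and checked for overlap per chromosome. Chromosomes
    not in ``genome`` are skipped with a warning (error with ``strict``).
    """
    import warnings

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing SEG columns {missing}")
    df = df.rename(columns={"loc.start": "start", "loc.end": "end", "seg.mean": "log2"})
    df["chrom"] = df["chrom"].astype(str)
    df.loc[~df["chrom"].str.startswith("chr"), "chrom"] = \
        "chr" + df.loc[~df["chrom"].str.startswith("chr"), "chrom"]
    if genome is not None:
        known = set(genome.chromosomes())
        unknown = sorted(set(df["chrom"]) - known)
        if unknown:
            msg = f"{path}: unknown chromosomes {unknown}"
            if strict:
                raise SchemaError(msg)
            warnings.warn(msg + " (skipped)", stacklevel=2)
            df = df[df["chrom"].isin(known)]
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    profiles = []
    for sample, grp in df.groupby("ID", sort=False):
        bins = grp[["chrom", "start", "end", "log2"]].reset_index(drop=True)
        profiles.append(CopyNumberProfile(str(sample), bins, "segmented"))
    return profiles


def write_seg(profiles: Sequence[CopyNumberProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        b = p.bins.copy()
        frames.append(pd.DataFrame({
            "ID": p.sample_id, "chrom": b["chrom"], "loc.start": b["start"] + 1,
            "loc.end": b["end"], "num.mark": 1, "seg.mean": b["log2"],
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path, sample_id: str | None = None) -> CopyNumberProfile:
    """Read a binned TSV (chrom, start, end, log2), 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "log2") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return CopyNumberProfile(sample_id or Path(path).stem,
                             df[["chrom", "start", "end", "log2"]], "binned")


def write_bins(profile: CopyNumberProfile, path: str | Path) -> None:
    profile.bins.to_csv(path, sep="\t", index=False)
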