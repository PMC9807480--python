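"""Genome arm model.

Chromosome arms are the coordinate frame for arm-level copy-number calling:
a gain or loss is only called when it covers (nearly) a whole arm, and the
whole-chromosomal-aberration (WCA) markers require *both* arms of a
chromosome to be aberrant. The default model ships with the package as an
hg19 arm table derived from the UCSC cytoband track (arm boundaries at the
centromeric ``acen`` bands), plus the two amplification loci that matter for
Group 3/4 medulloblastoma: *MYC* (8q24) and *MYCN* (2p24).

All coordinates are 0-based half-open, BED-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["Arm", "Locus", "GenomeModel", "load_default_genome", "read_arms_bed"]


@dataclass(frozen=True)
class Arm:
    """One chromosome arm as a half-open genomic interval."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    acrocentric: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Locus:
    """A named focal locus (e.g. the MYC gene body), used for amplification calls."""

    name: str
    chrom: str
    start: int
    end: int


class GenomeModel:
    """Arm intervals plus named loci for one genome build.

    Parameters
    ----------
    arms
        Iterable of :class:`Arm`. Within a chromosome the p arm must precede
        the q arm and the intervals must be disjoint.
    loci
        Mapping of locus name to :class:`Locus`; every locus must fall
        inside exactly one arm.
    """

    def __init__(self, arms: Iterable[Arm], loci: Mapping[str, Locus] | None = None,
                 build: str = "custom"):
        self.build = build
        self._arms: dict[str, Arm] = {}
        for a in arms:
            if a.end <= a.start:
                raise ValueError(f"arm {a.name}: end must exceed start")
            self._arms[a.name] = a
        self.loci: dict[str, Locus] = dict(loci or {})
        self._validate()

    def _validate(self) -> None:
        for chrom in self.chromosomes():
            arms = self.chromosome_arms(chrom)
            if len(arms) == 2:
                p, q = sorted(arms, key=lambda a: a.arm)
                if not (p.arm == "p" and q.arm == "q"):
                    raise ValueError(f"{chrom}: expected p and q arms")
                if p.end > q.start:
                    raise ValueError(f"{chrom}: p and q arms overlap")
        for locus in self.loci.values():
            hits = [a for a in self._arms.values()
                    if a.chrom == locus.chrom and a.start <= locus.start and locus.end <= a.end]
            if len(hits) != 1:
                raise ValueError(f"locus {locus.name} must lie inside exactly one arm, "
                                 f"found {len(hits)}")

    # -- access -----------------------------------------------------------

    @property
    def arms(self) -> dict[str, Arm]:
        return dict(self._arms)

    def __getitem__(self, name: str) -> Arm:
        try:
            return self._arms[name]
        except KeyError:
            raise KeyError(f"unknown arm {name!r}; known: {sorted(self._arms)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._arms

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self._arms.values():
            seen.setdefault(a.chrom, None)
        return list(seen)

    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes() if c.removeprefix("chr") not in ("X", "Y")]

    def chromosome_arms(self, chrom: str) -> list[Arm]:
        return [a for a in self._arms.values() if a.chrom == chrom]

    def arm_of_locus(self, name: str) -> Arm:
        locus = self.loci[name]
        for a in self._arms.values():
            if a.chrom == locus.chrom and a.start <= locus.start and locus.end <= a.end:
                return a
        raise KeyError(name)

    def subset(self, chromosomes: Iterable[str]) -> "GenomeModel":
        """Restrict the model to the given chromosomes (loci inside them are kept)."""
        keep = {c if str(c).startswith("chr") else f"chr{c}" for c in chromosomes}
        arms = [a for a in self._arms.values() if a.chrom in keep]
        loci = {n: l for n, l in self.loci.items() if l.chrom in keep}
        return GenomeModel(arms, loci, build=self.build)

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.chrom, a.start, a.end, a.name, int(a.acrocentric)) for a in self._arms.values()],
            columns=["chrom", "start", "end", "name", "acrocentric"],
        )

    def write_bed(self, path: str | Path) -> None:
        """Write arms as BED4+1 (name = e.g. ``7q``, score column = acrocentric flag)."""
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_arms_bed(path: str | Path, loci: Mapping[str, Locus] | None = None) -> GenomeModel:
    """Read a genome arm BED (chrom, start, end, name[, acrocentric])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: arm BED needs >=4 columns (chrom start end name)")
    arms = []
    for row in df.itertuples(index=False):
        name = str(row[3])
        arms.append(Arm(chrom=str(row[0]), arm=name[-1], start=int(row[1]), end=int(row[2]),
                        acrocentric=bool(int(row[4])) if df.shape[1] > 4 else False))
    return GenomeModel(arms, loci)


def load_default_genome() -> GenomeModel:
    """The packaged hg19 arm model with MYC and MYCN loci."""
    pkg = resources.files("mbrisk.data")
    arms_df = pd.read_csv(pkg / "hg19_arms.tsv", sep="\t")
    arms = [Arm(r.chrom, r.arm, int(r.start), int(r.end), bool(r.acrocentric))
            for r in arms_df.itertuples(index=False)]
    loci_df = pd.read_csv(pkg / "hg19_loci.tsv", sep="\t")
    loci = {r.name: Locus(r.name, r.chrom, int(r.start), int(r.end))
            for r in loci_df.itertuples(index=False)}
    return GenomeModel(arms, loci, build="hg19")
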