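"""Target regions for a candidate-gene panel.

Regions are held as named, 1-based, fully-closed intervals (the pileup/VCF
convention); BED input (0-based, half-open) is converted on read.  The panel
scale this package targets is small — a few kilobases of coding exons across
a handful of genes — so per-site enumeration of region positions is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["Region", "read_bed", "write_bed", "region_sites", "site_in_regions", "default_panel_regions"]

# the 15-gene obesity candidate panel; coordinates here are compact synthetic
# stand-ins (one toy "exon" window per gene), not the genes' true exons
_PANEL = [
    ("chr1", "NEGR1"),
    ("chr1", "NTRK2"),
    ("chr2", "TMEM18"),
    ("chr3", "PPARG"),
    ("chr3", "GHSR"),
    ("chr5", "PCSK1"),
    ("chr6", "SIM1"),
    ("chr7", "LEP"),
    ("chr8", "ADRB3"),
    ("chr11", "BDNF"),
    ("chr16", "FTO"),
    ("chr18", "MC4R"),
    ("chr20", "MC3R"),
    ("chr20", "PCSK2"),
    ("chr1b", "LEPR"),
]


@dataclass(frozen=True)
class Region:
    """A named 1-based closed interval on a contig."""

    contig: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    name: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"bad interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


def default_panel_regions(exon_bp: int = 40) -> list[Region]:
    """Toy one-exon-per-gene panel covering the 15 candidate genes."""
    regions = []
    for i, (contig, gene) in enumerate(_PANEL):
        start = 10_000 + i * 1_000
        regions.append(Region(contig, start, start + exon_bp - 1, gene))
    return regions


def read_bed(path) -> list[Region]:
    """Read BED (0-based half-open) into 1-based closed Regions."""
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["contig", "start", "end", "name"],
        dtype={"contig": str, "name": str},
    )
    return [
        Region(str(r.contig), int(r.start) + 1, int(r.end), str(r.name))
        for r in table.itertuples()
    ]


def write_bed(regions: Iterable[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def region_sites(regions: Iterable[Region]) -> Iterator[tuple[str, int, str]]:
    """Yield (contig, pos, region_name) for every targeted site, in order."""
    for r in regions:
        for pos in range(r.start, r.end + 1):
            yield r.contig, pos, r.name


def site_in_regions(regions: Iterable[Region], contig: str, pos: int) -> bool:
    return any(r.contains(contig, pos) for r in regions)
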