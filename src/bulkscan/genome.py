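"""Genome model and genetic map containers.

The default genome is the seven-chromosome cucumber (line 9930, assembly V2)
layout used throughout the package, with a 738 cM genetic map apportioned to
chromosomes in proportion to their physical length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physical chromosome lengths (bp) of the cucumber 9930 reference assembly V2.
CUCUMBER_CHROMOSOME_LENGTHS: dict[str, int] = {
    "chr1": 29_972_036,
    "chr2": 23_828_421,
    "chr3": 40_905_010,
    "chr4": 24_086_726,
    "chr5": 28_814_066,
    "chr6": 29_896_516,
    "chr7": 19_768_912,
}

#: Informative SLAF-marker counts per chromosome in the reference study design.
CUCUMBER_MARKERS_PER_CHROMOSOME: tuple[int, ...] = (360, 363, 563, 209, 249, 307, 208)

#: Total genetic map length (cM) of the SSR confirmation map.
CUCUMBER_MAP_LENGTH_CM: float = 738.0

MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cm"]


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome with a physical length (bp) and a map length (cM)."""

    id: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.id}: physical length must be > 0")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.id}: map length must be >= 0")


@dataclass
class GenomeModel:
    """An ordered collection of chromosomes with unique ids."""

    chromosomes: list[ChromosomeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")

    @classmethod
    def cucumber(cls, total_map_cm: float = CUCUMBER_MAP_LENGTH_CM) -> "GenomeModel":
        """The default 7-chromosome cucumber genome.

        Map length ``total_map_cm`` is split across chromosomes in proportion
        to their physical lengths (per-chromosome genetic lengths are not
        otherwise constrained).
        """
        total_bp = sum(CUCUMBER_CHROMOSOME_LENGTHS.values())
        chroms = [
            ChromosomeSpec(cid, length, total_map_cm * length / total_bp)
            for cid, length in CUCUMBER_CHROMOSOME_LENGTHS.items()
        ]
        return cls(chroms)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def total_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes)

    def __getitem__(self, cid: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class GeneticMap:
    """An ordered marker map with physical (bp) and genetic (cM) positions.

    ``df`` has columns ``marker_id, chrom, pos_bp, pos_cm``.  Within each
    chromosome both coordinates are strictly increasing; chromosome blocks
    are contiguous in map order, which is also the column order of any
    genotype matrix simulated from this map.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        if self.df["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        seen: set[str] = set()
        prev = None
        for chrom in self.df["chrom"]:
            if chrom != prev:
                if chrom in seen:
                    raise ValueError(f"chromosome {chrom} not contiguous in map")
                seen.add(chrom)
                prev = chrom
        for chrom, grp in self.df.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy()
            cm = grp["pos_cm"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {chrom}: pos_bp not strictly increasing")
            if np.any(np.diff(cm) <= 0):
                raise ValueError(f"chromosome {chrom}: pos_cm not strictly increasing")
            if np.any(cm < 0):
                raise ValueError(f"chromosome {chrom}: negative genetic position")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero((self.df["marker_id"] == marker_id).to_numpy())
        if idx.size == 0:
            raise KeyError(marker_id)
        return int(idx[0])

    def nearest_marker(self, chrom: str, pos_bp: int) -> int:
        """Index (map order) of the marker nearest ``pos_bp`` on ``chrom``."""
        mask = (self.df["chrom"] == chrom).to_numpy()
        if not mask.any():
            raise ValueError(f"chromosome {chrom} not in map")
        idx = np.flatnonzero(mask)
        bp = self.df["pos_bp"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(bp - pos_bp))])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))
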