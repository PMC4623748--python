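"""Simulation of a biparental F2 cross, extreme bulks, and pooled sequencing.

The simulator emulates a cucumber fruit-flesh-thickness mapping design: two
inbred parents (thick-fleshed D8, thin-fleshed XUE1), an F2 of 949
individuals, phenotype-extreme bulks of 50, and reduced-representation
pooled sequencing of parents and bulks at mean depths in the 15-50x range.

Phenotypes follow a single-QTL model

    y_i = mu + a * x_i + d * z_i + eps_i,   eps_i ~ Normal(0, residual_sd^2)

with x = genotype code - 1 in {-1, 0, +1} (count of D8 alleles minus one) and
z = 1 for heterozygotes.  The default parameterisation reproduces the
parental and F1 means of the study design: mu = 18.75, a = 5.45 mm
(homozygotes 24.2 / 13.3 mm) and d = 1.35 mm (heterozygotes 20.1 mm).
``residual_sd_for_r2`` solves the closed-form F2 variance decomposition
Var_g = a^2/2 + d^2/4 so that the QTL explains a chosen fraction of the
phenotypic variance (default target 0.4257).

Gametes are produced by a Markov walk along each chromosome: the
recombination probability of each marker interval is the inverse Kosambi
transform of its cM length, with no crossover interference beyond the map
function.  Pooled read counts are negative-binomial total depths with
binomial allele sampling at the bulk allele frequency, plus a symmetric
per-read error rate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    CUCUMBER_MARKERS_PER_CHROMOSOME,
    GeneticMap,
    GenomeModel,
    MAP_COLUMNS,
)
from .markers import MarkerTable, TABLE_COLUMNS
from .qtl import inverse_kosambi

_NUCLEOTIDES = np.array(list("ACGT"))

#: Variance explained by the default QTL in the confirmation scan (R^2).
DEFAULT_R2_TARGET = 0.4257


def genetic_variance(additive: float, dominance: float) -> float:
    """Variance contributed by one QTL in an F2 (1:2:1 segregation).

    With x in {-1, 0, +1} at frequencies 1/4, 1/2, 1/4 and z = [x == 0]:
    Var(a*x + d*z) = a^2/2 + d^2/4 (x and z are uncorrelated in an F2).
    """
    return additive**2 / 2.0 + dominance**2 / 4.0


def residual_sd_for_r2(additive: float, dominance: float, r2: float) -> float:
    """Residual SD such that the QTL explains fraction ``r2`` of F2 variance."""
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must be in (0, 1)")
    vg = genetic_variance(additive, dominance)
    return math.sqrt(vg * (1.0 - r2) / r2)


DEFAULT_RESIDUAL_SD = residual_sd_for_r2(5.45, 1.35, DEFAULT_R2_TARGET)


@dataclass(frozen=True)
class QTLSpec:
    """A single additive + dominance QTL acting on the phenotype (mm)."""

    chromosome: str = "chr2"
    position_bp: int = 4_500_000
    additive: float = 5.45
    dominance: float = 1.35
    grand_mean: float = 18.75
    residual_sd: float = DEFAULT_RESIDUAL_SD

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class DepthModel:
    """Per-sample sequencing depth model.

    Total depth per marker is negative binomial with the given mean and
    dispersion (``dispersion=None`` gives Poisson); ``error_rate`` is the
    probability a read reports the wrong allele.
    """

    mean_depth: float = 45.0
    dispersion: float | None = 8.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (or None for Poisson)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    def draw_depths(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.dispersion is None:
            return rng.poisson(self.mean_depth, size=size)
        k = self.dispersion
        return rng.negative_binomial(k, k / (k + self.mean_depth), size=size)


#: Parent sample depths follow the study's per-parent averages.
DEFAULT_D8_DEPTH = DepthModel(mean_depth=15.63)
DEFAULT_XUE1_DEPTH = DepthModel(mean_depth=24.56)


@dataclass
class F2Population:
    """Genotype codes (individuals x markers): 0 = XUE1/XUE1, 1 = het, 2 = D8/D8."""

    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[0] < 1:
            raise ValueError("genotypes must be a non-empty 2-D matrix")
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        self.genotypes = g.astype(np.int8)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def to_csv(self, path, gmap: GeneticMap | None = None) -> None:
        cols = gmap.df["marker_id"].tolist() if gmap is not None else None
        pd.DataFrame(self.genotypes, columns=cols).to_csv(path, index=False)


def simulate_genetic_map(
    genome: GenomeModel,
    n_markers_per_chr=None,
    seed: int | np.random.Generator | None = None,
    placement: str = "even",
) -> GeneticMap:
    """Place markers on each chromosome and assign genetic positions.

    Genetic positions are proportional to physical positions within a
    chromosome (uniform recombination rate).  ``placement='even'`` (default)
    spaces markers evenly from the first to the last base; ``'uniform'``
    draws sorted uniform positions instead.  ``n_markers_per_chr`` is a
    sequence aligned with ``genome.chromosomes`` and defaults to the study's
    per-chromosome informative-marker counts when the genome has seven
    chromosomes.
    """
    if n_markers_per_chr is None:
        if len(genome.chromosomes) != len(CUCUMBER_MARKERS_PER_CHROMOSOME):
            raise ValueError("n_markers_per_chr required for non-default genomes")
        n_markers_per_chr = CUCUMBER_MARKERS_PER_CHROMOSOME
    if len(n_markers_per_chr) != len(genome.chromosomes):
        raise ValueError("one marker count per chromosome required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    frames = []
    for chrom, k in zip(genome.chromosomes, n_markers_per_chr):
        k = int(k)
        if k < 2:
            raise ValueError(f"chromosome {chrom.id}: need at least 2 markers")
        if chrom.length_bp < k:
            raise ValueError(f"chromosome {chrom.id}: more markers than bases")
        if placement == "even":
            pos = np.unique(np.round(np.linspace(1, chrom.length_bp, k)).astype(np.int64))
        elif placement == "uniform":
            pos = np.sort(rng.choice(chrom.length_bp, size=k, replace=False) + 1)
        else:
            raise ValueError(f"unknown placement {placement!r}")
        if chrom.length_bp > 1:
            cm = (pos - 1) / (chrom.length_bp - 1) * chrom.length_cm
        else:
            raise ValueError(f"chromosome {chrom.id}: zero-length chromosome")
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom.id}_m{i + 1:04d}" for i in range(len(pos))],
                    "chrom": chrom.id,
                    "pos_bp": pos,
                    "pos_cm": cm,
                }
            )
        )
    return GeneticMap(pd.concat(frames, ignore_index=True)[MAP_COLUMNS])


def simulate_f2(
    gmap: GeneticMap,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> F2Population:
    """Simulate F2 genotypes by a Markov recombination walk along each chromosome."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    gmap.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    chunks = []
    for chrom in gmap.chromosomes:
        cm = gmap.chrom_view(chrom)["pos_cm"].to_numpy(dtype=float)
        m = cm.size
        r = inverse_kosambi(np.diff(cm)) if m > 1 else np.empty(0)
        gametes = np.empty((2 * n, m), dtype=np.int8)
        gametes[:, 0] = rng.integers(0, 2, size=2 * n)
        if m > 1:
            switches = rng.random((2 * n, m - 1)) < r
            flips = np.cumsum(switches, axis=1) % 2
            gametes[:, 1:] = gametes[:, [0]] ^ flips.astype(np.int8)
        chunks.append(gametes[:n] + gametes[n:])
    return F2Population(np.concatenate(chunks, axis=1))


def simulate_phenotype(
    pop: F2Population,
    qtl: QTLSpec,
    gmap: GeneticMap,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Phenotypes (mm) from the single-QTL model at the marker nearest the QTL."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    j = gmap.nearest_marker(qtl.chromosome, qtl.position_bp)
    code = pop.genotypes[:, j].astype(float)
    x = code - 1.0
    z = (code == 1.0).astype(float)
    y = qtl.grand_mean + qtl.additive * x + qtl.dominance * z
    if qtl.residual_sd > 0:
        y = y + rng.normal(0.0, qtl.residual_sd, size=pop.n)
    return y


def select_bulks(phenotypes, bulk_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the extreme-phenotype bulks (high, low).

    One stable ascending sort by (value, index): the low bulk is the first
    ``bulk_size`` entries (ties resolved to the lowest indices) and the high
    bulk the last ``bulk_size``, so the bulks are always disjoint.
    """
    y = np.asarray(phenotypes, dtype=float).ravel()
    if bulk_size <= 0:
        raise ValueError("bulk_size must be > 0")
    if 2 * bulk_size > y.size:
        raise ValueError("2 * bulk_size must not exceed the population size")
    order = np.lexsort((np.arange(y.size), y))
    low = np.sort(order[:bulk_size])
    high = np.sort(order[-bulk_size:])
    return high, low


def simulate_bulk_counts(
    pop: F2Population,
    high_indices,
    low_indices,
    gmap: GeneticMap,
    depth: DepthModel = DepthModel(),
    seed: int | np.random.Generator | None = None,
    d8_depth: DepthModel = DEFAULT_D8_DEPTH,
    xue1_depth: DepthModel = DEFAULT_XUE1_DEPTH,
) -> MarkerTable:
    """Pooled allele-depth table for parents and both bulks.

    For each marker the D8-allele frequency in a bulk is the mean genotype
    code over bulk members divided by two; read totals are drawn from the
    depth model and D8-allele reads are binomial at the error-perturbed
    frequency.  Parents are fixed opposite homozygotes with their own depth
    models.  The ``*_ref`` columns of the output count reads carrying the
    D8 allele, ``*_alt`` the XUE1 allele.
    """
    high = np.asarray(high_indices, dtype=int)
    low = np.asarray(low_indices, dtype=int)
    if high.size == 0 or low.size == 0:
        raise ValueError("bulks must be non-empty")
    if gmap.n_markers != pop.n_markers:
        raise ValueError("map and population marker counts differ")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = gmap.n_markers
    e = depth.error_rate

    def bulk_reads(members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = pop.genotypes[members].mean(axis=0) / 2.0
        total = depth.draw_depths(rng, m)
        ref = rng.binomial(total, p * (1.0 - e) + (1.0 - p) * e)
        return ref, total - ref

    high_ref, high_alt = bulk_reads(high)
    low_ref, low_alt = bulk_reads(low)

    d8_total = d8_depth.draw_depths(rng, m)
    d8_ref = rng.binomial(d8_total, 1.0 - d8_depth.error_rate)
    xue1_total = xue1_depth.draw_depths(rng, m)
    xue1_ref = rng.binomial(xue1_total, xue1_depth.error_rate)

    d8_idx = rng.integers(0, 4, size=m)
    allele_d8 = _NUCLEOTIDES[d8_idx]
    allele_xue1 = _NUCLEOTIDES[(d8_idx + rng.integers(1, 4, size=m)) % 4]

    df = pd.DataFrame(
        {
            "chrom": gmap.df["chrom"].to_numpy(),
            "pos": gmap.df["pos_bp"].to_numpy(),
            "allele_D8": allele_d8,
            "allele_XUE1": allele_xue1,
            "depth_D8_ref": d8_ref,
            "depth_D8_alt": d8_total - d8_ref,
            "depth_XUE1_ref": xue1_ref,
            "depth_XUE1_alt": xue1_total - xue1_ref,
            "high_bulk_ref": high_ref,
            "high_bulk_alt": high_alt,
            "low_bulk_ref": low_ref,
            "low_bulk_alt": low_alt,
        }
    )[TABLE_COLUMNS]
    return MarkerTable(df, provenance="simulate_bulk_counts")


@dataclass
class CrossSimulation:
    """Bundle of everything one simulated cross produces."""

    gmap: GeneticMap
    population: F2Population
    phenotypes: np.ndarray
    high_indices: np.ndarray
    low_indices: np.ndarray
    markers: MarkerTable
    qtl: QTLSpec


def simulate_cross(
    genome: GenomeModel | None = None,
    qtl: QTLSpec = QTLSpec(),
    n: int = 949,
    bulk_size: int = 50,
    n_markers_per_chr=None,
    depth: DepthModel = DepthModel(),
    seed: int | None = None,
    placement: str = "even",
) -> CrossSimulation:
    """End-to-end simulation: map, F2, phenotypes, bulks, pooled counts.

    Substreams for each stage are derived from one master seed, so a run is
    fully reproducible from ``seed`` alone.
    """
    genome = genome or GenomeModel.cucumber()
    ss = np.random.SeedSequence(seed).spawn(4)
    gmap = simulate_genetic_map(
        genome, n_markers_per_chr, seed=np.random.default_rng(ss[0]), placement=placement
    )
    pop = simulate_f2(gmap, n, seed=np.random.default_rng(ss[1]))
    phen = simulate_phenotype(pop, qtl, gmap, seed=np.random.default_rng(ss[2]))
    high, low = select_bulks(phen, bulk_size)
    markers = simulate_bulk_counts(
        pop, high, low, gmap, depth=depth, seed=np.random.default_rng(ss[3])
    )
    return CrossSimulation(gmap, pop, phen, high, low, markers, qtl)
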