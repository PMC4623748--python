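"""Bulked-segregant genome scan: SNP-index statistics, smoothing, peak calling.

Per-marker statistics
---------------------
With M = reads carrying the D8 (thick-flesh) parental allele and P = reads
carrying the XUE1 allele, the SNP-index of a bulk is M / (M + P).  The scan
statistic is

    Delta(SNP-index) = SNP_index(high bulk) - SNP_index(low bulk),

+1 when the high bulk carries only D8 alleles and the low bulk only XUE1
alleles, -1 in the opposite configuration, and 0 when the bulks match.  The
Euclidean-distance alternative is ED = sqrt(sum_alleles (f_high - f_low)^2),
which equals sqrt(2) * |f_high - f_low| for a biallelic site.

Smoothing and thresholding
--------------------------
Per-marker values are smoothed per chromosome by Loess (degree-1 locally
weighted regression with tricube weights); a sliding-window mean track is
kept as a separate reporting layer.  The genome-wide threshold is
median(fitted) + k * sd(fitted) over all chromosomes, and QTL peak regions
are maximal runs of markers whose Loess-fitted value strictly exceeds the
threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .markers import MarkerTable

#: Default multiplier on the genome-wide SD for the region threshold.
DEFAULT_K = 2.0


def snp_index(m_depth, p_depth, min_total_depth: int = 1):
    """Fraction of reads carrying the designated (D8) allele: M / (M + P).

    Returns NaN where the total depth is below ``min_total_depth``.
    Accepts scalars or arrays.
    """
    m = np.asarray(m_depth, dtype=float)
    p = np.asarray(p_depth, dtype=float)
    if np.any(m < 0) or np.any(p < 0):
        raise ValueError("read depths must be >= 0")
    total = m + p
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total >= min_total_depth, m / total, np.nan)
    return float(idx) if idx.ndim == 0 else idx


def delta_snp_index(index_aa, index_ab):
    """Difference of the high-bulk and low-bulk SNP-indices (NaN propagates)."""
    aa = np.asarray(index_aa, dtype=float)
    ab = np.asarray(index_ab, dtype=float)
    delta = aa - ab
    return float(delta) if delta.ndim == 0 else delta


def euclidean_distance(freq_high, freq_low):
    """ED between two allele-frequency vectors (each summing to 1)."""
    fh = np.asarray(freq_high, dtype=float)
    fl = np.asarray(freq_low, dtype=float)
    if fh.shape != fl.shape:
        raise ValueError("frequency vectors must have the same length")
    for name, f in (("freq_high", fh), ("freq_low", fl)):
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError(f"{name} must be non-negative and sum to 1")
    return float(np.sqrt(np.sum((fh - fl) ** 2)))


def compute_scan_table(table: MarkerTable, min_total_depth: int = 1) -> pd.DataFrame:
    """Per-marker SNP-indices, Delta(SNP-index) and ED from a marker table."""
    df = table.df
    idx_aa = snp_index(df["high_bulk_ref"], df["high_bulk_alt"], min_total_depth)
    idx_ab = snp_index(df["low_bulk_ref"], df["low_bulk_alt"], min_total_depth)
    delta = delta_snp_index(idx_aa, idx_ab)
    ed = np.sqrt(2.0) * np.abs(delta)  # biallelic closed form
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "snp_index_aa": idx_aa,
            "snp_index_ab": idx_ab,
            "delta": delta,
            "ed": ed,
        }
    )


def sliding_window(
    positions,
    values,
    window_bp: float = 1_000_000,
    step_bp: float = 10_000,
) -> pd.DataFrame:
    """Unweighted windowed means of a per-marker statistic on one chromosome.

    Windows are centred on a grid from the first to the last marker with
    spacing ``step_bp`` and width ``window_bp``; markers with missing values
    are ignored, and windows containing no (defined) marker yield NaN.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.size != val.size:
        raise ValueError("positions and values must have equal length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if pos.size == 0:
        return pd.DataFrame(columns=["center", "mean", "n_markers"])

    centers = np.arange(pos[0], pos[-1] + step_bp * 0.5, step_bp)
    finite = np.isfinite(val)
    cum_v = np.concatenate(([0.0], np.cumsum(np.where(finite, val, 0.0))))
    cum_n = np.concatenate(([0], np.cumsum(finite.astype(int))))
    left = np.searchsorted(pos, centers - window_bp / 2.0, side="left")
    right = np.searchsorted(pos, centers + window_bp / 2.0, side="right")
    n = cum_n[right] - cum_n[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (cum_v[right] - cum_v[left]) / n, np.nan)
    return pd.DataFrame({"center": centers, "mean": mean, "n_markers": n})


def loess_fit(positions, values, span: float = 0.3, chrom: str | None = None):
    """Loess (degree 1, tricube weights) fitted at the input positions.

    Markers with missing values are excluded from the fit and stay NaN in
    the output.  Requires at least 4 defined values.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    mask = np.isfinite(val) & np.isfinite(pos)
    if mask.sum() < 4:
        where = f" on chromosome {chrom}" if chrom else ""
        raise ValueError(f"need at least 4 defined values for loess{where}")
    fitted = np.full(pos.size, np.nan)
    fitted[mask] = lowess(
        val[mask], pos[mask], frac=span, it=0, return_sorted=False
    )
    return fitted


def compute_threshold(fitted, k: float = DEFAULT_K) -> float:
    """Genome-wide threshold: median + k * sample SD of the fitted values."""
    f = np.asarray(fitted, dtype=float)
    f = f[np.isfinite(f)]
    if f.size < 2:
        raise ValueError("need at least 2 defined fitted values")
    return float(np.median(f) + k * np.std(f, ddof=1))


@dataclass
class ScanProfile:
    """Smoothed genome-scan tracks and the genome-wide threshold.

    ``markers`` has per-marker columns (chrom, pos, value, fitted);
    ``windows`` the sliding-window track (chrom, center, mean, n_markers).
    """

    markers: pd.DataFrame
    windows: pd.DataFrame
    statistic: str
    span: float
    window_bp: float
    step_bp: float
    k: float
    genome_median: float
    genome_sd: float
    threshold: float


def compute_profile(
    scan_table: pd.DataFrame,
    statistic: str = "delta",
    span: float = 0.3,
    window_bp: float = 1_000_000,
    step_bp: float = 10_000,
    k: float = DEFAULT_K,
) -> ScanProfile:
    """Smooth a per-marker statistic per chromosome and set the threshold."""
    if statistic not in {"delta", "ed"}:
        raise ValueError("statistic must be 'delta' or 'ed'")
    marker_frames = []
    window_frames = []
    for chrom, grp in scan_table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        val = grp[statistic].to_numpy(dtype=float)
        fitted = loess_fit(pos, val, span=span, chrom=str(chrom))
        marker_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": grp["pos"].to_numpy(),
                          "value": val, "fitted": fitted})
        )
        win = sliding_window(pos, val, window_bp=window_bp, step_bp=step_bp)
        win.insert(0, "chrom", chrom)
        window_frames.append(win)
    markers = pd.concat(marker_frames, ignore_index=True)
    windows = pd.concat(window_frames, ignore_index=True)
    finite = markers["fitted"].to_numpy()
    finite = finite[np.isfinite(finite)]
    genome_median = float(np.median(finite))
    genome_sd = float(np.std(finite, ddof=1))
    return ScanProfile(
        markers=markers,
        windows=windows,
        statistic=statistic,
        span=span,
        window_bp=window_bp,
        step_bp=step_bp,
        k=k,
        genome_median=genome_median,
        genome_sd=genome_sd,
        threshold=genome_median + k * genome_sd,
    )


@dataclass
class QTLRegion:
    """A called peak interval (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    peak_value: float
    peak_pos: int
    n_markers: int

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak position must lie within the region")
        if self.n_markers < 1:
            raise ValueError("a region must contain at least one marker")

    @property
    def span_mb(self) -> float:
        return (self.end - self.start) / 1e6


def call_regions(profile: ScanProfile, table: MarkerTable | None = None) -> list[QTLRegion]:
    """Maximal runs of markers with Loess-fitted value strictly above threshold.

    Region bounds are the first and last marker positions of the run; the
    peak is the marker with the largest fitted value (first on ties).  When
    a filtered marker table is supplied, ``n_markers`` counts its markers
    within [start, end]; otherwise the run length is used.  Regions are
    returned ranked by descending peak value.
    """
    regions: list[QTLRegion] = []
    for chrom, grp in profile.markers.groupby("chrom", sort=False):
        fitted = grp["fitted"].to_numpy(dtype=float)
        pos = grp["pos"].to_numpy()
        above = np.where(np.isfinite(fitted), fitted > profile.threshold, False)
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            run_fit = fitted[i0:i1]
            j = int(np.nanargmax(run_fit))
            start, end = int(pos[i0]), int(pos[i1 - 1])
            if table is not None:
                sub = table.df
                n = int(((sub["chrom"] == chrom)
                         & (sub["pos"] >= start) & (sub["pos"] <= end)).sum())
            else:
                n = i1 - i0
            regions.append(
                QTLRegion(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    peak_value=float(run_fit[j]),
                    peak_pos=int(pos[i0 + j]),
                    n_markers=max(n, 1),
                )
            )
    regions.sort(key=lambda r: -r.peak_value)
    return regions


def regions_to_dataframe(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_value": r.peak_value,
                "peak_pos": r.peak_pos,
                "n_markers": r.n_markers,
                "span_mb": r.span_mb,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "peak_value", "peak_pos", "n_markers", "span_mb"],
    )


def regions_to_bed(regions: list[QTLRegion], path) -> None:
    """Write regions as BED (0-based half-open), score = peak fitted value."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t{r.peak_value:.6g}\n")


def genome_fraction_in_regions(regions: list[QTLRegion], genome_bp: int) -> float:
    """Fraction of the genome (bp) covered by called regions."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    covered = sum(r.end - r.start + 1 for r in regions)
    return covered / genome_bp


def plot_scan(profile: ScanProfile, regions: list[QTLRegion] | None = None, path=None):
    """Genome-scan figure: per-chromosome markers, Loess fit, threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(profile.markers["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(2.2 * len(chroms), 3.0), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        grp = profile.markers[profile.markers["chrom"] == chrom]
        ax.scatter(grp["pos"] / 1e6, grp["value"], s=3, alpha=0.35, color="grey")
        ax.plot(grp["pos"] / 1e6, grp["fitted"], color="black", lw=1.2)
        ax.axhline(profile.threshold, color="red", ls=":", lw=1)
        if regions:
            for r in regions:
                if r.chrom == chrom:
                    ax.axvspan(r.start / 1e6, r.end / 1e6, color="orange", alpha=0.25)
        ax.set_title(str(chrom), fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
    axes[0][0].set_ylabel(profile.statistic)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
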