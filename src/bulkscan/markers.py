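"""Marker allele-depth tables and informative-marker selection.

A marker table holds, per SNP locus, the two parental alleles and per-allele
read depths for the two parents (D8, XUE1) and the two phenotype-extreme
bulks.  The ``*_ref`` columns count reads supporting the D8 parental allele
and ``*_alt`` reads supporting the XUE1 allele; coordinates are 1-based
inclusive.

Informative markers for the bulked-segregant scan are those where each
parent is sequenced more than ``min_parent_depth``-fold, each parent is
effectively homozygous, and the two parents are fixed for different alleles.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TABLE_COLUMNS = [
    "chrom",
    "pos",
    "allele_D8",
    "allele_XUE1",
    "depth_D8_ref",
    "depth_D8_alt",
    "depth_XUE1_ref",
    "depth_XUE1_alt",
    "high_bulk_ref",
    "high_bulk_alt",
    "low_bulk_ref",
    "low_bulk_alt",
]

_DEPTH_COLUMNS = TABLE_COLUMNS[4:]
_VCF_SAMPLES = ["D8", "XUE1", "HIGH_BULK", "LOW_BULK"]
_ALLELE_RE = re.compile(r"^[ACGT]$")


@dataclass
class MarkerTable:
    """An ordered, duplicate-free table of marker allele depths."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        df = self.df[TABLE_COLUMNS].copy()
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in marker table")
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        for col in _DEPTH_COLUMNS:
            if (df[col] < 0).any():
                raise ValueError(f"negative depth in column {col}")
        for col in ("allele_D8", "allele_XUE1"):
            bad = ~df[col].astype(str).str.match(_ALLELE_RE)
            if bad.any():
                raise ValueError(f"non-ACGT or multi-base allele in column {col}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerTable) and self.df.equals(other.df)

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    def to_vcf(self, path) -> None:
        """Write as VCF 4.2 with per-sample AD; REF = D8 allele, ALT = XUE1."""
        df = self.df
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths (ref, alt)">\n')
            for chrom, grp in df.groupby("chrom", sort=False):
                fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(_VCF_SAMPLES) + "\n")
            pairs = [
                ("depth_D8_ref", "depth_D8_alt"),
                ("depth_XUE1_ref", "depth_XUE1_alt"),
                ("high_bulk_ref", "high_bulk_alt"),
                ("low_bulk_ref", "low_bulk_alt"),
            ]
            for row in df.itertuples(index=False):
                rec = dict(zip(df.columns, row))
                ads = "\t".join(f"{rec[a]},{rec[b]}" for a, b in pairs)
                fh.write(
                    f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['allele_D8']}\t"
                    f"{rec['allele_XUE1']}\t.\tPASS\t.\tAD\t{ads}\n"
                )


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # surface the offending line when pandas knows it
        raise ValueError(f"malformed marker table {path}: {exc}") from exc


def _read_vcf(path, on_multiallelic: str) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        missing = [s for s in _VCF_SAMPLES if s not in sample_names]
        if missing:
            raise ValueError(f"VCF lacks required samples: {missing}")
        for i, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                if on_multiallelic == "drop":
                    continue
                raise ValueError(
                    f"record {i} at {rec.chrom}:{rec.pos} is not biallelic"
                )
            depths = {}
            for sample, (ref_col, alt_col) in zip(
                _VCF_SAMPLES,
                [
                    ("depth_D8_ref", "depth_D8_alt"),
                    ("depth_XUE1_ref", "depth_XUE1_alt"),
                    ("high_bulk_ref", "high_bulk_alt"),
                    ("low_bulk_ref", "low_bulk_alt"),
                ],
            ):
                ad = rec.samples[sample].get("AD")
                if ad is None or len(ad) != 2:
                    raise ValueError(f"record {i}: sample {sample} lacks a 2-value AD")
                depths[ref_col], depths[alt_col] = int(ad[0]), int(ad[1])
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "allele_D8": rec.ref,
                    "allele_XUE1": rec.alts[0],
                    **depths,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_marker_table(
    path,
    format: str | None = None,
    on_multiallelic: str = "error",
) -> MarkerTable:
    """Read a marker table from TSV or VCF (records are sorted on load).

    ``format`` is inferred from the file suffix when omitted.
    ``on_multiallelic`` is ``'error'`` (default) or ``'drop'``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} else "tsv"
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "vcf":
        if on_multiallelic not in {"error", "drop"}:
            raise ValueError("on_multiallelic must be 'error' or 'drop'")
        df = _read_vcf(path, on_multiallelic)
    else:
        raise ValueError(f"unknown marker table format {format!r}")
    return MarkerTable(df, provenance=str(path))


def filter_informative(
    table: MarkerTable,
    min_parent_depth: int = 5,
    strict: bool = True,
    parent_het_tolerance: float = 0.1,
) -> MarkerTable:
    """Select markers informative for the bulked-segregant scan.

    A marker is retained when (i) each parent's total depth exceeds
    ``min_parent_depth`` (``strict=True`` means strictly greater, reading
    "more than N-fold" literally), (ii) each parent is effectively
    homozygous (minor-allele read fraction <= ``parent_het_tolerance``),
    and (iii) the parents' consensus alleles differ.  The operation is
    idempotent and preserves input order.
    """
    df = table.df
    d8_tot = df["depth_D8_ref"] + df["depth_D8_alt"]
    xue_tot = df["depth_XUE1_ref"] + df["depth_XUE1_alt"]
    if strict:
        depth_ok = (d8_tot > min_parent_depth) & (xue_tot > min_parent_depth)
    else:
        depth_ok = (d8_tot >= min_parent_depth) & (xue_tot >= min_parent_depth)

    with np.errstate(invalid="ignore", divide="ignore"):
        d8_minor = np.minimum(df["depth_D8_ref"], df["depth_D8_alt"]) / d8_tot
        xue_minor = np.minimum(df["depth_XUE1_ref"], df["depth_XUE1_alt"]) / xue_tot
    hom_ok = (
        (d8_tot > 0)
        & (xue_tot > 0)
        & (d8_minor <= parent_het_tolerance)
        & (xue_minor <= parent_het_tolerance)
    )

    # *_ref counts reads of the D8 allele for every sample, so a parent's
    # consensus is allele_D8 when its ref depth dominates, allele_XUE1 otherwise
    d8_major = np.where(df["depth_D8_ref"] >= df["depth_D8_alt"],
                        df["allele_D8"], df["allele_XUE1"])
    xue_major = np.where(df["depth_XUE1_ref"] >= df["depth_XUE1_alt"],
                         df["allele_D8"], df["allele_XUE1"])
    opposite = d8_major != xue_major

    keep = depth_ok & hom_ok & opposite
    note = (
        f"filter_informative(min_parent_depth={min_parent_depth}, strict={strict}, "
        f"parent_het_tolerance={parent_het_tolerance})"
    )
    prov = f"{table.provenance}; {note}" if table.provenance else note
    return MarkerTable(df[keep.to_numpy()].reset_index(drop=True), provenance=prov)


def polymorphism_rate(raw_count: int, polymorphic_count: int) -> float:
    """Percentage of raw loci that are polymorphic, rounded to 2 decimals."""
    if raw_count <= 0:
        raise ValueError("raw_count must be > 0")
    if polymorphic_count < 0 or polymorphic_count > raw_count:
        raise ValueError("polymorphic_count must be in [0, raw_count]")
    return round(100.0 * polymorphic_count / raw_count, 2)


def mean_depth(total_depth: int, n_loci: int) -> float:
    """Average per-locus depth (total depth / number of loci), 2 decimals."""
    if n_loci <= 0:
        raise ValueError("n_loci must be > 0")
    return round(total_depth / n_loci, 2)
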