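"""Candidate-gene qPCR analysis: ΔCt relative expression and fft correlation.

Relative expression follows the ΔCt method, RE = 2^-(Ct_target - Ct_reference),
with the reference an internal control gene (β-actin in the study design).
Replicates are averaged on the relative-expression scale.  Candidates are
ranked by the Pearson correlation between their mean relative expression and
the mean fruit-flesh-thickness (fft) trajectory, pooled over the
(line x timepoint) pairs of both parental lines; two-tailed p-values come
from the t transform with n - 2 degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "line", "timepoint", "replicate", "ct_target", "ct_reference"]


def relative_expression(ct_target, ct_reference):
    """ΔCt relative expression 2^-(Ct_target - Ct_reference)."""
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise ValueError("Ct values must be finite")
    re_ = np.power(2.0, -(ct_t - ct_r))
    return float(re_) if re_.ndim == 0 else re_


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one candidate gene with the fft trajectory."""

    gene: str
    pcc: float
    p_value: float
    n: int
    significant: bool


def pearson_correlation(x, y, alpha: float = 0.05, gene: str = "") -> CorrelationResult:
    """Product-moment correlation with a two-tailed t-test (n - 2 df)."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError("vectors must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in input vector")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(gene, float(r), float(p), xv.size, bool(p <= alpha))


def expression_profiles(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Mean relative expression per (gene, line, timepoint).

    Input columns: gene, line, timepoint, replicate, ct_target, ct_reference.
    Replicates are averaged after the 2^-ΔCt transform.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df = ct_table.copy()
    df["rel_expr"] = relative_expression(df["ct_target"], df["ct_reference"])
    prof = (
        df.groupby(["gene", "line", "timepoint"], sort=True)["rel_expr"]
        .mean()
        .reset_index()
    )
    return prof


def rank_candidates(
    profiles: pd.DataFrame,
    fft: pd.DataFrame,
    alpha: float = 0.05,
    pooled: bool = True,
) -> pd.DataFrame:
    """Rank genes by Pearson correlation of expression with mean fft.

    ``profiles`` has columns (gene, line, timepoint, rel_expr); ``fft`` has
    (line, timepoint, fft).  With ``pooled=True`` (default) the correlation
    uses the concatenated line x timepoint pairs; per-line coefficients are
    reported as extra columns either way.  A Bonferroni-adjusted flag across
    the genes tested is emitted for transparency; the primary ``significant``
    flag is the unadjusted two-tailed test at ``alpha``.
    """
    for col in ("gene", "line", "timepoint", "rel_expr"):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing column {col}")
    for col in ("line", "timepoint", "fft"):
        if col not in fft.columns:
            raise ValueError(f"fft table missing column {col}")

    expected = fft[["line", "timepoint"]].drop_duplicates()
    rows = []
    genes = list(dict.fromkeys(profiles["gene"]))
    for gene in genes:
        sub = profiles[profiles["gene"] == gene]
        merged = expected.merge(sub, on=["line", "timepoint"], how="left")
        absent = merged[merged["rel_expr"].isna()]
        if len(absent):
            pairs = ", ".join(
                f"{r.line}@{r.timepoint}" for r in absent.itertuples()
            )
            raise ValueError(f"gene {gene}: missing timepoints {pairs}")
        merged = merged.merge(fft, on=["line", "timepoint"])
        merged = merged.sort_values(["line", "timepoint"]).reset_index(drop=True)
        if pooled:
            res = pearson_correlation(merged["rel_expr"], merged["fft"],
                                      alpha=alpha, gene=gene)
        else:
            # mean of per-line coefficients is not meaningful for testing;
            # use the strongest line as the headline when not pooling
            per = [
                pearson_correlation(g["rel_expr"], g["fft"], alpha=alpha, gene=gene)
                for _, g in merged.groupby("line")
            ]
            res = max(per, key=lambda c: abs(c.pcc))
        row = {
            "gene": gene,
            "pcc": res.pcc,
            "p_value": res.p_value,
            "n": res.n,
            "significant": res.significant,
        }
        for line, g in merged.groupby("line"):
            row[f"pcc_{line}"] = pearson_correlation(
                g["rel_expr"], g["fft"], alpha=alpha, gene=gene
            ).pcc
        rows.append(row)
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_value"] * m, 1.0)
    out["significant_bonferroni"] = out["p_bonferroni"] <= alpha
    return out.sort_values("pcc", ascending=False).reset_index(drop=True)


# --------------------------------------------------------------------------
# synthetic qPCR experiment

#: fft trajectories (mm) over days after pollination; day-12 values match the
#: parental means of the study design (24.2 mm thick / 13.3 mm thin), with
#: growth levelling off after day 12.
DEFAULT_TIMEPOINTS = (0, 3, 6, 9, 12, 15)
DEFAULT_FFT_TRAJECTORIES = {
    "D8": (7.5, 12.0, 16.5, 20.5, 24.2, 24.4),
    "XUE1": (6.0, 8.5, 10.5, 12.2, 13.3, 13.4),
}


def default_fft_table() -> pd.DataFrame:
    rows = [
        {"line": line, "timepoint": t, "fft": v}
        for line, vals in DEFAULT_FFT_TRAJECTORIES.items()
        for t, v in zip(DEFAULT_TIMEPOINTS, vals)
    ]
    return pd.DataFrame(rows)


def simulate_expression_experiment(
    n_genes: int = 20,
    coupled_gene: int = 0,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.15,
    profile_sd: float = 0.8,
    fft: pd.DataFrame | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Simulate a Ct table for a candidate-gene screen.

    One gene (``coupled_gene``) has relative expression proportional to the
    fft trajectory (ΔCt = -log2(fft / 10)); the remaining genes receive
    fixed temporal ΔCt profiles residualised against the fft trajectory, so
    their true expression-fft correlation is exactly zero and any observed
    correlation reflects replicate noise alone.  Returns (ct_table,
    fft_table, coupled_gene_name).
    """
    if n_genes < 1 or not 0 <= coupled_gene < n_genes:
        raise ValueError("need n_genes >= 1 and a valid coupled gene index")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fft = default_fft_table() if fft is None else fft
    fft = fft.sort_values(["line", "timepoint"]).reset_index(drop=True)
    fft_vec = fft["fft"].to_numpy(dtype=float)
    npairs = fft_vec.size

    # basis for residualisation: intercept + fft
    X = np.column_stack([np.ones(npairs), fft_vec])
    proj = X @ np.linalg.pinv(X)

    names = [f"gene{i + 1:02d}" for i in range(n_genes)]
    rows = []
    for gi, name in enumerate(names):
        if gi == coupled_gene:
            dct = -np.log2(fft_vec / 10.0)
        else:
            raw = rng.normal(0.0, 1.0, size=npairs)
            resid = raw - proj @ raw
            sd = resid.std()
            pattern = resid / sd * profile_sd if sd > 0 else resid
            dct = rng.uniform(1.0, 6.0) + pattern
        for (line, timepoint), d in zip(
            fft[["line", "timepoint"]].itertuples(index=False), dct
        ):
            for rep in range(1, n_replicates + 1):
                ct_ref = 20.0 + rng.normal(0.0, 0.1)
                ct_tgt = ct_ref + d + rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "gene": name,
                        "line": line,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "ct_target": ct_tgt,
                        "ct_reference": ct_ref,
                    }
                )
    return pd.DataFrame(rows, columns=CT_COLUMNS), fft, names[coupled_gene]
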