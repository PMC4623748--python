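# Methods

`bulkscan` implements a bulked-segregant QTL-mapping analysis for an F2
cross between two inbred cucumber lines — a thick-fleshed parent (D8) and a
thin-fleshed parent (XUE1) — together with the simulator used to exercise
it. This note records the models, the defaults and why they were chosen,
and what the synthetic data does and does not emulate.

## The cross and phenotype model

The simulated trait is fruit flesh thickness (fft, mm). A single QTL with
additive effect *a* and dominance effect *d* acts on an F2 individual's
phenotype through the genotype code g ∈ {0, 1, 2} (count of D8 alleles) at
the marker nearest the QTL:

    y = μ + a·(g − 1) + d·[g = 1] + ε,   ε ~ N(0, σ²)

Defaults μ = 18.75 mm, a = 5.45 mm, d = 1.35 mm reproduce the design's
parental and F1 means: homozygotes 24.2 / 13.3 mm (a 10.9 mm difference)
and heterozygotes 20.1 mm. In an F2 segregating 1:2:1 the QTL variance is
Var_g = a²/2 + d²/4 (the additive score and the heterozygosity indicator
are uncorrelated), so the residual SD that makes the QTL explain a target
fraction R² of phenotypic variance is

    σ = sqrt(Var_g · (1 − R²) / R²)

`residual_sd_for_r2` implements this closed form; the default target is
R² = 0.4257, giving σ ≈ 4.54 mm. One consequence worth knowing: with this
σ the phenotype range of the top-50 bulk from an F2 of 949 reaches ~29–35
mm, wider than the handful of millimetres a real fft measurement spans
above the thick parent. Solving σ for the confirmation-scan R² and
reproducing a tightly bounded bulk phenotype range are not simultaneously
possible in a single-QTL Gaussian model; we prioritise the variance
decomposition, and tests check bulk ordering and separation rather than an
absolute range.

## Recombination and the genetic map

The default genome is the seven cucumber chromosomes (197.3 Mb total) with
a 738 cM map apportioned to chromosomes proportionally to physical length
(per-chromosome genetic lengths are not separately constrained). Within a
chromosome, marker genetic positions are proportional to physical
positions (uniform recombination rate), and markers are evenly spaced by
default (`placement="uniform"` draws random positions instead).

Gametes are generated by a first-order Markov walk: the allele at the
first marker is a fair coin, and each subsequent interval switches parental
origin with probability r = tanh(d/50)/2 — the inverse of the Kosambi map
function d = 25·ln((1+2r)/(1−2r)) (d in cM). No crossover interference is
modelled beyond what the map function implies for a single interval. Two
independent gametes form an individual.

## Pooled sequencing

Extreme bulks (default 50 of 949) are the phenotype tails, selected by one
stable ascending sort on (value, index): the low bulk takes the first
`bulk_size` entries, the high bulk the last, so ties are resolved
deterministically and the bulks are always disjoint.

Per marker and pool, total read depth is negative binomial with mean 45
(the average of the two pool depths in the emulated design, 48.86 and
40.34) and dispersion 8 — a moderate overdispersion typical of
reduced-representation libraries; only mean depths are constrained by the
design, so the distribution family is a modelling choice
(`dispersion=None` gives Poisson). Reads carrying the D8 allele are
binomial at the bulk's D8-allele frequency perturbed by a symmetric error
rate (default 0.001, consistent with ≥Q30 base quality). Parents are fixed
opposite homozygotes sequenced at their design depths (D8 15.63×, XUE1
24.56×; the table arithmetic total-depth ÷ locus-count pairs these values
with these samples, and we follow the arithmetic).

## Marker filtering

Informative markers require (i) each parent's total depth strictly greater
than 5 ("more than 5-fold" read as a strict inequality; both the cutoff
and strictness are configurable), (ii) each parent effectively homozygous
(minor-allele read fraction ≤ 0.1 — exactly zero is unrealistic under
sequencing error), and (iii) opposite parental consensus alleles.
Coordinates are 1-based inclusive throughout; multi-allelic VCF records
are rejected by default (the markers of interest are biallelic SNPs).

## The scan statistic, smoothing, and thresholding

With M = reads of the D8 allele and P = reads of the XUE1 allele, a pool's
SNP-index is M/(M+P) (undefined below a minimum total depth, default 1
read). The scan statistic is Δ(SNP-index) = index(high) − index(low);
+1/−1 at loci where the bulks are fixed for opposite parents and 0 where
they match. The Euclidean-distance alternative
ED = sqrt(Σ(f_high − f_low)²) = √2·|Δf| for biallelic loci is available
via `statistic="ed"`; Δ is the default because it is the statistic the
headline scan is presented in.

Per-marker values are smoothed per chromosome by Loess — degree-1 locally
weighted regression with tricube weights (statsmodels `lowess`, no
robustness iterations), span 0.3 by default. A 1 Mb / 10 kb sliding-window
mean track is computed as a separate reporting layer; the threshold and
region calls operate on the Loess fit. Window size, step and span are not
pinned down by the emulated design and are exposed as configuration.

The genome-wide threshold is median + k·SD of the fitted values pooled
over chromosomes (sample SD, n−1). The default is k = 2. The choice was
made analytically: the fitted curve's values are self-normalised by their
own median and SD, so for any roughly Gaussian marginal about 16% of the
genome exceeds median + 1·SD *under the null*, no matter how small the
noise — a 1-SD threshold cannot deliver a usefully small false-call
fraction. At k = 2 the null exceedance is ~2%, while a major QTL (whose
smoothed Δ approaches 0.8–0.9 against a null SD of ~0.05–0.2) remains far
above threshold. k is exposed for users who want the more permissive
convention.

Peak regions are maximal runs of markers whose fitted value strictly
exceeds the threshold; bounds are the first/last marker positions of the
run, the peak is the argmax of the fit, and the marker count is taken from
the filtered table within the bounds. Regions are ranked by peak value.
BED output converts the internal 1-based inclusive bounds to 0-based
half-open.

## Interval-mapping confirmation

The confirmation scan mirrors a classical SSR-based QTL analysis: an
independent F2 of 138 genotyped on a sparse ~100-marker, 738 cM map
(average interval 7.38 cM). Pairwise recombination fractions for map
building can be estimated by `estimate_r_f2`, an EM iteration over the
nine two-locus genotype classes in which only the phase-ambiguous double
heterozygote (0 or 2 recombinant gametes, posterior weight
r²/(r²+(1−r)²)) requires expectation steps. De novo linkage grouping is
out of scope; marker order comes from the map.

The genome scan is Haley–Knott regression: at each cM grid position
(default step 1 cM) the conditional distribution of the QTL genotype given
the flanking marker genotypes is computed by exact enumeration of the
two-gamete Markov chain (missing flanks are marginalised; both flanks
missing yields the 1:2:1 prior), and the phenotype is regressed on the
expected additive and dominance scores. LOD = (n/2)·log10(RSS0/RSS1),
capped at 300 for zero-residual fits; R² = 1 − RSS1/RSS0 at the peak. At a
fully observed marker the conditional distribution collapses to the
observed genotype, so the scan there equals single-marker regression —
the identity the oracle tests exploit. QTLs are declared where LOD ≥ 3.0.
Haley–Knott is an approximation to full-likelihood interval mapping; at
R² ≈ 0.43 and n = 138 the two are practically indistinguishable.

## Candidate-gene expression screen

Relative expression uses the ΔCt method, RE = 2^−(Ct_target − Ct_reference),
against an internal reference gene; replicates (default 3) are averaged on
the RE scale, not the Ct scale, since RE is the quantity correlated
downstream. Each gene's mean RE trajectory over 2 lines × 6 timepoints
(0–15 days after pollination) is correlated with the mean fft trajectory;
the default pools the 12 line×timepoint pairs into one Pearson
correlation (per-line coefficients are reported alongside), with a
two-tailed t-test at α = 0.05. No multiple-testing correction is applied
to the primary flag — matching the emulated screen — but a Bonferroni
column is emitted for transparency.

The synthetic screen gives one gene RE proportional to fft
(ΔCt = −log2(fft/10)) and assigns the other genes fixed temporal ΔCt
profiles that are residualised against the fft trajectory before noise is
added. This makes the null genes' true expression–fft correlation exactly
zero: their observed correlations reflect replicate noise (Ct SD 0.15
cycles against a ~0.8-cycle profile) and stay far from the n = 12 critical
value. Had null profiles been drawn as unconstrained random trajectories,
each would be "significant" 5% of the time by construction and a 20-gene
screen would rarely be clean — the orthogonalised null is what "expression
unrelated to the trait" means for a fixed trajectory measured with small
error. Passing the recovery test therefore demonstrates specificity
against measurement noise, not against biologically confounded expression
patterns.

## Pipeline and reproducibility

`run_pipeline` executes simulate → filter → scan → confirm → correlate
into one output directory, validating the configuration (e.g.
2·bulk_size ≤ n) before any stage runs. One master seed drives everything;
per-stage streams are derived by hashing the stage name into a
`SeedSequence` spawn key, so stages are independently reproducible and
insertion of a new stage does not shift the others. The manifest records
the config hash, per-stage output SHA-256 checksums and wall-clock times;
re-running with an unchanged config skips stages whose outputs still match
their recorded checksums. Identical config and seed give byte-identical
outputs regardless of the output directory.

## Problem sizes and limitations

The default scan experiment (2,259 markers, n = 949, bulks of 50) runs in
well under a second per replicate; the multi-seed recovery experiments in
the test suite use 20 replicates each. The confirmation scan uses the
design's n = 138 and a 100-marker map.

Known limitations: a single QTL with no epistasis or polygenic background;
no crossover interference beyond the Kosambi single-interval transform;
no simulation of raw reads, library artefacts, mapping bias or genotyping
error in the F2 matrix; depth overdispersion is a guess constrained only
by mean depths; the expression simulator's null is idealised as described
above. The Loess span / window / threshold-multiplier combination that a
particular historical analysis used is generally not recoverable from its
published summaries, so region coordinates from real data depend on those
settings and should be reported together with them.
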