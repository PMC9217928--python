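# Methods

This note documents the models, conventions and parameter choices behind
`loscreen`, and what its synthetic data can and cannot show.

## Overgrowth classification

A fetus is labelled LOS when its collection weight is **at or above** the
97th percentile of the AI control weights of the same sex and collection
day. Conventions:

- **Percentile**: Hyndman–Fan type 7 (`h = (n−1)q + 1` on the sorted
  controls, linear interpolation). The original analysis does not state its
  convention; type 7 is the default of the major statistical packages, and
  published thresholds that fall strictly between observed control values
  indicate that *some* interpolating estimator was used. We document the
  convention rather than claim it matches the original software.
- **Inclusive boundary**: a weight exactly at the threshold is LOS.
- **Days are never pooled**: thresholds are per collection day and per sex.
- AI fetuses are never LOS regardless of weight (the rule defines
  overgrowth relative to the conception method, not within controls).

The published-summary fixtures rebuild each day's cohort from the printed
subgroup sizes and weight ranges, spacing weights evenly within each range
(endpoints included). This is transparently synthetic: it conserves the
printed group compositions, range endpoints and classification counts
(9/43 at D56, 17/46 at D105) without claiming to reproduce unpublished
per-animal weights. One printed AI male count is accompanied by a note of
a missed observation in the source summaries; the fixture carries the full
8 weights, which does not affect any classification count.

## D55 ultrasound product index

`P = AD × AH × CRL × HL × TH × TD` (cm⁶). BPD is excluded because it shows
no correlation with collection weight. The screening threshold is the
maximum `P` among AI controls; flagging is **strictly greater** ("on or
below" the threshold is negative). A fixed threshold (100 cm⁶ by figure
convention) is exposed as an alternative. Correlation p-values use the
two-sided t reference `t = r√((n−2)/(1−r²))`; printed sources report only
bounds, so no exactness is claimed against them.

The exam fixtures assign products satisfying exactly the published
constraints — control maximum equal to the published threshold (79.92 cm⁶
at D105, 91.32 cm⁶ at D56), every non-extreme IVP product on or below it,
only the published extreme fetuses above it (and above the 100 line) — and
back-derive the six measurements from each product, so the stored table
reproduces the screening outcome exactly. Raw products were never
published; these exams are synthetic by construction.

## Sex-ratio test

Exact one-sided binomial tail in the female-deficiency direction,
`p = Σ_{k=0}^{n_f} C(n,k) (1/2)^n`, no normal approximation. The one-sided
choice follows the published AI value (p = 0.20, matching the exact
one-sided tail 794/4096 ≈ 0.194 for 4 females of 12, not the two-sided
0.388).

## Count-matrix analytics

**Size factors.** Median-of-ratios: `s_j = median_g(c_gj / geomean_g)`
over genes positive in every sample. Because the per-gene geometric-mean
reference contains every sample, only factor *ratios* are gauge-invariant:
scaling a sample by c multiplies its factor relative to every other sample
by exactly c (the absolute single-factor form of this identity is not
attainable by any estimator with an in-sample reference). TMM follows the
published trimmed-mean-of-M-values recipe — upper-quartile-closest-to-mean
reference, M and A over genes positive in both, 30%/5% double trimming,
inverse-variance weights, factors rescaled to geometric mean 1; M is
computed on library *proportions*, so pure depth scaling yields unit
factors (depth is carried separately by library size). Upper-quartile:
75th percentile (type 7) of positive counts, rescaled to geometric mean 1.

**Clustering.** UPGMA on euclidean distances between size-factor-normalized
sample profiles (no log transform by default; `log2(x+1)` is an option —
the original description says only that raw counts were normalized).
Ties are broken by the lexicographically smallest pair of cluster
representatives (smallest original leaf index), making the merge sequence
and the Newick export deterministic. Newick branch lengths are merge-height
differences, so root-to-tip distance equals the final merge height.

**Differential expression.** One NB-GLM engine
(`log μ_gj = x_jᵀβ_g + log(effective depth_j)`, variance `μ + φμ²`) fitted
by IRLS with fixed dispersion under nested designs;
`Λ = deviance_reduced − deviance_full`, p from χ² with df equal to the
difference in design ranks. Dispersions are gene-wise maxima of the
Cox–Reid adjusted profile likelihood
(`APL(φ) = ℓ(φ, β̂(φ)) − ½ log det(XᵀWX)`); the common (all-gene)
dispersion maximizes the *summed* APL over an evenly spaced subset of at
most 1000 genes (deterministic, so runs agree). The two backends mirror
the two mainstream frameworks as configurations, not reimplementations:

- **A** — upper-quartile depth step, TMM composition offsets on the
  depth-equalized counts, gene-wise dispersions shrunk toward the common
  value on the log scale with prior weight 10 residual-df equivalents;
- **B** — median-of-ratios offsets, unshrunk gene-wise dispersions.

Backend A is calibrated in the null simulations (type-I ≈ 0.05 at α = 0.05
over 2000 genes); backend B is mildly liberal (≈ 0.055–0.065), the known
behaviour of plug-in gene-wise dispersion at ~23 samples — one reason the
**consensus** (intersection of both backends' BH-significant sets at
adj-p ≤ 0.05) is the candidate list. All-zero genes get p = 1 and
log₂FC = 0 rather than being dropped, keeping gene universes aligned
across backends. The unwanted-variation factor analysis used upstream of
one original backend is *not* reimplemented; only its upper-quartile
between-lane step is kept (documented limitation).

**Reference genes** for qPCR must have backend-A adj-p ≥ 0.99 (the
practical reading of "FDR = 1"), backend-B adj-p > 0.8, and CV =
SD/mean ≤ 0.10 of normalized counts across all samples. The CV bound is
stringent by design: real leukocyte panels yield only a few qualifying
genes per ~10⁴ tested, and a 2000-gene synthetic panel may legitimately
yield none.

## ΔΔCT quantification

`ΔCT = CT_target − geomean(reference CTs)` — the geometric mean is taken
of the CT cycle values themselves (the literal protocol wording); the
alternative aggregation on the linear 2^(−CT) scale (equivalently the
arithmetic mean CT) is exposed as an option and differs by fractions of a
cycle at typical CTs. `ΔΔCT = ΔCT_sample − mean(ΔCT baseline)`;
`fold = 2^(−ΔΔCT)`. Because the baseline is an arithmetic mean on the ΔCT
(log₂) scale, the matching average of baseline folds — their geometric
mean — equals 1 exactly. Technical replicate CTs, when present, are
averaged arithmetically before any computation.

## Synthetic cohort generator

The generator emulates the study design: singleton AI pregnancies; two
embryos per IVP transfer, each implanting independently (p = 0.64, matching
the observed fetus yield); fetal sex Bernoulli(0.5); IVP females lost with
probability 0.30 between D56 and D105 (the observed female deficit);
weight lognormal per sex and day with (meanlog, sdlog) matched to the
printed AI control means and SDs; overgrowth as a two-component mixture —
with probability `pi_los = 0.30` an IVP fetus draws a lognormal multiplier
(meanlog 0.262, sdlog 0.18; mean ≈ 1.32) — the simplest model producing a
heavy right tail above a percentile threshold. Every linear biometric is
`base × (w₅₅/ref₅₅)^(1/3) × (1 + ε)`, ε ~ N(0, cv = 0.05): isometric
(allometric exponent 1/3) scaling, so the six-measurement product scales
as weight². At D55 the overgrowth multiplier enters attenuated (raised to
0.25), modelling the late divergence of LOS growth without committing to a
full biphasic growth curve the sources do not parameterize.

Counts are `NB(mean = libsize × q_g × exp(u_g,dam) × 2^(lfc_g·extreme),
dispersion φ_g)` with gene abundances from a log-normal profile, φ_g ~
Gamma(2, 0.05) (mean 0.1), library sizes uniform on [5·10⁵, 1.5·10⁶]
(reduced depth relative to production sequencing, chosen so the full suite
runs on one CPU in minutes), and a gene-wise animal effect shared by a
dam's two draw days — scale uniform on [0, 0.7] per gene (mean 0.35),
strong enough that samples cluster by animal, heterogeneous enough that a
subset of genes is cross-animal stable. A scalar per-dam effect would be
absorbed by depth normalization and could not reproduce the
clustering-by-animal structure. CT tables plant known fold differences
with gaussian cycle noise (sd 0.1).

All randomness derives from one seed through named substreams (cohort,
counts, CT), so enlarging the gene panel does not perturb the cohort.

**What passing tests do not show.** The generator draws genes
independently (no co-expression), uses a single overgrowth multiplier per
fetus (no organ-specific disproportion), ignores breed, parity and batch
effects, and its extreme-dam signature is planted rather than biological.
Calibration and recovery results on this data validate the *procedures* —
they do not certify performance on real cohorts. In particular, with one
animal per sample the extreme-dam contrast is fully confounded with the
animals' own expression profiles (in the real design as much as here), so
consensus lists contain animal-specific genes alongside any true
signature.

## Problem sizes and numerics

Null-calibration checks use 2000 genes × 23 samples; recovery checks use
1000 genes (16-fold planted signature) and 46 samples (dam pairing), sizes
at which the chi-square asymptotics and the clustering geometry are
already representative. IRLS converges on a relative deviance change of
1e−8 (cap 50 iterations, linear predictor clipped to ±30); dispersion
search is bounded to φ ∈ [1e−8, 10] on the log scale. Degenerate inputs
are conventions, not errors, where the analysis needs aligned universes
(all-zero genes: p = 1); they are errors where silence would corrupt
results (all-zero samples, missing references, non-nested designs,
mixed-day classification).
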