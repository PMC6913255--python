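# Methods

This note documents the models, estimators and design choices behind
condeseq, in the spirit of a statistical software methods appendix.

## Models

### Shared conventions

Every engine analyses one contrast (group B vs group A) through the same
design matrix: an intercept, the tested group indicator (1 for B), optional
pairing-block indicators (one dummy per subject beyond the first), and —
when RUV correction is on — the unwanted-variation covariates W. Fold
changes are reported as log2(B/A). Average expression (`AveExpr`) is the
mean log2-CPM over the contrast's samples computed with TMM effective
library sizes and a 0.5 pseudo-count, with one formula for all engines so
that the merged table averages commensurate quantities. Raw p-values are
adjusted by step-up Benjamini–Hochberg per engine over all tested genes;
significance ranks average ties. Genes with zero counts in every sample
get p = NA and logFC = 0 in all engines; NA propagates to the merged
table's `p_intersect` and sets the `na_flag` column rather than dropping
rows.

### NB-EB-LRT engine (edgeR-style)

Counts are modelled as NB(μ, φ) with Var = μ + φμ², log link and offsets
log(library size × TMM factor). Dispersion estimation uses the Cox–Reid
adjusted profile log-likelihood (APL): the common dispersion maximises the
summed APL over genes; tagwise dispersions maximise the weighted likelihood
APL_g + (prior df / residual df) · S_g, where S_g is the APL smoothed over
genes ordered by abundance with a moving average (window 10% of genes,
minimum 10). The prior df is 10. The abundance-ordered moving average was
chosen over a lowess smoother as the shared-likelihood curve: it is O(G),
exactly deterministic and has no fitting failure modes; the voom engine
keeps lowess because its published mean–variance trend specifies it. The
group coefficient is tested by the likelihood-ratio statistic against
χ²(1). GLM+LRT (rather than a two-group exact test) is used so that pairing
blocks and RUV covariates enter this engine exactly as they do the others.

### NB-Wald engine (DESeq2-style)

Median-of-ratios size factors (geometric-mean pseudo-reference over genes
positive in all samples) provide offsets log(s_j). Per-gene dispersion MLEs
maximise the APL on a 25-point log grid over [1e−7, 10] with parabolic
interpolation at the peak. A parametric trend φ(μ) = a₀ + a₁/μ is fitted
by iteratively reweighted Gamma regression (identity link) on genes with
informative MLEs, discarding genes whose dispersion-to-trend ratio leaves
[1e−4, 15] and refitting until stable; if no valid fit exists (e.g. both
coefficients cannot stay positive) the trend falls back to the median
gene-wise dispersion, with a warning. MAP dispersions maximise APL minus a
log-normal penalty centred on the trend with prior variance
max((1.4826·MAD of log residuals)² − trigamma(residual df / 2), 0.25).
The group coefficient is tested by a Wald statistic with standard errors
from the inverse observed information. Two defaults of the reference
family are deliberately disabled: outlier-based p-value masking and
independent filtering. Both would leave some genes without (comparable)
adjusted p-values, which breaks cross-engine ranking — the premise of the
consensus table.

### Precision-weights engine (voom/limma-style)

log2-CPM = log2((count + 0.5)/(effective library size + 1) · 10⁶) with TMM
effective library sizes. A first unweighted least-squares pass per gene
gives residual standard deviations; lowess (span 0.5) of sqrt(sd) against
mean log2-count forms the mean–variance trend, and each observation's
weight is the inverse fourth power of the trend value at its fitted
log2-count. Weighted least squares then yields coefficients and residual
variances s²_g, which are shrunk toward a scaled inverse-chi-square prior
fitted by moments (matching the mean and variance of log s²_g, with the
prior df solved by Newton inversion of the trigamma function). The
moderated t on residual + prior df tests the group coefficient. Forcing
the prior df to 0 recovers the ordinary weighted t; forcing it to ∞ pools
all genes to one prior variance — both limits are exposed for testing.
This engine requires at least 2 residual df.

### RUVr

Unwanted variation is estimated per contrast from the residuals of a
first-pass supervised NB GLM (group + pairing, TMM offsets, common
dispersion): deviance residuals are gene-centred and the first k
right-singular vectors of the centred matrix become the per-sample factor
columns of W (unit norm; sign fixed so each column's largest-magnitude
entry is positive, making the estimate fully deterministic). k defaults
to 1. The same W is appended to every engine's design, so the three
engines are always compared under identical correction. Deviance (not
Pearson) residuals follow the standard residual-based RUV description;
gene centring stops the mean trend from dominating the first factor.
W is estimated per contrast from that contrast's samples, matching the
per-pair analysis flow; whole-experiment estimation would also be
defensible but would entangle contrasts.

Identifiability caveat: a batch direction collinear with the group
indicator is absorbed by the supervised first pass and cannot be recovered
from residuals; RUVr corrects only the component of unwanted variation
orthogonal to the design. Correspondingly, a whole-transcriptome
multiplicative per-sample factor is indistinguishable from a library-size
change and is removed by normalisation, not by W.

## Normalisation

TMM: M-values trimmed 30% two-sided, A-values 5%, surviving M-values
averaged with inverse delta-method-variance weights; the reference sample
is the one whose upper-quartile count fraction is closest to the mean
(lowest index on ties); factors are rescaled to geometric mean 1.
Median-of-ratios: size factor = median over all-positive genes of
count / geometric mean. For CPM-scale quantities under median-of-ratios the
effective library size is size factor × geometric-mean library size, which
keeps values on a per-million scale. A single method ({tmm, median_ratio,
none}) can be forced across all engines in place of the per-engine
defaults.

## Simulator

Per-gene (mean, dispersion) pairs are estimated from a real count matrix by
method of moments on median-of-ratios-normalised counts:
φ̂ = max(0, (s² − μ̂)/μ̂²). Genes all-zero at source are excluded; genes
with positive variance but non-positive moment estimates (under-dispersion
is sampling noise) are floored to a lowess mean–dispersion trend, while
truly constant genes keep dispersion 0. A simulation draws `n_genes`
parameter pairs (without replacement when the pool suffices), plants
`n_de` DE genes (default 500 of 10,000; up/down split per `prop_up`,
rounding the up count toward up) with |log2FC| uniform on [0.585, 2.0]
(1.5×–4×; chosen to span subtle to strong regulation, configurable),
scales group-B means by 2^lfc, draws per-sample depths log-normal
(σ = 0.15) around the source depth, and samples counts NB(μ·depth/ref, φ)
— Poisson when φ = 0. Everything is deterministic given the seed; the
benchmark driver derives child seeds as base + sim index so individual
simulations are independently reproducible.

The bundled parameter set is synthetic: 12,000 genes generated from a
fixed internal seed with log-normal expressed-gene means (scaled to an 8M
read reference depth) and dispersions following φ = 0.02 + 2.5/μ with
log-normal scatter (σ = 0.6) — an asymptotic biological CV of ~0.14,
typical of genetically homogeneous model-organism replicates. It is
generated in code rather than shipped as a table (keeping the package pure
text) and verified against a frozen SHA-256 manifest. What it does *not*
emulate: real-data features such as correlated genes, zero inflation,
batch structure, or the exact mean–dispersion relationship of any
particular tissue. Benchmark statistics computed from it therefore
characterise the pipeline under clean NB sampling, not any specific real
dataset; with parameters re-estimated from a real matrix
(`estimate_nb_params`) the same driver benchmarks against that dataset's
characteristics. In particular, a clean NB simulation contains no
unwanted variation for RUVr to remove, so RUV's effect there is limited
to mild noise-soaking; its FDR benefit is most visible when structured
noise is present (see the batch-effect hook `apply_batch_effect`, which
scales a random gene subset — default 30% — by per-sample factors).

## Evaluation

Jaccard uses the asymmetric study convention: A is always the three-method
intersect, B the method (or union) under assessment — so JC reads as
closeness to the consensus core, not the symmetric textbook overlap.
Bland–Altman limits of agreement use the conventional 1.96 multiplier with
an n−1 standard deviation. FDR = 1 − PPV exactly wherever both are
defined; empty called sets yield NaN PPV/FDR (with a warning) and
sensitivity 0 against a non-empty truth. The benchmark driver reports
per-cell means over simulations, keeping all per-simulation values; for
signed quantities (bias) both signed and absolute means are exported.

## Numerical choices

- IRLS: at most 100 iterations, relative deviance tolerance 1e−8, linear
  predictor clipped to ±50, 1e−10 ridge on the normal equations.
  Non-convergent genes get p = NA and are logged.
- Dispersions are bounded in [1e−8, 10]; grid maxima are refined by a
  parabolic fit through the three neighbouring grid points.
- Rank ties are averaged; merged rows sort by rank_sum with gene-ID
  tie-break, so output order is fully deterministic.
- BH is computed per engine over all tested genes (no row filtering first).

## Known limitations

- The Wald engine's null p-value distribution deviates mildly from uniform
  in its body (a consequence of dispersion shrinkage shared by this model
  family generally), although its 0.05 rejection tail is well calibrated;
  the LRT and moderated-t engines pass distribution-level uniformity
  checks.
- Quasi-likelihood F-tests, logFC shrinkage estimators,
  duplicate-correlation random effects, and the negative-control-gene
  (RUVg) / technical-replicate (RUVs) correction variants are out of
  scope, as are BAM-level read counting and annotation retrieval
  (annotations are accepted only as a precomputed table).
- Unit-test simulations run at reduced scale (typically 1,500–2,000 genes
  with 5% DE) — the package's chosen problem sizes for routine checks —
  while the end-to-end acceptance tests and `scripts/acceptance.py` run the
  full 10,000-gene study (about ten minutes on one CPU).
- On clean NB simulations the RUV covariate has no structured unwanted
  variation to absorb; at three replicates per group it then costs a
  residual degree of freedom without a compensating benefit, so the
  intersect FDR with RUV is not systematically lower there. The FDR benefit
  of RUVr appears when identifiable (group-balanced) unwanted variation is
  present, as the batch-injection property test exercises.
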