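# Methods

## Data model

Observations live in a long table (genotype, environment, replicate,
trait, value) over twelve canonical traits; the registry fixes each
trait's units, layer (semolina/pasta) and polarity (PV: higher is better —
pigments and yellow indices; NV: lower is better — oxidative enzymes and
brown indices). All analyses except the ANOVA operate on the genotype ×
environment *cell means* (replicates averaged), flattened genotype-major
into an n = n_gen · n_env vector where a single sample is needed; in the
reference design n = 144.

## Variance decomposition

The two-way model with both factors random and r replicates per cell is
fitted by the closed-form balanced decomposition. For balanced data the
Type I/II/III sums of squares coincide, so this is exactly the "Type II"
analysis of the source study. Expected mean squares dictate the tests:
genotype and environment against the interaction mean square, interaction
against the residual; p-values are upper-tail F. Components are
method-of-moments:

    σ̂²_err = MS_err                σ̂²_GE = (MS_GE − MS_err)/r
    σ̂²_G  = (MS_G − MS_GE)/(rq)    σ̂²_E  = (MS_E − MS_GE)/(rp)

Negative estimates (possible whenever an F ratio is below 1) are truncated
to zero *before* percent shares are formed, so shares are non-negative and
sum to 100. How the original analysis handled negative components is not
stated; truncation is this package's documented choice, consistent with
the non-negative stacked shares it reports. A trait with zero total
variance has no defined shares and is rejected; its F ratios are reported
as NaN with p = 1.

## Association and processing effects

Correlations use the product-moment formula on the flattened cell-mean
vectors with the t transform t = r√((n−2)/(1−r²)) for two-sided p-values,
unadjusted for multiplicity (matching the source tables). Processing
effects compare semolina with pasta per genotype: percent decrease
100(S−P)/S for total carotenoids (lutein + β-carotene) and the yellow
index, percent increase 100(P−S)/S for the brown index. "Mean genotypic
values" is read as *average of the per-genotype percentages* (default),
which reproduces the published 16.0 / 8.2 summaries from the printed
genotype means; the grand-mean-ratio alternative (16.2 / 8.2) is exposed
via `mode="grand_mean"`. The published 86.7% carotenoid decrease
recomputes as ≈86.9% from the printed genotype means — the original may
have averaged at the G×E level, for which data were never printed — so
that quantity carries a documented ±0.5-point tolerance. Genotypes with a
zero semolina denominator are excluded from the summary and counted.

## Best-subset regression

The response (pasta YI) is regressed on every non-empty subset of the
eight semolina traits (exhaustive 2⁸−1 enumeration; subset SSE comes from
Gram-matrix solves, the reported fits from OLS). Mallow's criterion uses
the full-model residual variance:

    Cp = SSE_subset/σ̂²_full + 2(k+1) − n,  σ̂²_full = SSE_full/(n−p_full−1)

so the full model lands exactly at p_full + 1. Ties are broken by smaller
subset, then lexicographic codes. Reported diagnostics: standardized
β_j = B_j·sd(x_j)/sd(y); tolerance/VIF from the inverse predictor
correlation matrix (for two predictors, tolerance = 1 − r₁₂² exactly);
partial correlation t_j/√(t_j²+df); semi-partial t_j·√((1−R²)/df);
Durbin–Watson d = Σ(e_t−e_{t−1})²/Σe_t² on residuals in input row order.
No canonical ordering of G×E cells exists, so d depends on the
(documented, genotype-major) row order; the tabulated 5% bounds for
n = 144, k = 2 ship as the constant pair (1.468, 1.767) for reference.
Note a selection property of Cp: a pure-noise predictor joins the winning
subset whenever its partial F exceeds 2, so the minimum-Cp subset often
*contains* the generating predictors plus one spurious one; recovery is
therefore asserted as containment, not exact-set identity.

## PCA

Components are eigenvectors of the trait correlation matrix over genotype
means — invariant to units and to the sample/population SD convention,
which the source does not state. HP and BL are excluded by default (they
correlate with nothing else and were omitted from the published component
analysis); the exclusion is overridable. Scores are the (n−1)-standardized
data projected on loadings, so score covariance is diag(λ) and Σλ equals
the number of traits. Eigenvector signs follow a deterministic rule: the
largest-magnitude entry of each loading vector is made positive.

## High-Performance Index

Each trait's cell means are standardized against that trait's overall
mean and sample SD pooled over *all* cells — one stratum for both the
genotype-axis and the environment-axis analysis, the only reading under
which a single "overall mean of each variable" serves both. The score is
clamp(σz, −2, 2) with σ = +1 (PV) / −1 (NV): the simplest function that is
signed by polarity, monotone in the deviation, and capped at 2. The exact
deviation→score mapping of the original spreadsheet tool is described
only by those properties, and the underlying G×E data are unpublished, so
cell-by-cell reproduction of the printed SPI grid is not possible; the
implementation is validated by the stated properties (polarity
antisymmetry, shift invariance, bounds) and by row-sum consistency of the
printed grid. The mapping is injectable (`score_fn`) so step functions can
be swapped in. SPI sums scores over the opposite axis; HPI sums SPIs;
|HPI| ≤ 2·n_traits·n_contexts (192 for 12 traits × 8 environments). For
the environment axis an alternative `centering="within_genotype"` removes
genotype level before scoring; the overall-mean default matches the
published description. Exports round SPI to 2 decimals only at the CSV
boundary; internal aggregation keeps full precision. One caveat on the
printed grid: its cells are rounded to 2–3 decimals, so a printed row sum
can differ from the printed HPI by up to 13 × 0.005 = 0.065 (one row
differs by 0.025); the package checks the identity at that
printed-precision bound.

## Synthetic trials

The generator draws, per trait v, y(g,e,r,v) = μ_v + G + E + GE + ε with
each stratum multivariate normal across traits, covariance
D^{1/2} C D^{1/2}, where C is the published trait correlation matrix
(projected to PSD by eigenvalue clipping at 1e-8 with unit-diagonal
rescaling — the printed matrix happens to be PSD already, min eigenvalue
≈ 0.05) and D holds share × σ_v². Defaults: 18 × 8 × 3 design, published
overall means and SDs, and variance shares taken verbatim from the text
where stated (YI_S genotype 0.90; BCAR_P genotype 0.50, interaction 0.34;
HP environment 0.04; BCAR_S environment 0.21; BI_S/BI_P environment
0.68/0.70; LUT_P interaction 0.42; BL interaction 0.40) and read
approximately from the stacked-bar chart otherwise, with error shares
kept small ("completely marginal"). One C for all four strata: only one
correlation matrix (on cell means) was ever published, so per-stratum
structure is unidentifiable. Effects are normal by default; an optional
shifted-lognormal transform of the genotype stratum for the right-skewed
enzyme traits (HP, BL, POD, PPO) supports studying HPI clamp asymmetry
and is off by default. Negative simulated values are *not* truncated —
truncation would distort the variance partition the tests assert.

What the generator does not emulate: lattice field structure and spatial
trends, year effects, unbalanced or missing cells, measurement rounding,
and any genotype-specific environmental sensitivity beyond the normal
interaction stratum. Passing tests therefore certify the estimators on
data satisfying the stated model, not robustness to real-field artefacts.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 trials at the reference design (variance-share
recovery within ±5 points; best-subset recovery at n = 144 with noise SD
0.5), 2000 batched simulations for the null F rejection rate (±0.02 of
the nominal 0.05), and 500 draws for the white-noise Durbin–Watson mean
(2 ± 0.05) — sizes at which the asserted tolerances have comfortable
Monte-Carlo margins. Degenerate inputs fail loudly and by name: empty
cells, unbalanced tables, single replicates, zero-variance traits,
rank-deficient designs, all-zero residuals. Rank order everywhere breaks
ties deterministically (smaller subset then lexicographic for Cp;
alphabetical for equal HPI).
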