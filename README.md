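# durumcolor

Genotype-by-environment analysis of colour-related traits in durum wheat
semolina and pasta, for breeders and cereal scientists who need to decide
which semolina traits to select on when the goal is bright yellow pasta.

The package re-implements, as a tested pipeline, the statistical toolkit of
a multi-environment durum wheat trial (18 genotypes x 8 environments x 3
replicates, 12 traits: lipoxygenase hydroperoxidation HP and bleaching BL
activities, peroxidase POD, polyphenoloxidase PPO, lutein and β-carotene,
and the CIELAB yellow index YI = b\* and brown index BI = 100 − L\*, each
in semolina `_S` and pasta `_P`):

- **G×E variance decomposition** — balanced two-way ANOVA with both factors
  random, F against the interaction mean square (df (p−1,(p−1)(q−1)) etc.),
  and method-of-moments variance components
  σ̂²_err = MS_err, σ̂²_GE = (MS_GE − MS_err)/r, σ̂²_G = (MS_G − MS_GE)/(rq),
  σ̂²_E = (MS_E − MS_GE)/(rp), reported as percent shares.
- **Trait association** — Pearson r with p-values over the 144 flattened
  G×E cell means, and semolina→pasta processing effects (percent change in
  total carotenoids, YI, BI per genotype).
- **Best-subset regression** — exhaustive OLS subsets of the 8 semolina
  traits predicting pasta yellowness, ranked by Mallow's
  Cp = SSE/σ̂²_full + 2(k+1) − n, with standardized β, tolerance/VIF,
  partial and semi-partial correlations, and the Durbin–Watson d.
- **PCA** — correlation-matrix PCA of genotype-mean profiles (biplot data).
- **High-Performance Index (HPI)** — polarity-constrained scoring
  clamp(±z, −2, 2) of every standardized cell, summed over contexts into
  per-trait Specific Performance Indices (SPI) and totalled into one HPI
  per genotype or environment, bounded by 2 × n_traits × n_contexts.

The raw replicate data of the original trial were never deposited. The
package therefore ships (a) the printed summary tables (means ± SD,
correlations, environment SPI grid) as fixtures, and (b) a synthetic trial
generator whose defaults reproduce the published design sizes, trait
means/SDs, variance partitions and cross-trait correlations, so every
stage is testable end to end.

## Worked example

Recompute the headline quantities derivable from the packaged tables:

```bash
durumcolor reproduce --out-dir out
```

prints (abridged):

```text
quantity,value
beta_BI_S,-0.10874200426439236
beta_YI_S,0.9658848614072495
tolerance_two_predictor,0.8911
carotenoid_decrease_pct,86.94407954553475
yellow_index_decrease_pct,15.966595705415784
brown_index_increase_pct,8.191440045089758
pc1_percent,55.02776481113359
pc2_percent,27.554499791072026
hpi_bound_12x8,192.0
```

Reading: in the two-predictor model for pasta yellowness, semolina YI
dominates (β ≈ 0.97) while semolina BI contributes a small negative
correction (β ≈ −0.11) with mild collinearity (tolerance 0.891) — semolina
yellowness is a fast, reliable selection proxy for pasta colour. Pasta
making destroys ~87% of carotenoids and 16% of the yellow index while
browning rises ~8%. The first two principal components carry ~83% of the
between-genotype trait variability. The HPI of a genotype over 12 traits
and 8 environments is bounded by ±192.

A full synthetic run:

```bash
durumcolor pipeline --seed 42 --out-dir run42
```

simulates a balanced 18×8×3 trial under the published variance partitions
and writes the ANOVA/variance-component table, correlation matrices,
processing effects, Cp-ranked regression subsets, PCA exports and
genotype/environment HPI scorecards, plus a `manifest.json` with SHA-256
hashes (same seed → byte-identical outputs).

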