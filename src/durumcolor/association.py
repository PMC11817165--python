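"""Trait association on G x E cell means and semolina-to-pasta processing effects.

The correlation stage flattens each trait's genotype x environment
cell-mean grid (genotype-major) into one n-vector — n = 144 in the
published design — and computes the product-moment correlation for every
trait pair with the two-sided p-value from the t transform
``t = r sqrt((n-2) / (1 - r^2))``. p-values are reported unadjusted, as in
the source analysis.

The processing stage quantifies what pasta making does to the three
colour quantities, per genotype: total carotenoids (lutein + beta-carotene)
and the yellow index decrease, the brown index increases. Decreases are
``100 (semolina - pasta) / semolina`` and the brown-index increase is
``100 (pasta - semolina) / semolina``, so all three are positive under the
expected direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .trait_model import CellMeanMatrix

__all__ = ["CorrelationResult", "ProcessingEffect", "pearson_matrix", "processing_effects"]


@dataclass
class CorrelationResult:
    """Symmetric r and p matrices over traits, with the common sample size."""

    r: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)
    n: int
    degenerate: tuple[str, ...] = ()


def pearson_matrix(cell_means: dict[str, CellMeanMatrix]) -> CorrelationResult:
    """Pearson correlations among traits over flattened cell means.

    All traits must share the same (genotype, environment) grid with
    n >= 3 cells. A zero-variance trait gets NaN correlations against every
    other trait and is listed in ``degenerate``.
    """
    codes = list(cell_means)
    grids = [cell_means[c].values for c in codes]
    ref = grids[0]
    for c, g in zip(codes, grids):
        if not (g.index.equals(ref.index) and g.columns.equals(ref.columns)):
            raise ValueError(f"trait {c} is on a different genotype x environment grid")
    n = ref.size
    if n < 3:
        raise ValueError(f"need at least 3 cells, got {n}")
    X = np.column_stack([cell_means[c].flatten() for c in codes])
    sd = X.std(axis=0, ddof=1)
    degenerate = tuple(c for c, s in zip(codes, sd) if s == 0.0)

    k = len(codes)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    for i, j in combinations(range(k), 2):
        if sd[i] == 0.0 or sd[j] == 0.0:
            continue
        rij = float(np.clip(corr[i, j], -1.0, 1.0))
        if abs(rij) == 1.0:
            pij = 0.0
        else:
            t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
            pij = float(2.0 * stats.t.sf(abs(t), n - 2))
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    for c in degenerate:
        i = codes.index(c)
        r[i, i] = np.nan
        p[i, i] = np.nan
    return CorrelationResult(
        r=pd.DataFrame(r, index=codes, columns=codes),
        p=pd.DataFrame(p, index=codes, columns=codes),
        n=n,
        degenerate=degenerate,
    )


@dataclass
class ProcessingEffect:
    """Per-genotype percent changes after pasta processing, plus summaries.

    ``per_genotype`` has columns carotenoids, yellow_index, brown_index
    (percent decrease, decrease, increase respectively); ``mean`` holds the
    across-genotype summary; ``n_excluded`` counts genotypes dropped for a
    zero semolina denominator.
    """

    per_genotype: pd.DataFrame = field(repr=False)
    mean: pd.Series = field(repr=False)
    mode: str = "per_genotype"
    n_excluded: int = 0


def processing_effects(
    genotype_means: pd.DataFrame, mode: str = "per_genotype"
) -> ProcessingEffect:
    """Percent change of colour quantities from semolina to pasta.

    ``genotype_means`` is a genotype x trait matrix holding at least
    LUT_S, BCAR_S, YI_S, BI_S, LUT_P, BCAR_P, YI_P, BI_P.

    mode="per_genotype" (default) computes the percent change genotype by
    genotype and averages the percentages — the reading that reproduces the
    published summary figures. mode="grand_mean" takes the ratio of
    across-genotype mean values instead; both are scale-invariant per trait.
    """
    needed = ["LUT_S", "BCAR_S", "YI_S", "BI_S", "LUT_P", "BCAR_P", "YI_P", "BI_P"]
    missing = [t for t in needed if t not in genotype_means.columns]
    if missing:
        raise ValueError(f"missing traits: {missing}")
    gm = genotype_means
    num = pd.DataFrame(
        {
            "carotenoids": (gm["LUT_S"] + gm["BCAR_S"]) - (gm["LUT_P"] + gm["BCAR_P"]),
            "yellow_index": gm["YI_S"] - gm["YI_P"],
            "brown_index": gm["BI_P"] - gm["BI_S"],
        }
    )
    den = pd.DataFrame(
        {
            "carotenoids": gm["LUT_S"] + gm["BCAR_S"],
            "yellow_index": gm["YI_S"],
            "brown_index": gm["BI_S"],
        }
    )
    if mode == "per_genotype":
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * num / den.where(den != 0.0)
        n_excluded = int(pct.isna().any(axis=1).sum())
        mean = pct.mean(axis=0, skipna=True)
    elif mode == "grand_mean":
        dmean = den.mean(axis=0)
        if (dmean == 0.0).any():
            raise ValueError("zero grand-mean semolina denominator")
        pct = 100.0 * num / den.where(den != 0.0)
        n_excluded = int(pct.isna().any(axis=1).sum())
        mean = 100.0 * num.mean(axis=0) / dmean
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ProcessingEffect(per_genotype=pct, mean=mean, mode=mode, n_excluded=n_excluded)
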