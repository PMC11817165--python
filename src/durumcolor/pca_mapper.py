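"""Correlation-matrix PCA of genotype-mean trait profiles.

Principal components are the eigenvectors of the trait correlation matrix
computed over genotype means, so the analysis is invariant to trait units
and to the sample-vs-population SD convention. By default the two
lipoxygenase activities (HP, BL) are excluded: they correlate with no
other trait and were left out of the published component analysis.

Scores are the standardized data projected on the loadings; with the
(n - 1) standardization used here the score covariance is diagonal with
the eigenvalues on the diagonal, and the eigenvalues sum to the number of
traits. Eigenvector signs are arbitrary, so each loading vector is flipped
to make its largest-magnitude entry positive — a deterministic convention
that keeps biplot exports reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca_correlation", "DEFAULT_EXCLUDED"]

DEFAULT_EXCLUDED = ("HP", "BL")


@dataclass
class PCAResult:
    """Eigenvalues (descending), percent variance, loadings and scores."""

    eigenvalues: np.ndarray
    percent: np.ndarray
    loadings: pd.DataFrame = field(repr=False)  # trait x component
    scores: pd.DataFrame = field(repr=False)    # genotype x component


def pca_correlation(
    genotype_means: pd.DataFrame,
    traits: Sequence[str] | None = None,
    exclude: Sequence[str] = DEFAULT_EXCLUDED,
) -> PCAResult:
    """PCA of the trait correlation matrix over genotype means.

    ``traits`` selects columns explicitly; otherwise all columns except
    ``exclude`` are used. Requires at least 2 genotypes and 2 traits; a
    zero-variance trait is rejected by name.
    """
    if traits is None:
        traits = [c for c in genotype_means.columns if c not in set(exclude)]
    traits = list(traits)
    M = genotype_means.loc[:, traits]
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 genotypes and 2 traits")
    X = M.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    for code, s in zip(traits, sd):
        if s == 0.0:
            raise ValueError(f"zero-variance trait: {code}")
    Z = (X - X.mean(axis=0)) / sd
    C = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # sign convention: largest-|entry| of each loading vector positive
    flips = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flips[flips == 0] = 1.0
    V = V * flips
    pcs = [f"PC{i + 1}" for i in range(len(w))]
    scores = Z @ V
    return PCAResult(
        eigenvalues=w,
        percent=100.0 * w / w.sum(),
        loadings=pd.DataFrame(V, index=traits, columns=pcs),
        scores=pd.DataFrame(scores, index=M.index, columns=pcs),
    )
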