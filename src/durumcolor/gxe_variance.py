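"""Balanced two-way random-effects ANOVA and variance components.

For a balanced trial with p genotypes, q environments and r >= 2
replicates, both factors random, the sums of squares follow the standard
balanced decomposition (for balanced data Type I, II and III sums of
squares coincide, so the closed form below is exactly the Type II analysis
applied in the original study). The expected mean squares of the
all-random model dictate the F denominators: genotype and environment are
tested against the interaction mean square — giving the df pairs
(p-1, (p-1)(q-1)) and (q-1, (p-1)(q-1)) — and the interaction against the
residual, df ((p-1)(q-1), pq(r-1)).

Variance components are method-of-moments estimates from the same EMS::

    sigma2_err = MS_err
    sigma2_GE  = (MS_GE - MS_err) / r
    sigma2_G   = (MS_G - MS_GE) / (r q)
    sigma2_E   = (MS_E - MS_GE) / (r p)

Negative estimates are truncated to zero before percent shares are formed,
so the reported shares are non-negative and sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trait_model import TraitTable, cell_means

__all__ = [
    "VarianceDecomposition",
    "balanced_ss",
    "anova_two_way_random",
    "variance_components",
    "anova_all_traits",
]

SOURCES = ("genotype", "environment", "interaction", "error")


@dataclass
class VarianceDecomposition:
    """ANOVA table plus variance components for one trait.

    Per source: SS, df, MS, F, p; after :func:`variance_components` also the
    sigma^2 estimate and its percent share of total variance.
    """

    trait: str
    p: int
    q: int
    r: int
    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    sigma2: dict[str, float] = field(default_factory=dict)
    percent: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in SOURCES:
            rows.append(
                {
                    "source": s,
                    "SS": self.ss[s],
                    "df": self.df[s],
                    "MS": self.ms[s],
                    "F": self.f.get(s, np.nan),
                    "p": self.p_value.get(s, np.nan),
                    "sigma2": self.sigma2.get(s, np.nan),
                    "percent": self.percent.get(s, np.nan),
                }
            )
        out = pd.DataFrame(rows)
        out.insert(0, "trait", self.trait)
        return out


def balanced_ss(values: np.ndarray) -> tuple[np.ndarray, ...]:
    """Sums of squares of the balanced two-way layout with replication.

    ``values`` has shape (..., p, q, r); leading axes are treated as
    independent batches (used by the Monte-Carlo tests). Returns
    (SS_G, SS_E, SS_GE, SS_err), each of shape (...).
    """
    values = np.asarray(values, dtype=float)
    p, q, r = values.shape[-3:]
    cell = values.mean(axis=-1)               # (..., p, q)
    g = cell.mean(axis=-1)                    # (..., p)
    e = cell.mean(axis=-2)                    # (..., q)
    grand = g.mean(axis=-1)                   # (...)
    ss_g = q * r * ((g - grand[..., None]) ** 2).sum(axis=-1)
    ss_e = p * r * ((e - grand[..., None]) ** 2).sum(axis=-1)
    inter = cell - g[..., :, None] - e[..., None, :] + grand[..., None, None]
    ss_ge = r * (inter**2).sum(axis=(-2, -1))
    ss_err = ((values - cell[..., None]) ** 2).sum(axis=(-3, -2, -1))
    return ss_g, ss_e, ss_ge, ss_err


def _table_to_array(table: TraitTable, trait: str) -> np.ndarray:
    sub = table.data[table.data["trait"] == trait]
    cube = sub.pivot_table(
        index="genotype", columns=["environment", "replicate"], values="value"
    ).sort_index(axis=0).sort_index(axis=1)
    if cube.isna().any().any():
        raise ValueError(f"trait {trait}: unbalanced or missing cells")
    p = cube.shape[0]
    q = sub["environment"].nunique()
    r = cube.shape[1] // q
    return cube.to_numpy().reshape(p, q, r)


def anova_two_way_random(table: TraitTable, trait: str) -> VarianceDecomposition:
    """Fit the all-random two-way ANOVA for one trait of a balanced table.

    Requires r >= 2 replicates (with a single replicate the interaction and
    error strata are confounded). A trait with zero spread yields SS = 0
    everywhere; its F ratios are reported as NaN with p = 1.
    """
    values = _table_to_array(table, trait)
    p, q, r = values.shape
    if r < 2:
        raise ValueError(
            "r = 1: interaction and error are not separable; need >= 2 replicates"
        )
    ss_g, ss_e, ss_ge, ss_err = (float(x) for x in balanced_ss(values))
    df = {
        "genotype": p - 1,
        "environment": q - 1,
        "interaction": (p - 1) * (q - 1),
        "error": p * q * (r - 1),
    }
    ss = {"genotype": ss_g, "environment": ss_e, "interaction": ss_ge, "error": ss_err}
    ms = {s: ss[s] / df[s] for s in SOURCES}

    def f_test(num: str, den: str) -> tuple[float, float]:
        if ms[den] == 0.0:
            return float("nan"), 1.0
        f = ms[num] / ms[den]
        return f, float(stats.f.sf(f, df[num], df[den]))

    vd = VarianceDecomposition(trait=trait, p=p, q=q, r=r, ss=ss, df=df, ms=ms)
    for src, den in (
        ("genotype", "interaction"),
        ("environment", "interaction"),
        ("interaction", "error"),
    ):
        vd.f[src], vd.p_value[src] = f_test(src, den)
    return vd


def variance_components(vd: VarianceDecomposition) -> VarianceDecomposition:
    """Add method-of-moments variance components and percent shares."""
    p, q, r = vd.p, vd.q, vd.r
    ms = vd.ms
    raw = {
        "error": ms["error"],
        "interaction": (ms["interaction"] - ms["error"]) / r,
        "genotype": (ms["genotype"] - ms["interaction"]) / (r * q),
        "environment": (ms["environment"] - ms["interaction"]) / (r * p),
    }
    vd.sigma2 = {s: max(raw[s], 0.0) for s in SOURCES}
    total = sum(vd.sigma2.values())
    if total == 0.0:
        raise ValueError(f"trait {vd.trait}: total variance is zero, shares undefined")
    vd.percent = {s: 100.0 * vd.sigma2[s] / total for s in SOURCES}
    return vd


def anova_all_traits(table: TraitTable) -> pd.DataFrame:
    """Tidy decomposition (ANOVA + components) for every trait present."""
    frames = []
    for trait in table.traits:
        vd = variance_components(anova_two_way_random(table, trait))
        frames.append(vd.to_frame())
    return pd.concat(frames, ignore_index=True)
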