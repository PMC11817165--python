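"""Packaged summary tables from the multi-environment durum wheat trial.

The raw replicate-level data of the 18-genotype x 8-environment trial were
never deposited; the printed summary tables are the only real-data surface
and ship with the package as small CSVs:

* genotype means and SDs of the 12 traits (n = 24 per mean),
* environment means and SDs (n = 54 per mean),
* overall means and SDs,
* the Pearson correlation matrix of the 144 G x E cell means with p-values,
* the environment-axis Specific Performance Index grid with its HPI column.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .trait_model import TRAIT_CODES

__all__ = [
    "genotype_means",
    "environment_means",
    "overall_stats",
    "trait_correlations",
    "environment_spi",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("durumcolor.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def genotype_means(wide: bool = True) -> pd.DataFrame:
    """Genotype x trait means. ``wide=False`` returns the long table with SDs."""
    df = _read("table1_genotype_means.csv")
    if not wide:
        return df
    return df.pivot(index="genotype", columns="trait", values="mean")[list(TRAIT_CODES)]


def environment_means(wide: bool = True) -> pd.DataFrame:
    """Environment x trait means. ``wide=False`` returns the long table with SDs."""
    df = _read("table1_env_means.csv")
    if not wide:
        return df
    return df.pivot(index="environment", columns="trait", values="mean")[list(TRAIT_CODES)]


def overall_stats() -> pd.DataFrame:
    """Overall mean and SD per trait, indexed by trait code."""
    return _read("table1_overall.csv").set_index("trait").loc[list(TRAIT_CODES)]


def trait_correlations(with_p: bool = False):
    """The printed 12 x 12 Pearson correlation matrix of G x E cell means.

    Returns the symmetric r matrix (DataFrame, unit diagonal), or
    ``(r, p)`` when ``with_p`` is true. The diagonal of p is 0.
    """
    long = _read("table2_correlations.csv")
    codes = list(TRAIT_CODES)
    r = pd.DataFrame(np.eye(len(codes)), index=codes, columns=codes)
    p = pd.DataFrame(np.zeros((len(codes), len(codes))), index=codes, columns=codes)
    for row in long.itertuples(index=False):
        r.loc[row.trait_1, row.trait_2] = r.loc[row.trait_2, row.trait_1] = row.r
        p.loc[row.trait_1, row.trait_2] = p.loc[row.trait_2, row.trait_1] = row.p
    return (r, p) if with_p else r


def environment_spi() -> pd.DataFrame:
    """Environment-axis SPI grid (12 traits) plus the printed HPI column."""
    return _read("table5_env_spi.csv").set_index("environment")
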