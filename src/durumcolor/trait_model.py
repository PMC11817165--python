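"""Core data model for multi-environment colour-trait trials.

The package works on balanced genotype x environment x replicate trials of
twelve colour-related traits measured in durum wheat semolina and pasta:
oxidative enzyme activities (lipoxygenase hydroperoxidation HP and
carotene-bleaching BL, peroxidase POD, polyphenoloxidase PPO), carotenoid
pigments (lutein and beta-carotene) and the CIELAB colour indices
(yellow index YI = b*, brown index BI = 100 - L*), each measured in
semolina (``_S`` suffix) and, for pigments and indices, also in pasta
(``_P`` suffix).

Every trait carries a *polarity*: "PV" (positive variable — larger is
better for pasta colour: pigments and yellow indices) or "NV" (negative
variable — smaller is better: oxidative enzymes and brown indices). The
polarity drives the sign convention of the High-Performance Index.

The canonical interchange format is a long CSV with header
``genotype,environment,replicate,trait,value`` (UTF-8, RFC 4180).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "TRAITS",
    "TRAIT_CODES",
    "TraitTable",
    "CellMeanMatrix",
    "read_trait_table",
    "write_trait_table",
    "cell_means",
    "marginal_means",
]

Polarity = Literal["PV", "NV"]
Layer = Literal["semolina", "pasta"]


@dataclass(frozen=True)
class TraitSpec:
    """Registry entry for one canonical trait."""

    code: str
    label: str
    units: str
    layer: Layer
    polarity: Polarity


_ENZ = "EU g-1"
_PIG = "ug g-1 DM"
_IDX = "dimensionless"

#: The twelve canonical traits, in the column order used throughout.
TRAITS: dict[str, TraitSpec] = {
    t.code: t
    for t in (
        TraitSpec("HP", "LOX hydroperoxidation activity", _ENZ, "semolina", "NV"),
        TraitSpec("BL", "LOX carotene-bleaching activity", _ENZ, "semolina", "NV"),
        TraitSpec("POD", "peroxidase activity", _ENZ, "semolina", "NV"),
        TraitSpec("PPO", "polyphenoloxidase activity", _ENZ, "semolina", "NV"),
        TraitSpec("LUT_S", "lutein, semolina", _PIG, "semolina", "PV"),
        TraitSpec("BCAR_S", "beta-carotene, semolina", _PIG, "semolina", "PV"),
        TraitSpec("YI_S", "yellow index (b*), semolina", _IDX, "semolina", "PV"),
        TraitSpec("BI_S", "brown index (100-L*), semolina", _IDX, "semolina", "NV"),
        TraitSpec("LUT_P", "lutein, pasta", _PIG, "pasta", "PV"),
        TraitSpec("BCAR_P", "beta-carotene, pasta", _PIG, "pasta", "PV"),
        TraitSpec("YI_P", "yellow index (b*), pasta", _IDX, "pasta", "PV"),
        TraitSpec("BI_P", "brown index (100-L*), pasta", _IDX, "pasta", "NV"),
    )
}

TRAIT_CODES: tuple[str, ...] = tuple(TRAITS)

_COLUMNS = ("genotype", "environment", "replicate", "trait", "value")


@dataclass
class TraitTable:
    """Long-format replicate-level observations.

    ``data`` has columns genotype, environment, replicate, trait, value.
    Keys (genotype, environment, replicate, trait) are unique; trait codes
    are restricted to the canonical registry.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = self.data.loc[:, list(_COLUMNS)].copy()
        bad = set(self.data["trait"]) - set(TRAIT_CODES)
        if bad:
            raise ValueError(f"unknown trait codes: {sorted(bad)}")
        if (self.data["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        vals = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite trait values")
        dup = self.data.duplicated(
            subset=["genotype", "environment", "replicate", "trait"]
        )
        if dup.any():
            first = self.data.loc[dup.idxmax()]
            raise ValueError(
                "duplicate key (genotype, environment, replicate, trait): "
                f"{tuple(first[['genotype', 'environment', 'replicate', 'trait']])}"
            )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def traits(self) -> list[str]:
        present = set(self.data["trait"])
        return [c for c in TRAIT_CODES if c in present]

    @property
    def balanced(self) -> bool:
        """True iff every genotype x environment x trait cell has the same
        replicate count (and no cell is empty)."""
        counts = self.data.groupby(["trait", "genotype", "environment"]).size()
        if counts.empty:
            return False
        for trait, sub in counts.groupby(level="trait"):
            if len(sub) != len(self.genotypes) * len(self.environments):
                return False
        return counts.nunique() == 1

    def n_rep(self, trait: str) -> int:
        counts = self.data[self.data["trait"] == trait].groupby(
            ["genotype", "environment"]
        ).size()
        return int(counts.iloc[0])


@dataclass
class CellMeanMatrix:
    """Genotype x environment cell means for one trait.

    ``values`` is a DataFrame indexed by genotype with environments as
    columns; each entry is the mean over that cell's replicates.
    """

    trait: str
    values: pd.DataFrame = field(repr=False)

    @property
    def n_gen(self) -> int:
        return self.values.shape[0]

    @property
    def n_env(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Genotype-major flattening — the n = n_gen * n_env sample used by
        downstream correlation and regression stages."""
        return self.values.to_numpy(dtype=float).ravel()


def read_trait_table(path) -> TraitTable:
    """Read the canonical long CSV into a :class:`TraitTable`."""
    df = pd.read_csv(
        path,
        dtype={"genotype": str, "environment": str, "trait": str},
    )
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    return TraitTable(df)


def write_trait_table(table: TraitTable, path) -> None:
    """Write the canonical long CSV.

    Values are written with Python's shortest round-trip float repr, so a
    write/read cycle reproduces every value bit-identically.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for row in table.data.itertuples(index=False):
            writer.writerow(
                [row.genotype, row.environment, int(row.replicate), row.trait,
                 repr(float(row.value))]
            )


def cell_means(table: TraitTable, trait: str) -> CellMeanMatrix:
    """Average replicates within each genotype x environment cell.

    Raises if any cell of the genotype x environment grid is empty for this
    trait, naming the offending (genotype, environment) pair.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait code: {trait}")
    sub = table.data[table.data["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait}")
    grid = sub.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="mean"
    ).sort_index(axis=0).sort_index(axis=1)
    if grid.isna().any().any():
        stacked = grid.isna().stack()
        g, e = stacked[stacked].index[0]
        raise ValueError(f"empty cell for trait {trait}: (genotype={g}, environment={e})")
    counts = sub.groupby(["genotype", "environment"]).size()
    if counts.nunique() != 1:
        raise ValueError(f"trait {trait} is unbalanced across cells")
    return CellMeanMatrix(trait=trait, values=grid)


def marginal_means(matrix: CellMeanMatrix, axis: str) -> pd.Series:
    """Marginal means of a cell-mean grid.

    axis="genotype" averages each genotype over environments;
    axis="environment" averages each environment over genotypes. On a
    balanced grid the mean of either marginal vector is the grand mean.
    """
    if matrix.values.empty:
        raise ValueError("empty cell-mean matrix")
    if axis == "genotype":
        return matrix.values.mean(axis=1)
    if axis == "environment":
        return matrix.values.mean(axis=0)
    raise ValueError(f"axis must be 'genotype' or 'environment', got {axis!r}")


def cell_mean_set(table: TraitTable, traits: Iterable[str] | None = None
                  ) -> dict[str, CellMeanMatrix]:
    """Cell-mean matrices for several traits sharing one grid."""
    codes = list(traits) if traits is not None else table.traits
    return {code: cell_means(table, code) for code in codes}
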