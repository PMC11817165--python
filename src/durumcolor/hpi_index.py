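"""High-Performance Index: polarity-constrained multi-trait scoring.

The HPI condenses many traits with different units and opposite
desirability into one dimensionless number per genotype (or per
environment). For each trait the G x E cell means are standardized
against the trait's overall mean and sample SD over all cells; each
standardized deviation is turned into a score whose sign follows the
trait's polarity — below-average enzyme activity or brown index is
favourable (NV), above-average pigment content or yellow index is
favourable (PV) — and whose magnitude grows with the deviation up to a
cap of 2. Summing scores over the opposite axis gives the Specific
Performance Index (SPI) of each entity for each trait; summing SPIs over
traits gives the entity's HPI. With ``t`` traits and ``c`` contexts the
HPI is bounded by ``2 t c`` in absolute value (192 for 12 traits over 8
environments).

The published description fixes the score's properties (signed, monotone
in the deviation, capped at 2) but not its exact shape; the default here
is the simplest function with those properties, the clamped signed
z-score ``clamp(sign * z, -2, 2)``. Any alternative deviation-to-score
mapping can be injected through the ``score_fn`` hook of
:func:`hpi_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .trait_model import TRAITS, CellMeanMatrix

__all__ = [
    "ConstraintSet",
    "HPIScoreCard",
    "default_constraints",
    "standardize_cells",
    "score_cell",
    "hpi_table",
    "radar_export",
]


def default_constraints(traits) -> dict[str, str]:
    """Polarity map (trait code -> "PV" | "NV") from the canonical registry."""
    return {t: TRAITS[t].polarity for t in traits}


ConstraintSet = dict  # trait code -> "PV" | "NV"


@dataclass
class HPIScoreCard:
    """SPI grid and total HPI per entity on one axis.

    ``spi`` is entity x trait; ``hpi`` the row sums; ``rank`` 1-based,
    descending HPI with alphabetical tie-break; ``bound`` the theoretical
    maximum |HPI| = 2 * n_traits * n_contexts.
    """

    axis: str
    spi: pd.DataFrame = field(repr=False)
    hpi: pd.Series = field(repr=False)
    rank: pd.Series = field(repr=False)
    bound: float
    n_contexts: int


def standardize_cells(cell_means: CellMeanMatrix) -> pd.DataFrame:
    """Standardized deviations from the trait's overall cell-mean and SD.

    The mean and sample SD pool every genotype x environment cell of the
    trait (one stratum for both axes of analysis). A trait with zero
    spread is rejected by name.
    """
    X = cell_means.values.to_numpy(dtype=float)
    m = X.mean()
    s = X.std(ddof=1)
    if s == 0.0:
        raise ValueError(f"zero spread for trait {cell_means.trait}: cannot standardize")
    return (cell_means.values - m) / s


def score_cell(z: float, polarity: str) -> float:
    """Clamped signed score: +z for PV, -z for NV, capped at +/-2."""
    if not np.isfinite(z):
        raise ValueError("non-finite standardized deviation")
    if polarity == "PV":
        signed = z
    elif polarity == "NV":
        signed = -z
    else:
        raise ValueError(f"polarity must be 'PV' or 'NV', got {polarity!r}")
    return float(np.clip(signed, -2.0, 2.0))


def _default_score(z: np.ndarray, polarity: str) -> np.ndarray:
    sign = 1.0 if polarity == "PV" else -1.0
    return np.clip(sign * np.asarray(z, dtype=float), -2.0, 2.0)


def hpi_table(
    cell_means: dict[str, CellMeanMatrix],
    constraints: ConstraintSet | None = None,
    axis: str = "genotype",
    score_fn: Callable[[np.ndarray, str], np.ndarray] | None = None,
    centering: str = "overall",
) -> HPIScoreCard:
    """Score every cell of every trait and aggregate to SPI and HPI.

    ``axis`` chooses the entity being ranked; the opposite axis supplies
    the contexts summed into each SPI. ``centering="overall"`` (default)
    standardizes against the overall cell mean for both axes;
    ``centering="within_genotype"`` is an alternative for the environment
    axis that standardizes each genotype's row of cells around its own
    mean, isolating environmental deviations from genotypic level.
    """
    if axis not in ("genotype", "environment"):
        raise ValueError(f"axis must be 'genotype' or 'environment', got {axis!r}")
    if centering not in ("overall", "within_genotype"):
        raise ValueError(f"unknown centering {centering!r}")
    if centering == "within_genotype" and axis != "environment":
        raise ValueError("within_genotype centering applies to the environment axis")
    if not cell_means:
        raise ValueError("no traits supplied")
    if constraints is None:
        constraints = default_constraints(cell_means)
    missing = set(cell_means) - set(constraints)
    if missing:
        raise ValueError(f"missing polarity constraint for traits: {sorted(missing)}")
    score = score_fn if score_fn is not None else _default_score

    ref = next(iter(cell_means.values())).values
    spi_cols = {}
    for code, cm in cell_means.items():
        if not (cm.values.index.equals(ref.index) and cm.values.columns.equals(ref.columns)):
            raise ValueError(f"trait {code} is on a different grid")
        if centering == "overall":
            z = standardize_cells(cm)
        else:
            X = cm.values
            resid = X.sub(X.mean(axis=1), axis=0)
            s = resid.to_numpy().std(ddof=1)
            if s == 0.0:
                raise ValueError(f"zero spread for trait {code}: cannot standardize")
            z = resid / s
        scores = pd.DataFrame(
            score(z.to_numpy(), constraints[code]), index=z.index, columns=z.columns
        )
        spi_cols[code] = scores.sum(axis=1) if axis == "genotype" else scores.sum(axis=0)

    spi = pd.DataFrame(spi_cols)
    hpi = spi.sum(axis=1)
    n_contexts = ref.shape[1] if axis == "genotype" else ref.shape[0]
    order = sorted(hpi.index, key=lambda e: (-hpi[e], e))
    rank = pd.Series({e: i + 1 for i, e in enumerate(order)}, name="rank").loc[hpi.index]
    return HPIScoreCard(
        axis=axis,
        spi=spi,
        hpi=hpi.rename("HPI"),
        rank=rank,
        bound=hpi_bound(len(cell_means), n_contexts),
        n_contexts=n_contexts,
    )


def hpi_bound(n_traits: int, n_contexts: int) -> float:
    """Theoretical maximum |HPI|: every cell capped favourably."""
    return 2.0 * n_traits * n_contexts


def radar_export(scorecard: HPIScoreCard) -> pd.DataFrame:
    """(entity, HPI) series sorted descending, ties alphabetical — the data
    behind the spider chart."""
    if scorecard.hpi.empty:
        raise ValueError("empty scorecard")
    order = sorted(scorecard.hpi.index, key=lambda e: (-scorecard.hpi[e], e))
    out = scorecard.hpi.loc[order].reset_index()
    out.columns = [scorecard.axis, "HPI"]
    return out
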