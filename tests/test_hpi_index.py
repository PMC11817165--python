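"""High-Performance Index: scoring, aggregation, bounds, fixtures."""

import numpy as np
import pandas as pd
import pytest

from durumcolor.hpi_index import (
    hpi_bound,
    hpi_table,
    radar_export,
    score_cell,
    standardize_cells,
)
from durumcolor.trait_model import CellMeanMatrix


def grid(trait, arr):
    p, q = arr.shape
    return CellMeanMatrix(
        trait=trait,
        values=pd.DataFrame(
            arr, index=[f"G{i:02d}" for i in range(p)],
            columns=[f"E{j}" for j in range(q)],
        ),
    )


class TestStandardize:
    def test_mean_cell_scores_zero(self):
        arr = np.array([[1.0, 2.0], [3.0, 2.0]])
        z = standardize_cells(grid("YI_S", arr))
        assert z.iloc[0, 1] == pytest.approx(0.0)  # cell equal to overall mean

    def test_two_cell_hand_arithmetic(self):
        z = standardize_cells(grid("YI_S", np.array([[0.0], [2.0]])))
        assert z.iloc[0, 0] == pytest.approx(-1 / np.sqrt(2))
        assert z.iloc[1, 0] == pytest.approx(+1 / np.sqrt(2))

    def test_random_grid_unit_moments(self):
        rng = np.random.default_rng(0)
        z = standardize_cells(grid("YI_S", rng.normal(size=(12, 7)))).to_numpy()
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_spread_rejected_by_name(self):
        with pytest.raises(ValueError, match="YI_S"):
            standardize_cells(grid("YI_S", np.full((3, 3), 1.0)))


class TestScoreCell:
    @pytest.mark.parametrize("polarity", ["PV", "NV"])
    def test_zero_deviation_scores_zero(self, polarity):
        assert score_cell(0.0, polarity) == 0.0

    @pytest.mark.parametrize(
        "z,polarity,want",
        [(3.0, "PV", 2.0), (3.0, "NV", -2.0), (-0.5, "NV", 0.5), (-3.0, "PV", -2.0),
         (1.2, "PV", 1.2)],
    )
    def test_sign_and_clamp(self, z, polarity, want):
        assert score_cell(z, polarity) == pytest.approx(want)

    def test_monotonicity(self):
        zs = np.linspace(-4, 4, 41)
        pv = [score_cell(z, "PV") for z in zs]
        nv = [score_cell(z, "NV") for z in zs]
        assert all(a <= b + 1e-12 for a, b in zip(pv, pv[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(nv, nv[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            score_cell(float("nan"), "PV")


class TestHpiTable:
    def _cms(self, seed=1, p=6, q=4, traits=("YI_S", "BI_S", "HP")):
        rng = np.random.default_rng(seed)
        return {t: grid(t, rng.normal(size=(p, q))) for t in traits}

    def test_published_design_bound(self):
        assert hpi_bound(12, 8) == 192.0

    def test_hpi_is_spi_row_sum_and_bounded(self):
        cms = self._cms()
        card = hpi_table(cms, axis="genotype")
        assert np.allclose(card.spi.sum(axis=1), card.hpi)
        assert (card.hpi.abs() <= card.bound + 1e-12).all()
        assert (card.spi.abs().to_numpy() <= 2 * card.n_contexts + 1e-12).all()

    def test_constant_shift_invariance(self):
        cms = self._cms(seed=2)
        shifted = {
            t: grid(t, cm.values.to_numpy() + (5.0 if t == "YI_S" else 0.0))
            for t, cm in cms.items()
        }
        a = hpi_table(cms, axis="genotype")
        b = hpi_table(shifted, axis="genotype")
        assert np.allclose(a.spi.to_numpy(), b.spi.to_numpy(), atol=1e-10)

    def test_polarity_flip_negates_spi_column(self):
        cms = self._cms(seed=3)
        base = hpi_table(cms, constraints={"YI_S": "PV", "BI_S": "NV", "HP": "NV"})
        flip = hpi_table(cms, constraints={"YI_S": "NV", "BI_S": "NV", "HP": "NV"})
        assert np.allclose(flip.spi["YI_S"], -base.spi["YI_S"], atol=1e-12)
        assert np.allclose(flip.spi["BI_S"], base.spi["BI_S"], atol=1e-12)

    def test_dominant_genotype_ranks_first(self):
        rng = np.random.default_rng(4)
        pv = rng.normal(size=(5, 3))
        nv = rng.normal(size=(5, 3))
        pv[0] = pv.max() + 10.0  # best on the PV trait everywhere
        nv[0] = nv.min() - 10.0  # lowest on the NV trait everywhere
        card = hpi_table({"YI_S": grid("YI_S", pv), "HP": grid("HP", nv)})
        assert card.rank.iloc[0] == 1
        assert radar_export(card).iloc[0, 0] == "G00"

    def test_null_configuration_scores_balance_out(self):
        # standardization makes scores zero-mean; while no cell reaches the
        # clamp, favourable and unfavourable scores cancel exactly over the
        # whole table (evenly spaced values keep every |z| < 2)
        rng = np.random.default_rng(5)
        base = np.linspace(0.0, 1.0, 12)
        cms = {
            t: grid(t, 10.0 + 1e-9 * rng.permutation(base).reshape(4, 3))
            for t in ("YI_S", "HP")
        }
        card = hpi_table(cms)
        assert card.hpi.sum() == pytest.approx(0.0, abs=1e-8)

    def test_missing_constraint_rejected(self):
        cms = self._cms(seed=6)
        with pytest.raises(ValueError, match="constraint"):
            hpi_table(cms, constraints={"YI_S": "PV"})

    def test_environment_axis_contexts(self):
        cms = self._cms(seed=7, p=6, q=4)
        card = hpi_table(cms, axis="environment")
        assert card.n_contexts == 6
        assert card.bound == 2 * 3 * 6

    def test_within_genotype_centering_removes_genotype_level(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(5, 4))
        shifted = base + rng.normal(size=(5, 1)) * 10  # big genotype offsets
        a = hpi_table({"YI_S": grid("YI_S", base)}, axis="environment",
                      centering="within_genotype")
        b = hpi_table({"YI_S": grid("YI_S", shifted)}, axis="environment",
                      centering="within_genotype")
        assert np.allclose(a.spi.to_numpy(), b.spi.to_numpy(), atol=1e-8)


class TestRadarExport:
    def test_single_entity(self):
        card = hpi_table({"YI_S": grid("YI_S", np.array([[1.0, 2.0], [3.0, 0.0]]))})
        out = radar_export(card)
        assert list(out.columns) == ["genotype", "HPI"]
        assert len(out) == 2

    def test_ties_alphabetical(self):
        arr = np.array([[1.0, -1.0], [-1.0, 1.0], [2.0, -2.0]])
        card = hpi_table({"YI_S": grid("YI_S", arr)})
        out = radar_export(card)
        tied = out[out["HPI"].round(12) == 0.0]["genotype"].tolist()
        assert tied == sorted(tied)


class TestPrintedSpiGrid:
    def test_row_sum_identity_within_printed_precision(self, env_spi):
        # cells are printed at 2-3 decimals; 12 cells + the HPI itself bound
        # the accumulated rounding by 13 * 0.005 = 0.065
        resid = env_spi.drop(columns="HPI").sum(axis=1) - env_spi["HPI"]
        assert resid.abs().max() <= 0.065

    def test_named_rows_tight(self, env_spi):
        for env, printed in (("ENV3", 10.80), ("ENV5", -4.88)):
            s = env_spi.drop(columns="HPI").loc[env].sum()
            assert s == pytest.approx(printed, abs=0.02)

    def test_environment_spi_sign_pattern(self, env_spi):
        # enzymes scored favourably (positive SPI) in most environments,
        # pasta yellowness unfavourably (negative SPI) in all
        assert (env_spi["HP"] > 0).all()
        assert (env_spi["YI_P"] < 0).all()
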