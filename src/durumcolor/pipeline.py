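"""End-to-end orchestration: simulate/load -> cell means -> ANOVA ->
correlations -> regression -> PCA -> HPI, with a JSON manifest.

Each enabled stage writes tidy CSVs into the output directory; every CSV
starts with a ``# durumcolor seed=<seed>`` comment line so any artifact
can be traced to its run. The manifest lists, per stage, the files
written with their SHA-256 content hashes; rerunning with the same config
and seed reproduces every byte.

In fixture mode the pipeline runs the desk-scale reproduction of the
published summary quantities instead of the trial chain: the standardized
betas of the two-predictor pasta-yellowness model solved from the printed
correlations, the processing-effect percentages and PCA shares from the
printed genotype means, and the row-sum consistency of the printed
environment SPI grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .association import pearson_matrix, processing_effects
from .colour_regression import best_subset_cp, standardized_beta_from_correlations
from .gxe_variance import anova_all_traits
from .hpi_index import hpi_bound, hpi_table, radar_export
from .pca_mapper import pca_correlation
from .synthetic_data import SimulationConfig, simulate_trial
from .trait_model import (
    TraitTable,
    cell_mean_set,
    marginal_means,
    read_trait_table,
    write_trait_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_fixture_results"]

ALL_STAGES = ("anova", "correlate", "process-effects", "regress", "pca", "hpi")

SEMOLINA_PREDICTORS = ["HP", "BL", "POD", "PPO", "LUT_S", "BCAR_S", "YI_S", "BI_S"]


@dataclass
class PipelineConfig:
    """Exactly one input source: a simulation config, a CSV path, or the
    packaged fixture tables."""

    source: str  # "simulate" | "csv" | "fixture"
    out_dir: str | Path = "durumcolor_out"
    sim_config: SimulationConfig | None = None
    csv_path: str | Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("simulate", "csv", "fixture"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "csv" and self.csv_path is None:
            raise ValueError("csv source requires csv_path")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, seed: int, index: bool = True) -> Path:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# durumcolor seed={seed}\n")
        df.to_csv(fh, index=index)
    return path


def read_output_csv(path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the seed header comment."""
    return pd.read_csv(path, comment="#", **kwargs)


def reproduce_fixture_results() -> pd.DataFrame:
    """Recompute the desk-scale headline quantities from the packaged tables.

    Returns a tidy (quantity, value) frame: the standardized betas and
    predictor tolerance of the two-predictor pasta-yellowness model solved
    from printed correlations, the mean processing-effect percentages from
    printed genotype means, the first two PCA shares, the HPI bound, and
    the maximum row-sum discrepancy of the printed SPI grid.
    """
    rows = []
    corr = datasets.trait_correlations()
    R_xx = corr.loc[["BI_S", "YI_S"], ["BI_S", "YI_S"]].to_numpy()
    r_xy = corr.loc[["BI_S", "YI_S"], "YI_P"].to_numpy()
    beta = standardized_beta_from_correlations(R_xx, r_xy)
    rows += [
        ("beta_BI_S", beta[0]),
        ("beta_YI_S", beta[1]),
        ("tolerance_two_predictor", 1.0 - corr.loc["BI_S", "YI_S"] ** 2),
    ]

    gm = datasets.genotype_means()
    eff = processing_effects(gm).mean
    rows += [
        ("carotenoid_decrease_pct", eff["carotenoids"]),
        ("yellow_index_decrease_pct", eff["yellow_index"]),
        ("brown_index_increase_pct", eff["brown_index"]),
    ]

    pca = pca_correlation(gm)
    rows += [("pc1_percent", pca.percent[0]), ("pc2_percent", pca.percent[1])]

    spi = datasets.environment_spi()
    resid = spi.drop(columns="HPI").sum(axis=1) - spi["HPI"]
    rows += [
        ("hpi_bound_12x8", hpi_bound(12, 8)),
        ("table5_max_rowsum_abs_residual", resid.abs().max()),
    ]

    env = datasets.environment_means()
    rows.append(("hp_env_grand_mean", env["HP"].mean()))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; return (and write) the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"seed": seed, "source": config.source, "stages": []}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": [
                    {"path": p.name, "sha256": _sha256(p)} for p in paths
                ],
            }
        )

    if not config.stages:
        _finish(manifest, out)
        return manifest

    if config.source == "fixture":
        df = reproduce_fixture_results()
        p = _write_csv(df, out / "fixture_reproduction.csv", seed, index=False)
        record("reproduce", [p])
        _finish(manifest, out)
        return manifest

    if config.source == "simulate":
        sim = config.sim_config or SimulationConfig(seed=seed)
        if config.sim_config is None or config.seed != 0:
            sim = SimulationConfig(
                n_gen=sim.n_gen, n_env=sim.n_env, n_rep=sim.n_rep,
                traits=sim.traits, mu=dict(sim.mu), sigma=dict(sim.sigma),
                shares=dict(sim.shares), corr=sim.corr, skew=sim.skew,
                skew_shape=sim.skew_shape, seed=seed,
            )
        table = simulate_trial(sim)
        trial_path = out / "trial.csv"
        write_trait_table(table, trial_path)
        record("simulate", [trial_path])
    else:
        table = read_trait_table(config.csv_path)

    cms = cell_mean_set(table)
    gm = pd.DataFrame(
        {c: marginal_means(cm, "genotype") for c, cm in cms.items()}
    )

    for stage in config.stages:
        if stage == "anova":
            df = anova_all_traits(table)
            record(stage, [_write_csv(df, out / "anova.csv", seed, index=False)])
        elif stage == "correlate":
            res = pearson_matrix(cms)
            record(stage, [
                _write_csv(res.r, out / "correlations_r.csv", seed),
                _write_csv(res.p, out / "correlations_p.csv", seed),
            ])
        elif stage == "process-effects":
            eff = processing_effects(gm)
            tidy = eff.per_genotype.copy()
            tidy.loc["MEAN"] = eff.mean
            record(stage, [_write_csv(tidy, out / "processing_effects.csv", seed)])
        elif stage == "regress":
            y = cms["YI_P"].flatten()
            X = np.column_stack([cms[c].flatten() for c in SEMOLINA_PREDICTORS])
            models = best_subset_cp(y, X, SEMOLINA_PREDICTORS, top=10)
            summary = pd.DataFrame(
                {
                    "predictors": ["+".join(m.predictors) for m in models],
                    "k": [m.k for m in models],
                    "cp": [m.cp for m in models],
                    "r2": [m.r2 for m in models],
                    "sse": [m.sse for m in models],
                }
            )
            best = models[0]
            paths = [
                _write_csv(summary, out / "regression_subsets.csv", seed, index=False),
                _write_csv(best.coef, out / "regression_best_coef.csv", seed),
                _write_csv(best.collinearity, out / "regression_best_collinearity.csv", seed),
            ]
            record(stage, paths)
        elif stage == "pca":
            res = pca_correlation(gm)
            eig = pd.DataFrame(
                {"eigenvalue": res.eigenvalues, "percent": res.percent},
                index=res.loadings.columns,
            )
            record(stage, [
                _write_csv(eig, out / "pca_eigenvalues.csv", seed),
                _write_csv(res.loadings, out / "pca_loadings.csv", seed),
                _write_csv(res.scores, out / "pca_scores.csv", seed),
            ])
        elif stage == "hpi":
            paths = []
            for axis in ("genotype", "environment"):
                card = hpi_table(cms, axis=axis)
                grid = card.spi.copy()
                grid["HPI"] = card.hpi
                grid["rank"] = card.rank
                paths.append(_write_csv(grid, out / f"hpi_{axis}.csv", seed))
                paths.append(
                    _write_csv(radar_export(card), out / f"hpi_{axis}_radar.csv",
                               seed, index=False)
                )
            record(stage, paths)

    _finish(manifest, out)
    return manifest


def _finish(manifest: dict, out: Path) -> None:
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
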