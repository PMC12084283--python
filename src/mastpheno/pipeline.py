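"""Pipeline orchestration: simulate, metrics, fit, report.

Thin, file-oriented wrappers over the library modules. Each stage reads
and writes the package's CSV/JSON interchange formats, logs its resolved
configuration, and is idempotent for a fixed seed and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mastpheno import io as mio
from mastpheno.metrics import doy_table, metrics_table, pca_metrics
from mastpheno.ordinal import (
    MCMCConfig,
    PriorSpec,
    SpeciesModel,
    fit_species,
    predict_classes,
)
from mastpheno.process import ProcessParams
from mastpheno.synthetic import (
    ClimateConfig,
    StudyDesign,
    generate_study,
    write_truth,
)

logger = logging.getLogger(__name__)

# distinct process exit codes used by the CLI
EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NOT_CONVERGED = 3
EXIT_MISSING_INPUT = 4


@dataclass
class PipelineConfig:
    """Paths and options for the end-to-end pipeline."""

    out_dir: str = "out"
    observations: str = "observations.csv"
    roster: str = "roster.csv"
    climate: str = "climate.csv"
    seed: int = 0
    # metric options
    min_months: int = 6
    gap_policy: str = "interpolate"
    aggregation: str = "tree_mean"
    # mcmc options
    n_iter: int = 20_000
    burn: int = 2_000
    max_iter: int = 60_000
    ess_threshold: float = 50.0
    phenophases: tuple = ("leaf", "flower", "fruit")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def resolve(self, name: str) -> Path:
        p = Path(name)
        return p if p.is_absolute() else Path(self.out_dir) / p

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter,
            burn=self.burn,
            max_iter=self.max_iter,
            ess_threshold=self.ess_threshold,
        )


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing required input {path}")
    return path


def run_simulate(config: PipelineConfig, design: StudyDesign | None = None) -> dict:
    """Generate a synthetic study and write its four interchange files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulate: config %s", asdict(config))
    obs, roster, climate, truth = generate_study(design=design, seed=config.seed)
    mio.write_observations(obs, out / "observations.csv")
    mio.write_roster(roster, out / "roster.csv")
    mio.write_climate(climate, out / "climate.csv")
    write_truth(truth, out / "truth.json")
    return {"observations": len(obs), "trees": roster["tree_id"].nunique()}


def load_inputs(config: PipelineConfig):
    obs = mio.read_observations(_require(config.resolve(config.observations)))
    roster = mio.read_roster(_require(config.resolve(config.roster)))
    climate = mio.read_climate(_require(config.resolve(config.climate)))
    return obs, roster, climate


def run_metrics(config: PipelineConfig) -> dict:
    """Masting metric suite + DOY timing + PCA; writes three files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("metrics: config %s", asdict(config))
    obs, roster, _ = load_inputs(config)
    mt = metrics_table(
        obs,
        roster,
        min_months=config.min_months,
        gap_policy=config.gap_policy,
        aggregation=config.aggregation,
    )
    if len(mt) == 0:
        raise ValueError("no species with valid metrics")
    mt.to_csv(out / "metrics.csv", index=False)
    dt = doy_table(obs)
    dt.to_csv(out / "doy.csv", index=False)
    pca = {}
    for ph in ("flower", "fruit"):
        try:
            pca[ph] = pca_metrics(mt, ph).to_dict()
        except ValueError as exc:
            logger.warning("pca skipped for %s: %s", ph, exc)
    with open(out / "pca.json", "w") as fh:
        json.dump(pca, fh, indent=1)
    return {"n_rows": len(mt)}


def run_fit(
    config: PipelineConfig,
    species: str,
    process_params: ProcessParams | None = None,
) -> dict:
    """Fit the state-space observation model for one species.

    Writes ``fit_<species>.json`` and ``predictions_<species>.csv``;
    returns a dict with the converged flag and per-phenophase accuracy.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("fit(%s): config %s", species, asdict(config))
    obs, roster, climate = load_inputs(config)
    sub = obs.loc[obs["species"] == species]
    if len(sub) == 0:
        raise ValueError(f"species {species!r} not present in observations")
    model = SpeciesModel(
        sub, climate, process_params, phenophases=config.phenophases
    )
    fit = fit_species(
        sub,
        climate,
        priors=PriorSpec(),
        config=config.mcmc_config(),
        seed=config.seed,
        model=model,
    )
    preds, accuracy = predict_classes(fit, model)
    fit.save_json(out / f"fit_{species}.json")
    pred_out = preds.copy()
    pred_out["date"] = pd.DatetimeIndex(pred_out["date"]).strftime("%Y-%m-%d")
    pred_out.to_csv(out / f"predictions_{species}.csv", index=False)
    return {"species": species, "converged": fit.converged, "accuracy": accuracy}


def observed_vs_modelled(preds: pd.DataFrame) -> pd.DataFrame:
    """Mean observed and modelled intensity per phenophase x pheno-year.

    The modelled intensity is the probability-weighted expected score of
    the fitted ordinal model.
    """
    df = preds.copy()
    df["pheno_year"] = [mio.pheno_year_of(d) for d in df["date"]]
    agg = df.groupby(["phenophase", "pheno_year"], as_index=False).agg(
        observed=("observed", "mean"), modelled=("expected_score", "mean")
    )
    return agg


def run_report(config: PipelineConfig, make_plots: bool = True) -> dict:
    """Assemble report tables (and plots) from metrics and fit outputs.

    Produces observed-vs-modelled intensity tables per species (all
    years and per year), the DOY timing chart, and PCA biplot data.
    """
    out = Path(config.out_dir)
    report = out / "report"
    report.mkdir(parents=True, exist_ok=True)
    for name in ("metrics.csv", "doy.csv"):
        _require(out / name)
    fits = sorted(out.glob("predictions_*.csv"))
    rows = []
    for f in fits:
        species = f.stem.replace("predictions_", "")
        preds = pd.read_csv(f, parse_dates=["date"])
        ovm = observed_vs_modelled(preds)
        ovm.insert(0, "species", species)
        rows.append(ovm)
    if rows:
        per_year = pd.concat(rows, ignore_index=True)
        per_year.to_csv(report / "observed_vs_modelled_per_year.csv", index=False)
        overall = per_year.groupby(["species", "phenophase"], as_index=False)[
            ["observed", "modelled"]
        ].mean()
        overall.to_csv(report / "observed_vs_modelled.csv", index=False)
    doy = pd.read_csv(out / "doy.csv")
    doy.to_csv(report / "doy_windows.csv", index=False)
    if make_plots:
        _report_plots(report, out)
    return {"n_fit_species": len(fits), "report_dir": str(report)}


def _report_plots(report: Path, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ovm_path = report / "observed_vs_modelled.csv"
    if ovm_path.exists():
        ovm = pd.read_csv(ovm_path)
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, ph in zip(axes, ("leaf", "flower", "fruit")):
            sub = ovm.loc[ovm["phenophase"] == ph]
            ax.scatter(sub["observed"], sub["modelled"], s=18)
            lim = max(0.1, sub[["observed", "modelled"]].to_numpy().max() * 1.1) if len(sub) else 1
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
            ax.set_title(ph)
            ax.set_xlabel("observed mean intensity")
        axes[0].set_ylabel("modelled mean intensity")
        fig.tight_layout()
        fig.savefig(report / "observed_vs_modelled.png", dpi=120)
        plt.close(fig)

    doy = pd.read_csv(report / "doy_windows.csv")
    if len(doy):
        fig, ax = plt.subplots(figsize=(8, 6))
        species = sorted(doy["species"].unique())
        colors = {"leaf": "tab:green", "flower": "tab:orange", "fruit": "tab:purple"}
        for i, sp in enumerate(species):
            for ph, off in (("leaf", -0.22), ("flower", 0.0), ("fruit", 0.22)):
                row = doy.loc[(doy["species"] == sp) & (doy["phenophase"] == ph)]
                if len(row) == 0:
                    continue
                lo, hi = float(row["window_lo"].iloc[0]), float(row["window_hi"].iloc[0])
                y = i + off
                if lo <= hi:
                    ax.plot([lo, hi], [y, y], color=colors[ph], lw=3)
                else:  # window wraps the year boundary
                    ax.plot([lo, 365], [y, y], color=colors[ph], lw=3)
                    ax.plot([0, hi], [y, y], color=colors[ph], lw=3)
        ax.set_yticks(range(len(species)), species)
        ax.set_xlabel("day of year")
        ax.set_xlim(0, 365)
        fig.tight_layout()
        fig.savefig(report / "doy_timing.png", dpi=120)
        plt.close(fig)


def run_all(config: PipelineConfig, fit_species_list=None) -> dict:
    """simulate -> metrics -> fit (selected species) -> report."""
    results = {"simulate": run_simulate(config), "metrics": run_metrics(config)}
    fits = []
    for sp in fit_species_list or []:
        fits.append(run_fit(config, sp))
    results["fits"] = fits
    results["report"] = run_report(config)
    return results
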