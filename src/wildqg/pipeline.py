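"""End-to-end analysis pipeline.

Runs: data (simulate or load) -> trait standardization -> phenotypic
selection GLMM -> univariate animal models (trait, fitness) ->
latent-to-data-scale conversion -> bivariate animal model ->
evolutionary predictions (Breeder's Equation, secondary theorem),
observed EBV trend with a gene-dropping drift null, and the
environmental-bias decomposition.  Writes tidy posterior CSVs, a JSON
report and a reproducibility manifest; fully deterministic under a
fixed master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .animal_model import (
    MCMCSettings,
    PriorSpec,
    fit_bivariate_animal_model,
    fit_gaussian_animal_model,
    fit_poisson_animal_model,
    heritability,
)
from .evolution import (
    DEFAULT_GENERATION_TIME,
    bias_decomposition,
    breeders_equation,
    drift_null,
    ebv_trend,
    sts_prediction,
)
from .pedigree import Pedigree, read_pedigree
from .posterior import diagnostics, summarize
from .scale import transform_posterior
from .selection import fit_selection_model, gradients_from_fit, standardize
from .simulate import (
    SimulationConfig,
    read_phenotypes,
    simulate_population,
    write_population,
)

log = logging.getLogger("wildqg")

__all__ = ["RunConfig", "EvolutionReport", "run_pipeline"]


class Estimate(BaseModel):
    mode: float
    hpd: list[float]


class TrendSection(BaseModel):
    slope_per_year: Estimate
    haldanes: Estimate
    p_gt_zero: float
    p_gt_drift: float
    generation_time: float


class EvolutionReport(BaseModel):
    """Schema of the final pipeline report."""

    sex: str
    n_records: int
    beta_latent: Estimate          # latent linear coefficient b1
    beta_gradient: Estimate        # Lande-Arnold-equivalent conversion
    gamma_gradient: Estimate
    h2_latent_size: Estimate
    h2_data_scale_lrs: Estimate
    R_BE: Estimate                 # Haldanes
    R_STS: Estimate                # Haldanes
    trend: TrendSection
    beta_G: Estimate
    beta_E: Estimate
    delta_beta: Estimate
    p_delta_gt_zero: float
    warnings: list[str] = []


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``simulation`` (a :class:`SimulationConfig`) or both
    ``pedigree_path``/``phenotypes_path`` must be provided.
    """

    simulation: SimulationConfig | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    sex: str = "F"
    out_dir: str = "wildqg_run"
    seed: int = 1
    generation_time: float = DEFAULT_GENERATION_TIME
    include_cohort_re: bool = True
    gradient_averaging: str = "empirical"
    drift_reps: int | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    bivariate_priors: PriorSpec = field(default_factory=PriorSpec)
    selection_settings: MCMCSettings | None = None
    gaussian_settings: MCMCSettings | None = None
    poisson_settings: MCMCSettings | None = None
    bivariate_settings: MCMCSettings | None = None
    write_files: bool = True

    def resolve_settings(self) -> dict:
        base = self.seed
        return {
            "selection": self.selection_settings
            or MCMCSettings(burn_in=1000, n_iter=10000, thin=10, seed=base + 11),
            "gaussian": self.gaussian_settings
            or MCMCSettings(burn_in=1000, n_iter=10000, thin=10, seed=base + 22),
            "poisson": self.poisson_settings
            or MCMCSettings(burn_in=1000, n_iter=10000, thin=10, seed=base + 33),
            "bivariate": self.bivariate_settings
            or MCMCSettings(burn_in=3000, n_iter=30000, thin=30, seed=base + 44),
        }


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> EvolutionReport:
    """Execute the full analysis; returns the report (and writes
    artifacts under ``cfg.out_dir`` unless ``write_files=False``)."""
    out = Path(cfg.out_dir)
    if cfg.write_files:
        out.mkdir(parents=True, exist_ok=True)
    settings = cfg.resolve_settings()
    warnings_acc: list[str] = []

    # ------------------------------------------------------------------ data
    t0 = _stage("data")
    if cfg.simulation is not None:
        pop = simulate_population(cfg.simulation)
        ped, pheno = pop.ped, pop.phenotypes
        if cfg.write_files:
            write_population(pop, out / "data")
    elif cfg.pedigree_path and cfg.phenotypes_path:
        ped = read_pedigree(cfg.pedigree_path)
        pheno = read_phenotypes(cfg.phenotypes_path)
    else:
        raise ValueError("RunConfig needs a simulation or input paths")
    data = pheno[pheno["sex"] == cfg.sex].reset_index(drop=True)
    if data.empty:
        raise ValueError(f"no records for sex {cfg.sex!r}")
    size_col = "size_cm" if "size_cm" in data.columns else "size_z"
    trait = standardize(data[size_col].to_numpy(), cfg.sex)
    data = data.assign(size_z=trait.z)
    log.info("data: %d records (%.1fs)", len(data), time.perf_counter() - t0)

    # ------------------------------------------------------- selection GLMM
    t0 = _stage("selection")
    sel = fit_selection_model(
        data["lrs"].to_numpy(),
        trait,
        quadratic=True,
        cohort=data["cohort"].to_numpy() if cfg.include_cohort_re else None,
        priors=cfg.priors,
        settings=settings["selection"],
    )
    grads = gradients_from_fit(
        sel,
        trait.z,
        averaging=cfg.gradient_averaging,
    )
    log.info("selection done (%.1fs)", time.perf_counter() - t0)

    # ------------------------------------------------- univariate animal models
    t0 = _stage("gaussian animal model (size)")
    size_fit = fit_gaussian_animal_model(
        data, ped, response="size_z",
        priors=cfg.priors, settings=settings["gaussian"], store_ebv=True,
    )
    h2_size = heritability(size_fit)
    log.info("size model done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("poisson animal model (LRS)")
    lrs_fit = fit_poisson_animal_model(
        data, ped, response="lrs",
        priors=cfg.priors, settings=settings["poisson"],
    )
    obs_scale = transform_posterior(lrs_fit)
    if obs_scale["n_skipped"]:
        warnings_acc.append(
            f"data-scale transform skipped {obs_scale['n_skipped']} draws"
        )
    log.info("LRS model done (%.1fs)", time.perf_counter() - t0)

    # ---------------------------------------------------------- bivariate
    t0 = _stage("bivariate animal model (size, LRS)")
    biv = fit_bivariate_animal_model(
        data, ped, responses=("size_z", "lrs"), families=("gaussian", "poisson"),
        priors=cfg.bivariate_priors, settings=settings["bivariate"],
    )
    log.info("bivariate model done (%.1fs)", time.perf_counter() - t0)

    # ---------------------------------------------------------- evolution
    t0 = _stage("evolutionary predictions")
    r_be = breeders_equation(
        size_fit["V_A"], sel["b1"], cfg.generation_time, seed=cfg.seed + 55
    )
    r_sts = sts_prediction(biv)
    trend = ebv_trend(
        size_fit.ebv, data["cohort"].to_numpy(), cfg.generation_time
    )
    drift = drift_null(
        ped,
        size_fit["V_A"],
        trend.slopes,
        size_fit.ebv_ids,
        data["cohort"].to_numpy(),
        n_reps=cfg.drift_reps,
        seed=cfg.seed + 66,
        generation_time=cfg.generation_time,
    )
    bias = bias_decomposition(biv)
    log.info("evolution done (%.1fs)", time.perf_counter() - t0)

    # ---------------------------------------------------------- diagnostics
    for name, fit in (("selection", sel), ("size", size_fit),
                      ("lrs", lrs_fit), ("bivariate", biv)):
        diag = diagnostics(fit)
        if diag.flagged:
            warnings_acc.append(
                f"{name}: autocorrelation above 0.10 for {sorted(diag.flagged)}"
            )
        if cfg.write_files:
            diag.to_frame().to_csv(out / f"diagnostics_{name}.csv", index=False)

    report = EvolutionReport(
        sex=cfg.sex,
        n_records=int(len(data)),
        beta_latent=Estimate(**summarize(sel["b1"])),
        beta_gradient=Estimate(**summarize(grads.beta)),
        gamma_gradient=Estimate(**summarize(grads.gamma)),
        h2_latent_size=Estimate(**summarize(h2_size)),
        h2_data_scale_lrs=Estimate(**summarize(obs_scale["h2_obs"])),
        R_BE=Estimate(**summarize(r_be)),
        R_STS=Estimate(**summarize(r_sts)),
        trend=TrendSection(
            slope_per_year=Estimate(**summarize(trend.slopes)),
            haldanes=Estimate(**summarize(trend.haldanes)),
            p_gt_zero=trend.p_gt_zero,
            p_gt_drift=drift.p_gt_drift,
            generation_time=cfg.generation_time,
        ),
        beta_G=Estimate(**summarize(bias.beta_G)),
        beta_E=Estimate(**summarize(bias.beta_E)),
        delta_beta=Estimate(**summarize(bias.delta_beta)),
        p_delta_gt_zero=bias.p_delta_gt_zero,
        warnings=warnings_acc,
    )

    if cfg.write_files:
        sel.write_tidy_csv(out / "posterior_selection.csv")
        size_fit.write_tidy_csv(out / "posterior_size.csv")
        lrs_fit.write_tidy_csv(out / "posterior_lrs.csv")
        biv.write_tidy_csv(out / "posterior_bivariate.csv")
        size_fit.write_ebv_csv(out / "ebv_size.csv")
        (out / "report.json").write_text(report_json(report))
        (out / "manifest.json").write_text(_manifest_json(cfg, settings))
    return report


def report_json(report: EvolutionReport) -> str:
    """Deterministic serialization of the report."""
    return json.dumps(report.model_dump(), indent=2, sort_keys=True)


def _manifest_json(cfg: RunConfig, settings: dict) -> str:
    import scipy

    man = {
        "package": {"wildqg": __version__},
        "libraries": {"numpy": np.__version__, "scipy": scipy.__version__,
                      "pandas": pd.__version__},
        "seed": cfg.seed,
        "sex": cfg.sex,
        "generation_time": cfg.generation_time,
        "mcmc": {
            k: {"burn_in": s.burn_in, "n_iter": s.n_iter,
                "thin": s.thin, "seed": s.seed}
            for k, s in settings.items()
        },
        "simulation": (
            None if cfg.simulation is None
            else {k: v for k, v in vars(cfg.simulation).items()}
        ),
    }
    return json.dumps(man, indent=2, sort_keys=True, default=str)
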