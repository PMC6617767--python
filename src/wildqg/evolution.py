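"""Evolutionary predictions, observed genetic trends and bias metrics.

Ties the fitted models together:

* Breeder's Equation prediction        R_BE  = V_A * beta
* Secondary-theorem prediction         R_STS = cov_A(w, z)
* Observed trend in mean breeding values per cohort year, against a
  gene-dropping drift null
* Environmental-vs-genetic selection-gradient decomposition
  (beta_G = cov_A / V_A;  beta_E = sum of non-genetic covariances over
  the corresponding trait variances;  Delta-beta = beta_E - beta_G)

All traits are assumed variance-standardized, so annual trends are in
phenotypic standard deviations per year (PSD) and per-generation rates
(annual rate x generation time) are Haldanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree, gene_drop
from .posterior import PosteriorSamples, summarize

__all__ = [
    "breeders_equation",
    "sts_prediction",
    "ebv_trend",
    "drift_null",
    "bias_decomposition",
    "TrendResult",
    "BiasDecomposition",
    "DEFAULT_GENERATION_TIME",
]

#: modal generation interval (years) of the study system
DEFAULT_GENERATION_TIME = 4.0


def _pair_chains(x, y, rng) -> tuple[np.ndarray, np.ndarray]:
    """Randomly match draws from two independently fitted posteriors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty posterior chain")
    n = max(x.size, y.size)
    return x[rng.integers(0, x.size, n)], y[rng.integers(0, y.size, n)]


def breeders_equation(
    va_draws,
    beta_draws,
    generation_time: float = DEFAULT_GENERATION_TIME,
    seed: int = 0,
) -> np.ndarray:
    """Posterior of the Breeder's-Equation response R_BE = V_A * beta.

    ``va_draws`` and ``beta_draws`` come from independently fitted
    models, so draws are paired by seeded random matching; for a
    variance-standardized trait the product is already per generation,
    i.e. in Haldanes (``generation_time`` is carried in metadata only
    and kept for symmetry with the annual-trend conversion).
    """
    rng = np.random.default_rng(seed)
    va, beta = _pair_chains(va_draws, beta_draws, rng)
    return va * beta


def sts_prediction(bivariate: PosteriorSamples) -> np.ndarray:
    """Secondary-theorem response: the posterior of the additive genetic
    covariance between relative fitness and the trait.

    With a log-link fitness model the latent-scale additive covariance
    equals the additive covariance with relative fitness, so the
    ``cov_A`` draws of the trait-fitness bivariate animal model are the
    R_STS posterior (Haldanes, trait variance-standardized)."""
    if "cov_A" not in bivariate.params:
        raise ValueError("bivariate fit lacks a cov_A chain")
    return np.asarray(bivariate["cov_A"], dtype=float)


# ---------------------------------------------------------------------------
# observed genetic trend and drift null


@dataclass
class TrendResult:
    """Posterior of the annual trend in cohort-mean breeding values."""

    slopes: np.ndarray                  # PSD per year
    p_gt_zero: float
    haldanes: np.ndarray                # PSD per generation
    generation_time: float
    zero_variance: bool = False
    p_gt_drift: float | None = None
    drift_slopes: np.ndarray | None = None

    def report(self) -> dict:
        out = {
            "slope_per_year": summarize(self.slopes),
            "haldanes": summarize(self.haldanes),
            "p_gt_zero": self.p_gt_zero,
            "generation_time": self.generation_time,
        }
        if self.zero_variance:
            out["zero_variance"] = True
        if self.p_gt_drift is not None:
            out["p_gt_drift"] = self.p_gt_drift
        return out


def _cohort_mean_slope(values, cohort_idx, years, n_cohorts):
    """OLS slope of cohort means on cohort year; ``values`` may be a
    (draws x individuals) matrix, in which case a slope per draw is
    returned."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    counts = np.bincount(cohort_idx, minlength=n_cohorts).astype(float)
    sums = np.stack(
        [np.bincount(cohort_idx, weights=v, minlength=n_cohorts) for v in values]
    )
    means = sums / counts
    x = years - years.mean()
    denom = float(x @ x)
    return (means @ x) / denom


def ebv_trend(
    ebv_draws,
    cohorts,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> TrendResult:
    """Temporal trend of estimated breeding values.

    For each posterior draw, cohort-mean EBVs are regressed on cohort
    year (ordinary least squares, one point per cohort), giving a
    posterior of annual rates of genetic change; multiplying by the
    generation time converts to Haldanes.
    """
    cohorts = np.asarray(cohorts, dtype=float)
    if np.any(~np.isfinite(cohorts)):
        raise ValueError("every individual needs a cohort year")
    years, cohort_idx = np.unique(cohorts, return_inverse=True)
    if years.size < 3:
        raise ValueError("need at least 3 distinct cohorts for a trend")
    slopes = _cohort_mean_slope(ebv_draws, cohort_idx, years, years.size)
    zero_var = bool(np.ptp(slopes) == 0 and slopes[0] == 0)
    return TrendResult(
        slopes=slopes,
        p_gt_zero=float(np.mean(slopes > 0)),
        haldanes=slopes * generation_time,
        generation_time=generation_time,
        zero_variance=zero_var,
    )


def drift_null(
    ped: Pedigree,
    va_draws,
    observed_slopes,
    ind_ids,
    cohorts,
    *,
    n_reps: int | None = None,
    seed: int = 0,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> TrendResult:
    """Gene-dropping drift null for the EBV trend.

    For each posterior draw of ``V_A`` (or a seeded subsample of
    ``n_reps`` draws), random breeding values are simulated down the
    full pedigree, the cohort-mean slope is computed over the same
    individuals and cohorts as the observed trend, and the paired
    exceedance probability  P(observed slope > drift slope)  is
    reported.

    Because gene-dropped breeding values scale exactly as ``sqrt(V_A)``,
    one unit-variance drop per replicate is simulated and rescaled by
    that replicate's ``V_A`` draw.
    """
    rng = np.random.default_rng(seed)
    va = np.asarray(va_draws, dtype=float)
    obs = np.asarray(observed_slopes, dtype=float)
    if va.size != obs.size:
        raise ValueError("need one V_A draw per observed-slope draw")
    if np.any(va < 0):
        raise ValueError("negative V_A draw")
    if n_reps is not None and n_reps < va.size:
        pick = rng.choice(va.size, size=n_reps, replace=False)
        va, obs = va[pick], obs[pick]
    pos = ped.positions(ind_ids)
    cohorts = np.asarray(cohorts, dtype=float)
    years, cohort_idx = np.unique(cohorts, return_inverse=True)
    bv = gene_drop(ped, 1.0, rng, n_reps=va.size)[:, pos]
    bv *= np.sqrt(va)[:, None]
    drift = _cohort_mean_slope(bv, cohort_idx, years, years.size)
    return TrendResult(
        slopes=drift,
        p_gt_zero=float(np.mean(drift > 0)),
        haldanes=drift * generation_time,
        generation_time=generation_time,
        p_gt_drift=float(np.mean(obs > drift)),
        drift_slopes=drift,
    )


# ---------------------------------------------------------------------------
# environmental-bias decomposition


@dataclass
class BiasDecomposition:
    """Genetic vs non-genetic selection gradients and their difference."""

    beta_G: np.ndarray
    beta_E: np.ndarray
    delta_beta: np.ndarray
    p_delta_gt_zero: float
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "beta_G": summarize(self.beta_G),
            "beta_E": summarize(self.beta_E),
            "delta_beta": summarize(self.delta_beta),
            "p_delta_gt_zero": self.p_delta_gt_zero,
            "n_excluded": self.n_excluded,
        }


def bias_decomposition(
    bivariate: PosteriorSamples,
    *,
    env_terms: tuple = ("dam", "cohort", "resid"),
) -> BiasDecomposition:
    """Split the trait-fitness association into genetic and non-genetic
    selection gradients, per posterior draw of the bivariate model.

    ``beta_G = cov_A / V_A(trait)``; ``beta_E`` sums the non-genetic
    covariance terms and divides by the corresponding trait variance
    components; ``delta_beta = beta_E - beta_G`` exactly per draw.
    Draws with a zero denominator are excluded (count reported).
    """
    need = ["cov_A", "V_A_t1"] + [f"cov_{t}" for t in env_terms] + [
        f"V_{t}_t1" for t in env_terms
    ]
    for name in need:
        if name not in bivariate.params:
            raise ValueError(f"bivariate fit lacks the {name!r} chain")
    cov_a = np.asarray(bivariate["cov_A"], dtype=float)
    va = np.asarray(bivariate["V_A_t1"], dtype=float)
    cov_e = sum(np.asarray(bivariate[f"cov_{t}"], dtype=float) for t in env_terms)
    ve = sum(np.asarray(bivariate[f"V_{t}_t1"], dtype=float) for t in env_terms)
    ok = (va > 0) & (ve > 0)
    beta_g = cov_a[ok] / va[ok]
    beta_e = cov_e[ok] / ve[ok]
    delta = beta_e - beta_g
    return BiasDecomposition(
        beta_G=beta_g,
        beta_E=beta_e,
        delta_beta=delta,
        p_delta_gt_zero=float(np.mean(delta > 0)),
        n_excluded=int((~ok).sum()),
        meta={"env_terms": tuple(env_terms)},
    )
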