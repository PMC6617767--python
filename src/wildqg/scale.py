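"""Latent-scale to data-scale conversion for Poisson log-link models.

A GLMM estimates variance components on the link (latent) scale.  For a
log link with latent value eta = mu + a + r, a ~ N(0, V_A),
total latent variance V_total, the observed count y ~ Poisson(exp(eta))
has closed-form data-scale moments under log-normal mixing:

    mean_obs = exp(mu + V_total / 2)
    V_P_obs  = mean_obs + mean_obs^2 (exp(V_total) - 1)
    V_A_obs  = mean_obs^2 V_A        (average-derivative Psi = mean_obs,
                                      exact for the log link)
    h2_obs   = V_A_obs / V_P_obs

The phenotypic variance combines Poisson sampling noise (first term)
with the variance of the log-normally distributed rate (second term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .posterior import PosteriorSamples

__all__ = ["LatentParams", "DataScaleParams", "poisson_log_to_data_scale",
           "transform_posterior"]

#: latent total variances above this are rejected as non-physical
_V_TOTAL_MAX = 700.0


@dataclass(frozen=True)
class LatentParams:
    mu: float
    v_a: float
    v_total: float

    def __post_init__(self) -> None:
        if self.v_a < 0:
            raise ValueError("V_A must be non-negative")
        if self.v_total < self.v_a:
            raise ValueError("V_total must be at least V_A")
        if self.v_total > _V_TOTAL_MAX:
            raise ValueError("latent variance too large to exponentiate")


@dataclass(frozen=True)
class DataScaleParams:
    mean_obs: float
    v_a_obs: float
    v_p_obs: float
    h2_obs: float


def poisson_log_to_data_scale(p: LatentParams) -> DataScaleParams:
    """Exact data-scale mean, variances and heritability for a Poisson
    log-link latent model (see module docstring for the closed forms)."""
    mean_obs = float(np.exp(p.mu + p.v_total / 2.0))
    v_p = mean_obs + mean_obs**2 * float(np.expm1(p.v_total))
    v_a = mean_obs**2 * p.v_a
    return DataScaleParams(mean_obs, v_a, v_p, v_a / v_p)


def transform_posterior(
    samples: PosteriorSamples,
    *,
    intercept: str = "intercept",
    components: tuple = ("V_A", "V_dam", "V_cohort", "V_resid"),
) -> dict:
    """Apply the latent-to-data-scale transform draw by draw.

    ``V_total`` is the sum of every latent variance component present in
    ``components`` (all four by default, mirroring the latent
    heritability denominator).  Draws violating the latent-parameter
    preconditions are skipped; their count is reported.

    Returns arrays ``mean_obs``, ``V_A_obs``, ``V_P_obs``, ``h2_obs``
    plus ``n_skipped``.
    """
    mu = np.asarray(samples[intercept], dtype=float)
    present = [c for c in components if c in samples.params]
    v_a = np.asarray(samples["V_A"], dtype=float)
    v_total = sum(np.asarray(samples[c], dtype=float) for c in present)
    ok = (v_a >= 0) & (v_total >= v_a) & (v_total <= _V_TOTAL_MAX)
    mu, v_a, v_total = mu[ok], v_a[ok], v_total[ok]
    mean_obs = np.exp(mu + v_total / 2.0)
    v_p = mean_obs + mean_obs**2 * np.expm1(v_total)
    v_a_obs = mean_obs**2 * v_a
    return {
        "mean_obs": mean_obs,
        "V_A_obs": v_a_obs,
        "V_P_obs": v_p,
        "h2_obs": v_a_obs / v_p,
        "n_skipped": int((~ok).sum()),
    }
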