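"""Synthetic salmon-like populations with known genetic ground truth.

The generator emulates the sampling structure of a trapped anadromous
population: nine annual return cohorts, a modal four-year overlapping
life cycle (ages 3-5 at return), roughly 1,185 phenotyped females and
300 males, a heritable variance-standardized body-size trait
(V_A = 0.25 of a unit phenotypic variance, h2 ~ 0.23) and Poisson
lifetime reproductive success (LRS) whose log-rate depends on the
mother's size.  LRS counts only offspring returning inside the study
window, reproducing the truncation of the last cohorts.

Ground-truth knobs:

* ``b_w``     - direct effect of maternal size on the latent log fitness
                rate (phenotypic selection that is causally real).
* ``rho_A``   - additive genetic covariance between size and latent
                fitness over and above the ``b_w`` path.
* ``confounder_s`` - a shared environmental deviate with coefficient
                ``s`` added to both the trait residual and the fitness
                latent residual (total residual variances are
                preserved).  This induces trait-fitness covariance with
                no genetic basis: the "missing environmental factor"
                scenario in which phenotypic selection overstates the
                expected evolutionary response (Delta-beta > 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UNKNOWN

__all__ = ["SimulationConfig", "SyntheticPopulation", "simulate_population",
           "write_population", "read_phenotypes", "write_phenotypes"]


@dataclass
class SimulationConfig:
    """Generating parameters; defaults are the study conditions."""

    n_cohorts: int = 9
    start_year: int = 1977
    females_per_cohort: int = 132
    males_per_cohort: int = 34
    #: age at adult return -> probability (modal 4-year life cycle)
    age_dist: dict = field(default_factory=lambda: {4: 0.90, 3: 0.05, 5: 0.05})
    # trait architecture (variance-standardized scale)
    V_A: float = 0.25
    V_dam: float = 0.001
    V_cohort: float = 0.08
    V_resid: float = 0.67
    # fitness architecture (latent log scale)
    mu_w: float | None = None      # None -> solved for demographic stationarity
    b_w: float = 0.23
    V_A_w: float = 0.003
    V_cohort_w: float = 0.33
    V_resid_w: float = 0.93
    # trait-fitness links beyond b_w
    confounder_s: float = 0.0
    rho_A: float = 0.0
    male_b_w: float = 0.0          # size-biased siring success, off by default
    #: candidate recruits are produced at this multiple of the run size
    #: and thinned back by density regulation (see simulate_population)
    recruitment_surplus: float = 3.0
    #: extra years past the last cohort in which returning offspring are
    #: still created, pedigreed and counted in parental LRS (emulating
    #: continued trap sampling beyond the analysis cohorts; only the
    #: final cohorts' oldest offspring are truncated)
    assignment_years: int = 4
    # optional affine map from the z scale to centimetres
    size_mean_cm: float | None = 60.0
    size_sd_cm: float | None = 6.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("V_A", "V_dam", "V_cohort", "V_resid",
                     "V_A_w", "V_cohort_w", "V_resid_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        probs = np.array(list(self.age_dist.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("age_dist probabilities must sum to 1")
        s2 = self.confounder_s**2
        if s2 > min(self.V_resid, self.V_resid_w):
            raise ValueError("confounder_s^2 exceeds a residual variance")
        if self.females_per_cohort <= 0:
            raise ValueError("need at least one female per cohort")
        if np.linalg.eigvalsh(self.genetic_cov()).min() < -1e-12:
            raise ValueError("implied genetic covariance matrix not PSD")

    def genetic_cov(self) -> np.ndarray:
        """2x2 additive covariance of (size BV, latent-fitness BV beyond
        the direct ``b_w`` path)."""
        return np.array([[self.V_A, self.rho_A], [self.rho_A, self.V_A_w]])

    @property
    def years(self) -> list:
        return list(range(self.start_year, self.start_year + self.n_cohorts))

    def latent_fitness_variance(self) -> float:
        vz = self.V_A + self.V_dam + self.V_cohort + self.V_resid
        return (
            self.b_w**2 * vz
            + self.V_A_w + self.V_cohort_w + self.V_resid_w
            + 2.0 * self.b_w * self.rho_A
            + 2.0 * self.b_w * self.confounder_s**2
        )

    def solved_mu_w(self) -> float:
        """Intercept giving a stationary regulated population: candidate
        offspring per mother exceed the replacement need by the
        recruitment surplus; density regulation thins them back."""
        if self.mu_w is not None:
            return self.mu_w
        target = self.recruitment_surplus * \
            (self.females_per_cohort + self.males_per_cohort) / \
            self.females_per_cohort
        return float(np.log(target) - self.latent_fitness_variance() / 2.0)

    @property
    def true_cov_a_wz(self) -> float:
        """Built-in additive covariance between latent fitness and size."""
        return self.b_w * self.V_A + self.rho_A


@dataclass
class SyntheticPopulation:
    ped: Pedigree
    phenotypes: pd.DataFrame
    truth: dict


def simulate_population(cfg: SimulationConfig) -> SyntheticPopulation:
    """Forward-simulate the population; deterministic given ``cfg.seed``.

    Founder cohorts are seeded in the five years before the study
    window at the configured sizes.  Each spawning year, every returning
    female produces candidate offspring at a Poisson rate built from her
    size, her latent genetic fitness effect, a year effect and an
    overdispersion residual; candidates receive a random sire from the
    same run, an age at return, and are then thinned by density
    regulation so that each year's run does not exceed the configured
    run size (an approximately stationary population, as in a trapped
    catchment with a fixed carrying capacity).  Offspring breeding
    values are mid-parent plus Mendelian noise; an adult's LRS is its
    count of regulated recruits returning by the end of the assignment
    horizon, so the final cohorts' oldest offspring are truncated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years
    start, end = years[0], years[-1]
    seed_years = list(range(start - 5, start))
    last_return = end + cfg.assignment_years
    all_years = seed_years + list(range(start, last_return + 1))
    ages = np.array(sorted(cfg.age_dist))
    age_p = np.array([cfg.age_dist[k] for k in ages], dtype=float)
    mu_w = cfg.solved_mu_w()
    if float(np.exp(mu_w + cfg.latent_fitness_variance() / 2.0)) < 0.1:
        warnings.warn("mean reproductive rate < 0.1: population will die out")

    G = cfg.genetic_cov()
    w, V = np.linalg.eigh(G)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    s = cfg.confounder_s
    sd_ez = np.sqrt(cfg.V_resid - s * s)
    sd_ew = np.sqrt(cfg.V_resid_w - s * s)
    c_z = {y: rng.normal(0.0, np.sqrt(cfg.V_cohort)) for y in all_years}
    c_w = {y: rng.normal(0.0, np.sqrt(cfg.V_cohort_w)) for y in all_years}

    ids: list[str] = []
    dam_i: list[int] = []
    sire_i: list[int] = []
    ret_year: list[int] = []
    sex: list[str] = []
    bvs: list[np.ndarray] = []     # (size BV, extra latent-fitness BV)
    z: list[float] = []            # realized standardized size
    u_conf: list[float] = []       # shared environmental deviate
    lrs: list[int] = []
    lam_w: list[float] = []        # true Poisson LRS rate (mothers; nan else)
    by_year = {y: {"F": [], "M": []} for y in all_years}
    p_female = cfg.females_per_cohort / (cfg.females_per_cohort + cfg.males_per_cohort)

    def create(year, sx, dam=UNKNOWN, sire=UNKNOWN, bv=None, dam_eff=0.0) -> int:
        k = len(ids)
        ids.append(f"{sx}{year}-{k}")
        dam_i.append(dam)
        sire_i.append(sire)
        ret_year.append(year)
        sex.append(sx)
        if bv is None:
            bv = L @ rng.standard_normal(2)
        bvs.append(bv)
        u = rng.standard_normal()
        u_conf.append(u)
        z.append(bv[0] + dam_eff + c_z[year] + s * u + sd_ez * rng.standard_normal())
        lrs.append(0)
        lam_w.append(np.nan)
        by_year[year][sx].append(k)
        return k

    # founder cohorts fill the pre-window years; their dam effects are
    # independent draws (their mothers are outside the pedigree)
    for y in seed_years:
        for _ in range(cfg.females_per_cohort):
            create(y, "F", dam_eff=rng.normal(0, np.sqrt(cfg.V_dam)))
        for _ in range(cfg.males_per_cohort):
            create(y, "M", dam_eff=rng.normal(0, np.sqrt(cfg.V_dam)))

    dam_effect_of: dict[int, float] = {}   # drawn once per mother
    run_cap = cfg.females_per_cohort + cfg.males_per_cohort
    candidates: dict[int, list] = {ry: [] for ry in range(start, last_return + 1)}

    def finalize_return_year(ry: int) -> None:
        """Density regulation: the run of year ``ry`` recruits at most
        the configured run size, by uniform thinning of the candidate
        pool.  Uniform thinning of per-mother Poisson counts keeps LRS
        Poisson with a year-level factor on the rate, which the cohort
        random effect absorbs, so the fitted models stay correctly
        specified."""
        pool = candidates.pop(ry)
        if len(pool) > run_cap:
            keep = rng.choice(len(pool), size=run_cap, replace=False)
            pool = [pool[int(k)] for k in sorted(keep)]
        for m, sire in pool:
            if m not in dam_effect_of:
                dam_effect_of[m] = rng.normal(0, np.sqrt(cfg.V_dam))
            mid = 0.5 * (bvs[m] + bvs[sire])
            bv = mid + np.sqrt(0.5) * (L @ rng.standard_normal(2))
            sx = "F" if rng.random() < p_female else "M"
            create(ry, sx, dam=m, sire=sire, bv=bv, dam_eff=dam_effect_of[m])
            lrs[m] += 1
            lrs[sire] += 1

    # each year: settle that year's returning run, then let it spawn;
    # spawners of year y only feed runs of year y+3 onward, so every
    # run is complete before it is finalized
    for y in range(start - 5, last_return + 1):
        if y >= start:
            finalize_return_year(y)
        if y > end:
            continue          # post-window returns are pedigreed, not spawned
        mothers = by_year[y]["F"]
        males = by_year[y]["M"]
        if not mothers:
            if y >= start:
                raise RuntimeError(f"no returning females in {y}: extinction")
            continue
        if not males:
            warnings.warn(f"no returning males in {y}; skipping matings")
            continue
        male_w = None
        if cfg.male_b_w != 0.0:
            male_w = np.exp(cfg.male_b_w * np.array([z[m] for m in males]))
            male_w = male_w / male_w.sum()
        males_arr = np.asarray(males)
        for m in mothers:
            lam = np.exp(
                mu_w
                + cfg.b_w * z[m]
                + bvs[m][1]
                + c_w[y]
                + s * u_conf[m]
                + sd_ew * rng.standard_normal()
            )
            lam_w[m] = lam
            n_off = rng.poisson(lam)
            for _ in range(n_off):
                age = int(rng.choice(ages, p=age_p))
                ry = y + age
                if ry < start or ry > last_return:
                    continue
                sire = int(rng.choice(males_arr, p=male_w))
                candidates[ry].append((m, sire))

    ped = Pedigree(
        np.array(ids, dtype=object),
        np.array(dam_i, dtype=np.int64),
        np.array(sire_i, dtype=np.int64),
        np.array(ret_year, dtype=float),
        np.array(sex, dtype=object),
    )
    in_window = np.array([start <= ry <= end for ry in ret_year])
    size_z = np.array(z)
    if cfg.size_mean_cm is not None and cfg.size_sd_cm is not None:
        size_cm = cfg.size_mean_cm + cfg.size_sd_cm * size_z
    else:
        size_cm = size_z
    pheno = pd.DataFrame(
        {
            "id": np.array(ids, dtype=object)[in_window],
            "size_cm": size_cm[in_window],
            "size_z": size_z[in_window],
            "lrs": np.array(lrs)[in_window],
            "lam_w": np.array(lam_w)[in_window],
            "cohort": np.array(ret_year, dtype=int)[in_window],
            "sex": np.array(sex, dtype=object)[in_window],
        }
    ).reset_index(drop=True)
    if not len(pheno):
        raise RuntimeError("empty population: no fish returned in the window")

    fem = in_window & (np.array(sex, dtype=object) == "F")
    bv_arr = np.array(bvs)
    a_z = bv_arr[fem, 0]
    a_w = cfg.b_w * bv_arr[fem, 0] + bv_arr[fem, 1]
    realized = float(np.cov(a_z, a_w)[0, 1]) if fem.sum() > 2 else np.nan
    truth = asdict(cfg)
    truth["mu_w_solved"] = cfg.solved_mu_w()
    truth["true_cov_A_wz"] = cfg.true_cov_a_wz
    truth["realized_cov_A_wz"] = realized
    truth["true_h2"] = cfg.V_A / (cfg.V_A + cfg.V_dam + cfg.V_cohort + cfg.V_resid)
    truth["n_female_records"] = int((pheno["sex"] == "F").sum())
    truth["n_male_records"] = int((pheno["sex"] == "M").sum())
    return SyntheticPopulation(ped=ped, phenotypes=pheno, truth=truth)


# ---------------------------------------------------------------------------
# file round-trip


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "lrs", "cohort", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df


def write_population(pop: SyntheticPopulation, out_dir) -> dict:
    """Write ``pedigree.csv``, ``phenotypes.csv`` and ``truth.json``;
    files round-trip losslessly through the package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .pedigree import write_pedigree

    write_pedigree(pop.ped, out / "pedigree.csv")
    write_phenotypes(pop.phenotypes, out / "phenotypes.csv")
    (out / "truth.json").write_text(json.dumps(pop.truth, indent=2, sort_keys=True))
    return {
        "pedigree": str(out / "pedigree.csv"),
        "phenotypes": str(out / "phenotypes.csv"),
        "truth": str(out / "truth.json"),
    }
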