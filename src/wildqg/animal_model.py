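"""Bayesian animal models by blocked Gibbs sampling.

The engine fits univariate Gaussian, univariate Poisson (log link, with
a latent overdispersion residual) and bivariate Gaussian-Poisson mixed
models with an intercept and additive-genetic, dam, cohort and residual
random effects.  The additive-genetic term is structured by the pedigree
numerator relationship matrix ``A``.

Implementation notes
--------------------
Rather than working with the sparse inverse of ``A`` over the whole
pedigree, the engine marginalises the model to the phenotyped
individuals: their breeding values have covariance ``V_A * A_obs`` where
``A_obs`` is the corresponding dense submatrix of ``A``, and this is an
exact marginalisation.  A single eigendecomposition ``A_obs = U D U'``
per fit then makes the full conditional of the rotated breeding values
diagonal (2x2-block-diagonal in the bivariate case), so every Gibbs
iteration costs two matrix-vector products instead of a sparse Cholesky
factorisation.

Poisson responses are handled through one latent value per observation,
updated by stepping-out/shrinkage slice sampling of its log-concave full
conditional; given the latent values all variance components remain
conjugate.  Scalar variance components in univariate models use
parameter expansion (a working scale with a diffuse Gaussian prior),
which keeps chains mobile when a variance sits near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .pedigree import Pedigree, relationship_matrix
from .posterior import PosteriorSamples

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "fit_gaussian_animal_model",
    "fit_poisson_animal_model",
    "fit_bivariate_animal_model",
    "fit_glmm",
    "heritability",
    "PAPER_SCALE_GAUSSIAN",
    "PAPER_SCALE_POISSON",
]

log = logging.getLogger("wildqg")

#: latent values are clipped here before exponentiation (overflow guard)
ETA_CLIP = 30.0


class ModelError(RuntimeError):
    """Raised for degenerate inputs or diverging chains."""


@dataclass
class MCMCSettings:
    """Chain-length settings.

    Defaults are desk-scale (minutes per fit on one core); the
    publication-scale presets below reproduce chain lengths typically
    used for final inference on real datasets.
    """

    burn_in: int = 1000
    n_iter: int = 10000
    thin: int = 10
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter // self.thin < 100:
            raise ValueError("need n_iter/thin >= 100 draws for summaries")

    @property
    def n_draws(self) -> int:
        return self.n_iter // self.thin


PAPER_SCALE_GAUSSIAN = MCMCSettings(burn_in=500_000, n_iter=2_000_000, thin=1000)
PAPER_SCALE_POISSON = MCMCSettings(burn_in=1_000_000, n_iter=14_000_000, thin=10_000)


@dataclass
class PriorSpec:
    """Weakly informative defaults in the inverse-gamma / inverse-Wishart
    parameterisation: scalar variances ~ IG(nu/2, nu*V0/2) with a
    parameter-expansion working scale ~ N(0, px_var); 2x2 terms ~
    IW(df=3, scale=I); fixed effects ~ N(0, fixed_var)."""

    nu: float = 0.002
    V0: float = 1.0
    px_var: float = 1000.0
    iw_df: float = 3.0
    iw_scale: float = 1.0
    fixed_var: float = 1e8

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.iw_df <= 1:
            raise ValueError("prior degrees of freedom must be positive")
        if self.V0 <= 0 or self.iw_scale <= 0:
            raise ValueError("prior scales must be positive definite")


def _sample_invgamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _check_counts(y: np.ndarray) -> None:
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ModelError("Poisson response must be non-negative integers")


def _slice_poisson_eta(eta, y, m, v, rng, width=1.0, max_step=20, max_shrink=100):
    """One slice-sampling update of each latent log-rate.

    Target (per site): y*eta - exp(eta) - (eta - m)^2 / (2 v), i.e. a
    Poisson likelihood times a Gaussian prior from the linear predictor.
    Stepping-out with unit width then shrinkage; log-concavity makes the
    update essentially rejection-free.
    """
    n = eta.shape[0]

    def logf(e):
        return y * e - np.exp(np.minimum(e, ETA_CLIP)) - (e - m) ** 2 / (2.0 * v)

    logu = logf(eta) + np.log(rng.random(n))
    L = eta - width * rng.random(n)
    R = L + width
    for _ in range(max_step):
        grow = logf(L) > logu
        if not grow.any():
            break
        L[grow] -= width
    for _ in range(max_step):
        grow = logf(R) > logu
        if not grow.any():
            break
        R[grow] += width
    out = eta.copy()
    todo = np.ones(n, dtype=bool)
    for _ in range(max_shrink):
        x = L + rng.random(n) * (R - L)
        ok = todo & (logf(x) >= logu)
        out[ok] = x[ok]
        todo &= ~ok
        if not todo.any():
            break
        lower = todo & (x < out)
        upper = todo & ~lower
        L[lower] = x[lower]
        R[upper] = x[upper]
    return out


# ---------------------------------------------------------------------------
# design helpers


def _dam_levels(ped: Pedigree, pos: np.ndarray) -> np.ndarray:
    """Dam grouping for phenotyped individuals.

    Individuals sharing a known dam share a level; each unknown-dam
    individual gets its own singleton level (no spurious pooling).
    """
    dams = ped.dam[pos]
    levels = {}
    idx = np.empty(len(pos), dtype=np.int64)
    for k, d in enumerate(dams):
        key = ("dam", int(d)) if d >= 0 else ("solo", k)
        idx[k] = levels.setdefault(key, len(levels))
    return idx


def _codes(values) -> np.ndarray:
    return pd.Categorical(values).codes.astype(np.int64)


def _eigen_a_obs(ped: Pedigree, pos: np.ndarray):
    A, _ = relationship_matrix(ped)
    A_obs = A[np.ix_(pos, pos)]
    lam, U = np.linalg.eigh(A_obs)
    lam = np.clip(lam, 1e-10, None)
    return U, lam


# ---------------------------------------------------------------------------
# univariate engine


class _ScalarTerm:
    """One scalar-variance random term with parameter expansion.

    Stored as working effects ``u~`` (rotated to the eigenbasis for the
    genetic term) with variance ``V~`` and a working scale ``g``;
    reported variance is ``g^2 V~`` and fitted effects ``g u~``.
    """

    def __init__(self, name, n_levels, priors, rng, lam=None, U=None, level_idx=None):
        self.name = name
        self.k = n_levels
        self.lam = lam              # eigenvalues of A_obs (genetic term only)
        self.U = U
        self.idx = level_idx        # level index per record (non-genetic terms)
        self.priors = priors
        self.u = np.zeros(n_levels)
        self.g = 1.0 + 0.1 * rng.standard_normal()
        self.vt = priors.V0

    @property
    def variance(self) -> float:
        return self.g * self.g * self.vt

    def fitted(self) -> np.ndarray:
        """Per-record contribution to the linear predictor."""
        if self.U is not None:
            return self.g * (self.U @ self.u)
        return self.g * self.u[self.idx]

    def update(self, resid_plus_self, v_r, rng):
        """Gibbs-update effects, working scale and variance.

        ``resid_plus_self`` is the working response minus every other
        model component (i.e. the residual with this term added back).
        """
        pri = self.priors
        g2 = self.g * self.g
        if self.U is not None:
            r = self.U.T @ resid_plus_self
            prec = g2 / v_r + 1.0 / (self.vt * self.lam)
            mean = (self.g / v_r) * r / prec
            self.u = mean + rng.standard_normal(self.k) / np.sqrt(prec)
            x = self.U @ self.u
        else:
            counts = np.bincount(self.idx, minlength=self.k)
            sums = np.bincount(self.idx, weights=resid_plus_self, minlength=self.k)
            prec = counts * g2 / v_r + 1.0 / self.vt
            mean = (self.g / v_r) * sums / prec
            self.u = mean + rng.standard_normal(self.k) / np.sqrt(prec)
            x = self.u[self.idx]
        # working-scale update: regression of the residual on the raw effects
        gprec = float(x @ x) / v_r + 1.0 / pri.px_var
        gmean = float(x @ resid_plus_self) / v_r / gprec
        self.g = gmean + rng.standard_normal() / np.sqrt(gprec)
        # working-variance update (scaled-inverse-chi-square)
        ss = float(self.u @ (self.u / self.lam)) if self.lam is not None \
            else float(self.u @ self.u)
        self.vt = _sample_invgamma(
            rng, 0.5 * (pri.nu + self.k), 0.5 * (pri.nu * pri.V0 + ss)
        )
        return self.g * x


def _run_univariate(
    y,
    family,
    X,
    terms,
    priors,
    settings,
    store_ebv=False,
    genetic_name="animal",
    extra_names=None,
):
    """Shared Gibbs loop for univariate models.

    ``terms`` is an ordered dict name -> _ScalarTerm.  Returns draws for
    the intercept / fixed effects, each term's variance and the residual
    variance; optionally per-individual breeding-value draws.
    """
    rng = np.random.default_rng(settings.seed)
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    beta = np.zeros(p)
    v_r = priors.V0
    if family == "poisson":
        eta = np.log1p(y)  # sensible start
    else:
        eta = y
    contrib = {name: t.fitted() for name, t in terms.items()}
    fixed_names = extra_names or [f"b{j}" for j in range(p)]

    n_keep = settings.n_draws
    draws = {nm: np.empty(n_keep) for nm in fixed_names}
    for name in terms:
        draws[f"V_{name}"] = np.empty(n_keep)
    draws["V_resid"] = np.empty(n_keep)
    ebv_draws = np.empty((n_keep, n)) if store_ebv and genetic_name in terms else None

    total = settings.burn_in + settings.n_iter
    kept = 0
    for it in range(total):
        pred_random = sum(contrib.values()) if contrib else 0.0
        if family == "poisson":
            m = X @ beta + pred_random
            eta = _slice_poisson_eta(eta, y, m, v_r, rng)
        # fixed effects
        resid = eta - pred_random
        prec = XtX / v_r + np.eye(p) / priors.fixed_var
        rhs = X.T @ resid / v_r
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        fixed_part = X @ beta
        # random terms
        base = eta - fixed_part
        for name, t in terms.items():
            others = sum(v for k, v in contrib.items() if k != name)
            contrib[name] = t.update(base - others, v_r, rng)
        # residual variance
        resid = base - (sum(contrib.values()) if contrib else 0.0)
        v_r = _sample_invgamma(
            rng,
            0.5 * (priors.nu + n),
            0.5 * (priors.nu * priors.V0 + float(resid @ resid)),
        )
        if not np.isfinite(v_r) or v_r > 1e12:
            raise ModelError(f"residual variance diverged at iteration {it}")
        k = it - settings.burn_in
        if k >= 0 and (k + 1) % settings.thin == 0:
            for j, nm in enumerate(fixed_names):
                draws[nm][kept] = beta[j]
            for name, t in terms.items():
                draws[f"V_{name}"][kept] = t.variance
            draws["V_resid"][kept] = v_r
            if ebv_draws is not None:
                ebv_draws[kept] = contrib[genetic_name]
            kept += 1
    return draws, ebv_draws


def _prepare_animal(data, ped, response, id_col, cohort_col):
    ids = data[id_col].to_numpy()
    pos = ped.positions(ids)
    y = data[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ModelError(f"non-finite values in response {response!r}")
    return ids, pos, y


def _build_terms(ped, pos, data, cohort_col, priors, rng, dam=True, cohort=True):
    U, lam = _eigen_a_obs(ped, pos)
    n = len(pos)
    terms = {"A": _ScalarTerm("A", n, priors, rng, lam=lam, U=U)}
    if dam:
        didx = _dam_levels(ped, pos)
        terms["dam"] = _ScalarTerm(
            "dam", int(didx.max()) + 1, priors, rng, level_idx=didx
        )
    if cohort:
        cidx = _codes(data[cohort_col])
        terms["cohort"] = _ScalarTerm(
            "cohort", int(cidx.max()) + 1, priors, rng, level_idx=cidx
        )
    return terms


def fit_gaussian_animal_model(
    data: pd.DataFrame,
    ped: Pedigree,
    response: str = "size_z",
    *,
    id_col: str = "id",
    cohort_col: str = "cohort",
    dam: bool = True,
    cohort: bool = True,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    store_ebv: bool = True,
) -> PosteriorSamples:
    """Univariate Gaussian animal model (intercept + A + dam + cohort).

    Returns draws of ``intercept``, ``V_A``, ``V_dam``, ``V_cohort`` and
    ``V_resid`` (terms present), plus per-individual breeding values when
    ``store_ebv``.
    """
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    ids, pos, y = _prepare_animal(data, ped, response, id_col, cohort_col)
    if np.ptp(y) == 0:
        raise ModelError("response is constant; nothing to partition")
    rng = np.random.default_rng(settings.seed + 1)
    terms = _build_terms(ped, pos, data, cohort_col, priors, rng, dam, cohort)
    X = np.ones((len(y), 1))
    draws, ebv = _run_univariate(
        y, "gaussian", X, terms, priors, settings,
        store_ebv=store_ebv, genetic_name="A", extra_names=["intercept"],
    )
    return PosteriorSamples(
        params=draws,
        ebv=ebv,
        ebv_ids=ids if ebv is not None else None,
        meta={"family": "gaussian", "response": response,
              "settings": settings, "terms": list(terms)},
    )


def fit_poisson_animal_model(
    data: pd.DataFrame,
    ped: Pedigree,
    response: str = "lrs",
    *,
    id_col: str = "id",
    cohort_col: str = "cohort",
    dam: bool = True,
    cohort: bool = True,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    store_ebv: bool = False,
) -> PosteriorSamples:
    """Univariate Poisson log-link animal model with latent
    overdispersion; same random-effects structure as the Gaussian fit.
    All variance components are reported on the latent scale."""
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    ids, pos, y = _prepare_animal(data, ped, response, id_col, cohort_col)
    _check_counts(y)
    rng = np.random.default_rng(settings.seed + 1)
    terms = _build_terms(ped, pos, data, cohort_col, priors, rng, dam, cohort)
    X = np.ones((len(y), 1))
    draws, ebv = _run_univariate(
        y, "poisson", X, terms, priors, settings,
        store_ebv=store_ebv, genetic_name="A", extra_names=["intercept"],
    )
    return PosteriorSamples(
        params=draws,
        ebv=ebv,
        ebv_ids=ids if ebv is not None else None,
        meta={"family": "poisson", "response": response,
              "settings": settings, "terms": list(terms)},
    )


def fit_glmm(
    y,
    X,
    *,
    family: str = "poisson",
    group=None,
    fixed_names=None,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
) -> PosteriorSamples:
    """Mixed model without a pedigree term (used by the selection fit).

    ``group`` optionally adds one scalar random intercept term (e.g.
    cohort); a latent residual always provides overdispersion for the
    Poisson family.
    """
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if family == "poisson":
        _check_counts(y)
    rng = np.random.default_rng(settings.seed + 1)
    terms = {}
    if group is not None:
        gidx = _codes(group)
        terms["cohort"] = _ScalarTerm(
            "cohort", int(gidx.max()) + 1, priors, rng, level_idx=gidx
        )
    draws, _ = _run_univariate(
        y, family, X, terms, priors, settings, extra_names=fixed_names
    )
    return PosteriorSamples(
        params=draws, meta={"family": family, "settings": settings}
    )


def heritability(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw narrow-sense heritability V_A / (sum of all components).

    Draws with zero total variance are excluded (with a warning).
    """
    names = [k for k in samples.params if k.startswith("V_")]
    need = {"V_A", "V_resid"}
    if not need <= set(names):
        raise ValueError("heritability requires a fit with V_A and V_resid")
    total = sum(np.asarray(samples[k], dtype=float) for k in names)
    va = np.asarray(samples["V_A"], dtype=float)
    ok = total > 0
    if not ok.all():
        log.warning("excluding %d zero-total-variance draws", (~ok).sum())
    return va[ok] / total[ok]


# ---------------------------------------------------------------------------
# bivariate engine


def _solve2x2_sample(p11, p12, p22, r1, r2, rng):
    """Vectorised draw from N(P^-1 r, P^-1) for stacked 2x2 precisions."""
    det = p11 * p22 - p12 * p12
    m1 = (p22 * r1 - p12 * r2) / det
    m2 = (p11 * r2 - p12 * r1) / det
    l11 = np.sqrt(p11)
    l21 = p12 / l11
    l22 = np.sqrt(p22 - l21 * l21)
    z1 = rng.standard_normal(np.shape(p11))
    z2 = rng.standard_normal(np.shape(p11))
    x2 = z2 / l22
    x1 = (z1 - l21 * x2) / l11
    return m1 + x1, m2 + x2


def _inv2(M):
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


def _sample_invwishart2(rng, df: float, S: np.ndarray) -> np.ndarray:
    """Draw from IW(df, S) for 2x2 scale matrices via the Bartlett
    decomposition of the corresponding Wishart(df, S^-1) draw.

    Much cheaper than the generic scipy sampler inside a Gibbs loop.
    """
    V = _inv2(S)  # Wishart scale
    # Cholesky of V
    l11 = np.sqrt(V[0, 0])
    l21 = V[1, 0] / l11
    l22 = np.sqrt(V[1, 1] - l21 * l21)
    a11 = np.sqrt(rng.chisquare(df))
    a22 = np.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    # T = L @ A (lower triangular); W = T T'
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    W = np.array(
        [[t11 * t11, t11 * t21], [t11 * t21, t21 * t21 + t22 * t22]]
    )
    return _inv2(W)


def fit_bivariate_animal_model(
    data: pd.DataFrame,
    ped: Pedigree,
    responses=("size_z", "lrs"),
    families=("gaussian", "poisson"),
    *,
    id_col: str = "id",
    cohort_col: str = "cohort",
    dam: bool = True,
    cohort: bool = True,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    store_ebv: bool = False,
) -> PosteriorSamples:
    """Bivariate animal model with an unstructured 2x2 covariance matrix
    per random term (additive genetic, dam, cohort, residual).

    Missing values (NaN in either response column) are handled by data
    augmentation, so traits need not be
    observed on the same individuals.  Draws are returned per term as
    ``V_<term>_t1``, ``V_<term>_t2`` and ``cov_<term>`` with trait order
    as given in ``responses``.
    """
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    if len(responses) != 2 or len(families) != 2:
        raise ValueError("exactly two responses/families required")
    for f in families:
        if f not in ("gaussian", "poisson"):
            raise ValueError(f"unsupported family {f!r}")
    rng = np.random.default_rng(settings.seed)
    ids = data[id_col].to_numpy()
    pos = ped.positions(ids)
    n = len(pos)

    raw = np.column_stack([data[r].to_numpy(dtype=float) for r in responses])
    obs = np.isfinite(raw)
    counts = {}
    for t, fam in enumerate(families):
        if fam == "poisson":
            yt = raw[obs[:, t], t]
            _check_counts(yt)
            counts[t] = raw[:, t]
    if not (obs.any(axis=0).all()):
        raise ModelError("each trait needs at least one observation")

    U, lam = _eigen_a_obs(ped, pos)
    didx = _dam_levels(ped, pos) if dam else None
    cidx = _codes(data[cohort_col]) if cohort else None

    # initial working responses: observed data / log1p(counts); zeros for missing
    Y = np.where(obs, raw, 0.0)
    for t, fam in enumerate(families):
        if fam == "poisson":
            Y[:, t] = np.where(obs[:, t], np.log1p(np.where(obs[:, t], raw[:, t], 0)), 0.0)

    S0 = priors.iw_scale * np.eye(2)
    df0 = priors.iw_df
    # per term: working covariance G~, per-trait working scales g (parameter
    # expansion; reported covariance is diag(g) G~ diag(g))
    Gt = {"A": np.eye(2) * 0.5}
    gsc = {"A": 1.0 + 0.1 * rng.standard_normal(2)}
    raw_eff = {"A": np.zeros((n, 2))}   # unscaled per-record effects
    alpha = np.zeros((n, 2))
    u_dam = u_coh = None
    if dam:
        n_dam = int(didx.max()) + 1
        Gt["dam"] = np.eye(2) * 0.5
        gsc["dam"] = 1.0 + 0.1 * rng.standard_normal(2)
        u_dam = np.zeros((n_dam, 2))
        raw_eff["dam"] = np.zeros((n, 2))
    if cohort:
        n_coh = int(cidx.max()) + 1
        Gt["cohort"] = np.eye(2) * 0.5
        gsc["cohort"] = 1.0 + 0.1 * rng.standard_normal(2)
        u_coh = np.zeros((n_coh, 2))
        raw_eff["cohort"] = np.zeros((n, 2))
    R = np.eye(2) * 0.5
    mu = np.zeros(2)

    def fitted(term):
        return raw_eff[term] * gsc[term]

    def reported(term):
        Dg = np.diag(gsc[term])
        return Dg @ Gt[term] @ Dg

    n_keep = settings.n_draws
    pnames = ["intercept_t1", "intercept_t2"]
    draws = {nm: np.empty(n_keep) for nm in pnames}
    for term in list(Gt) + ["resid"]:
        for suffix in ("t1", "t2"):
            draws[f"V_{term}_{suffix}"] = np.empty(n_keep)
        draws[f"cov_{term}"] = np.empty(n_keep)
    ebv_draws = np.empty((n_keep, n, 2)) if store_ebv else None

    def sample_scales(term, E, rng):
        """Gibbs draw of the working scales: a bivariate regression of
        the residual-plus-term on the raw effects (likelihood coupled
        through the residual covariance)."""
        x = raw_eff[term]
        P11 = Rinv[0, 0] * float(x[:, 0] @ x[:, 0]) + 1.0 / priors.px_var
        P12 = Rinv[0, 1] * float(x[:, 0] @ x[:, 1])
        P22 = Rinv[1, 1] * float(x[:, 1] @ x[:, 1]) + 1.0 / priors.px_var
        r1 = Rinv[0, 0] * float(x[:, 0] @ E[:, 0]) + Rinv[0, 1] * float(x[:, 0] @ E[:, 1])
        r2 = Rinv[1, 0] * float(x[:, 1] @ E[:, 0]) + Rinv[1, 1] * float(x[:, 1] @ E[:, 1])
        g1, g2 = _solve2x2_sample(P11, P12, P22, r1, r2, rng)
        gsc[term] = np.array([float(g1), float(g2)])

    kept = 0
    total = settings.burn_in + settings.n_iter
    for it in range(total):
        all_fit = {term: fitted(term) for term in Gt}
        pred = mu + sum(all_fit.values())
        Rinv = _inv2(R)
        # --- latent / missing updates, trait by trait
        for t in range(2):
            o = 1 - t
            ccoef = R[t, o] / R[o, o]
            cvar = R[t, t] - R[t, o] * ccoef
            mcond = pred[:, t] + ccoef * (Y[:, o] - pred[:, o])
            if families[t] == "poisson":
                eta = Y[:, t].copy()
                m_obs = obs[:, t]
                if m_obs.any():
                    eta[m_obs] = _slice_poisson_eta(
                        eta[m_obs], counts[t][m_obs], mcond[m_obs], cvar, rng
                    )
                miss = ~m_obs
                if miss.any():
                    eta[miss] = mcond[miss] + np.sqrt(cvar) * rng.standard_normal(miss.sum())
                Y[:, t] = eta
            else:
                miss = ~obs[:, t]
                if miss.any():
                    Y[miss, t] = mcond[miss] + np.sqrt(cvar) * rng.standard_normal(miss.sum())
        # --- intercepts
        E = Y - sum(all_fit.values())
        P = n * Rinv + np.eye(2) / priors.fixed_var
        rhs = Rinv @ E.sum(axis=0)
        m1, m2 = _solve2x2_sample(P[0, 0], P[0, 1], P[1, 1], rhs[0], rhs[1], rng)
        mu = np.array([float(m1), float(m2)])
        # --- genetic block (rotated; diagonal per-individual 2x2 systems)
        E = Y - mu - sum(v for k, v in all_fit.items() if k != "A")
        Rt = U.T @ E
        g1s, g2s = gsc["A"]
        Ginv = _inv2(Gt["A"])
        inv_lam = 1.0 / lam
        p11 = g1s * g1s * Rinv[0, 0] + Ginv[0, 0] * inv_lam
        p12 = g1s * g2s * Rinv[0, 1] + Ginv[0, 1] * inv_lam
        p22 = g2s * g2s * Rinv[1, 1] + Ginv[1, 1] * inv_lam
        r1 = g1s * (Rinv[0, 0] * Rt[:, 0] + Rinv[0, 1] * Rt[:, 1])
        r2 = g2s * (Rinv[1, 0] * Rt[:, 0] + Rinv[1, 1] * Rt[:, 1])
        a1, a2 = _solve2x2_sample(p11, p12, p22, r1, r2, rng)
        alpha = np.column_stack([a1, a2])
        raw_eff["A"] = U @ alpha
        sample_scales("A", E, rng)
        S = (alpha * inv_lam[:, None]).T @ alpha
        Gt["A"] = _sample_invwishart2(rng, df0 + n, S0 + S)
        all_fit["A"] = fitted("A")
        # --- dam / cohort blocks
        for term, uarr, idx in (("dam", u_dam, didx), ("cohort", u_coh, cidx)):
            if term not in Gt:
                continue
            E = Y - mu - sum(v for k, v in all_fit.items() if k != term)
            k_levels = uarr.shape[0]
            g1s, g2s = gsc[term]
            cnt = np.bincount(idx, minlength=k_levels).astype(float)
            s1 = np.bincount(idx, weights=E[:, 0], minlength=k_levels)
            s2 = np.bincount(idx, weights=E[:, 1], minlength=k_levels)
            Ginv_t = _inv2(Gt[term])
            p11 = cnt * g1s * g1s * Rinv[0, 0] + Ginv_t[0, 0]
            p12 = cnt * g1s * g2s * Rinv[0, 1] + Ginv_t[0, 1]
            p22 = cnt * g2s * g2s * Rinv[1, 1] + Ginv_t[1, 1]
            r1 = g1s * (Rinv[0, 0] * s1 + Rinv[0, 1] * s2)
            r2 = g2s * (Rinv[1, 0] * s1 + Rinv[1, 1] * s2)
            g1, g2 = _solve2x2_sample(p11, p12, p22, r1, r2, rng)
            uarr[:, 0], uarr[:, 1] = g1, g2
            raw_eff[term] = uarr[idx]
            sample_scales(term, E, rng)
            S = uarr.T @ uarr
            Gt[term] = _sample_invwishart2(rng, df0 + k_levels, S0 + S)
            all_fit[term] = fitted(term)
        # --- residual covariance
        E = Y - mu - sum(all_fit.values())
        R = _sample_invwishart2(rng, df0 + n, S0 + E.T @ E)
        if not np.all(np.isfinite(R)) or R[0, 0] > 1e12 or R[1, 1] > 1e12:
            raise ModelError(f"residual covariance diverged at iteration {it}")
        k = it - settings.burn_in
        if k >= 0 and (k + 1) % settings.thin == 0:
            draws["intercept_t1"][kept] = mu[0]
            draws["intercept_t2"][kept] = mu[1]
            for term in Gt:
                M = reported(term)
                draws[f"V_{term}_t1"][kept] = M[0, 0]
                draws[f"V_{term}_t2"][kept] = M[1, 1]
                draws[f"cov_{term}"][kept] = M[0, 1]
            draws["V_resid_t1"][kept] = R[0, 0]
            draws["V_resid_t2"][kept] = R[1, 1]
            draws["cov_resid"][kept] = R[0, 1]
            if ebv_draws is not None:
                ebv_draws[kept] = fitted("A")
            kept += 1

    return PosteriorSamples(
        params=draws,
        ebv=ebv_draws[:, :, 0] if ebv_draws is not None else None,
        ebv_ids=ids if ebv_draws is not None else None,
        meta={
            "family": "bivariate",
            "responses": tuple(responses),
            "families": tuple(families),
            "settings": settings,
            "terms": list(Gt) + ["resid"],
        },
    )
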