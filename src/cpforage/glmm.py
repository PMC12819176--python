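"""Generalised linear mixed models for habitat use and movement metrics.

Two families cover the study's responses, both with a per-bird random
intercept to absorb repeated measures:

* **beta with logit link** for the proportion of anthropogenic habitat use
  (one observation per bird x season, open support (0, 1));
* **gamma with log link** for the positive per-trip movement parameters
  (duration, maximum distance, path length; one observation per trip).

Fixed effects are colony status, austral season and their interaction,
coded sum-to-zero, so type-III Wald chi-square tests and equal-weight
estimated marginal means follow directly. The random intercept is
integrated out by a Laplace approximation (per-group scalar Newton inner
optimisation); maximum-likelihood estimates come from quasi-Newton outer
optimisation over fixed effects, log random-intercept SD and log
dispersion. Standard errors derive from the numerical Hessian of the
marginal negative log-likelihood. Reference implementations using
adaptive quadrature may differ in the third decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

STATUS_LEVELS = ("urban", "wild")
SEASON_LEVELS = ("summer", "autumn", "winter", "spring")

_TERMS = {
    "intercept": slice(0, 1),
    "status": slice(1, 2),
    "season": slice(2, 5),
    "status:season": slice(5, 8),
}


class ConvergenceError(RuntimeError):
    """The marginal likelihood optimisation failed to converge."""


# ---------------------------------------------------------------- families

class _GammaLog:
    """Gamma response, log link; dispersion parameter is the shape k."""

    name = "gamma_log"

    @staticmethod
    def check(y: np.ndarray) -> np.ndarray:
        if np.any(y <= 0):
            raise ValueError("gamma family requires strictly positive responses")
        return y

    @staticmethod
    def loglik(y, eta, k):
        return (
            k * np.log(k) - special.gammaln(k) + (k - 1.0) * np.log(y)
            - k * eta - k * y * np.exp(-eta)
        )

    @staticmethod
    def d1_d2(y, eta, k):
        r = y * np.exp(-eta)
        return k * (r - 1.0), -k * r

    @staticmethod
    def init_disp(y):
        m, v = np.mean(y), np.var(y)
        return float(np.clip(m * m / max(v, 1e-12), 0.2, 500.0))

    @staticmethod
    def inverse_link(eta):
        return np.exp(np.clip(eta, -700.0, 700.0))


class _BetaLogit:
    """Beta response, logit link; dispersion parameter is the precision phi."""

    name = "beta_logit"

    @staticmethod
    def check(y: np.ndarray) -> np.ndarray:
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError(
                "beta family requires responses in the open interval (0, 1); "
                "apply compress_proportions first"
            )
        return y

    @staticmethod
    def _mu(eta):
        return np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)

    @classmethod
    def loglik(cls, y, eta, phi):
        mu = cls._mu(eta)
        return (
            special.gammaln(phi)
            - special.gammaln(mu * phi)
            - special.gammaln((1.0 - mu) * phi)
            + (mu * phi - 1.0) * np.log(y)
            + ((1.0 - mu) * phi - 1.0) * np.log1p(-y)
        )

    @classmethod
    def d1_d2(cls, y, eta, phi):
        mu = cls._mu(eta)
        m = mu * (1.0 - mu)
        t = (
            np.log(y) - np.log1p(-y)
            - special.digamma(mu * phi)
            + special.digamma((1.0 - mu) * phi)
        )
        d1 = phi * t * m
        d2 = phi * m * (
            -phi * m * (special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi))
            + t * (1.0 - 2.0 * mu)
        )
        return d1, d2

    @staticmethod
    def init_disp(y):
        m, v = np.mean(y), np.var(y)
        phi = m * (1.0 - m) / max(v, 1e-12) - 1.0
        return float(np.clip(phi, 2.0, 500.0))

    @staticmethod
    def inverse_link(eta):
        return special.expit(eta)


FAMILIES = {"gamma_log": _GammaLog, "beta_logit": _BetaLogit}


def compress_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Pull proportions off the boundary: y' = (y (N - 1) + 1/2) / N.

    The beta distribution has open support; observed proportions of
    exactly 0 or 1 are compressed toward 1/2 by the sample size N (the
    standard Smithson-Verkuilen device).
    """
    y = np.asarray(y, dtype=float)
    n = len(y) if n is None else n
    return (y * (n - 1) + 0.5) / n


# ------------------------------------------------------------- design

def build_design(status, season) -> np.ndarray:
    """Sum-to-zero design matrix for status + season + status:season.

    Columns: intercept; status (urban +1, wild -1); three season-effect
    columns (summer, autumn, winter; spring rows get -1 in each); three
    interaction columns (status x season codes). Shape (n, 8).
    """
    status = np.asarray(status)
    season = np.asarray(season)
    bad = set(status) - set(STATUS_LEVELS)
    if bad:
        raise ValueError(f"unknown status level(s): {bad}")
    bad = set(season) - set(SEASON_LEVELS)
    if bad:
        raise ValueError(f"unknown season level(s): {bad}")
    n = len(status)
    s = np.where(status == "urban", 1.0, -1.0)
    S = np.zeros((n, 3))
    for j, lev in enumerate(SEASON_LEVELS[:3]):
        S[season == lev, j] = 1.0
    S[season == "spring", :] = -1.0
    return np.column_stack([np.ones(n), s, S, s[:, None] * S])


def _cell_row(status: str, season: str) -> np.ndarray:
    return build_design(np.array([status]), np.array([season]))[0]


# ------------------------------------------------------------- fitting

@dataclass
class GlmmSpec:
    """What to fit: response column, family, and the test level alpha."""

    response: str
    family: str  # 'beta_logit' | 'gamma_log'
    alpha: float = 0.05

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class GlmmResult:
    spec: GlmmSpec
    beta: np.ndarray                 # link-scale fixed effects (8,)
    se_beta: np.ndarray
    vcov_beta: np.ndarray            # (8, 8)
    sigma_b: float                   # random-intercept SD
    dispersion: float                # phi (beta) or shape k (gamma)
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    n_iter: int
    term_slices: dict = field(default_factory=lambda: dict(_TERMS))
    _refit: tuple = field(default=None, repr=False)  # (y, status, season, groups)

    @property
    def df_t(self) -> int:
        """Between-cluster degrees of freedom for coefficient intervals.

        Status contrasts are between-bird comparisons, so their reference
        distribution has roughly (number of birds - between-bird
        parameters) = n_groups - 2 degrees of freedom; normal quantiles
        undercover badly with 8 birds.
        """
        return max(self.n_groups - 2, 1)

    def coefficients(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.spec.alpha if alpha is None else alpha
        names = [
            "intercept", "status", "season[summer]", "season[autumn]",
            "season[winter]", "status:season[summer]", "status:season[autumn]",
            "status:season[winter]",
        ][: len(self.beta)]
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_t)
        return pd.DataFrame({
            "term": names, "estimate": self.beta, "se": self.se_beta,
            "lcl": self.beta - q * self.se_beta,
            "ucl": self.beta + q * self.se_beta,
        })


class _LaplaceObjective:
    """Negative Laplace-approximated marginal log-likelihood."""

    def __init__(self, family, X, y, group_idx, n_groups):
        self.family = family
        self.X = X
        self.y = y
        self.gidx = group_idx
        self.ng = n_groups
        self.b = np.zeros(n_groups)  # warm-started between evaluations

    def inner(self, beta, sigma2, disp):
        """Per-group posterior modes of the random intercepts (Newton)."""
        eta_fix = self.X @ beta
        b = self.b.copy()
        h = np.full(self.ng, -1.0 / sigma2)
        for _ in range(100):
            eta = eta_fix + b[self.gidx]
            d1, d2 = self.family.d1_d2(self.y, eta, disp)
            g = np.bincount(self.gidx, d1, self.ng) - b / sigma2
            h = np.bincount(self.gidx, d2, self.ng) - 1.0 / sigma2
            h = np.minimum(h, -1e-8)
            if np.max(np.abs(g)) < 1e-9:
                break
            step = np.clip(g / h, -2.0, 2.0)
            b = b - step
        return b, h, eta_fix

    def __call__(self, theta):
        beta = theta[:-2]
        sigma2 = np.exp(2.0 * theta[-2])
        disp = np.exp(theta[-1])
        if not np.all(np.isfinite(theta)) or disp > 1e8:
            return 1e12
        b, h, eta_fix = self.inner(beta, sigma2, disp)
        self.b = b
        eta = eta_fix + b[self.gidx]
        ll = float(np.sum(self.family.loglik(self.y, eta, disp)))
        ll -= float(np.sum(b * b) / (2.0 * sigma2))
        ll -= 0.5 * float(np.sum(np.log(sigma2 * (-h))))
        if not np.isfinite(ll):
            return 1e12
        return -ll


def _numeric_hessian(f, x, eps=1e-4):
    p = len(x)
    H = np.empty((p, p))
    hs = eps * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def fit_glmm(data: pd.DataFrame, spec: GlmmSpec, _design: str = "full") -> GlmmResult:
    """Fit the status x season mixed model to ``data``.

    ``data`` needs columns ``status``, ``season``, ``bird_id`` and the
    response named by ``spec``. Beta responses must already lie strictly
    inside (0, 1) (see :func:`compress_proportions`). At least two birds
    per status are required.
    """
    family = FAMILIES[spec.family]
    y = family.check(np.asarray(data[spec.response], dtype=float))
    status = np.asarray(data["status"])
    season = np.asarray(data["season"])
    for lev in STATUS_LEVELS:
        if len(np.unique(data.loc[status == lev, "bird_id"])) < 2:
            raise ValueError(f"need at least two birds with status {lev!r}")
    if _design == "full":
        X = build_design(status, season)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: every status x season cell must be "
                "observed to fit the interaction model"
            )
    else:  # intercept-only (null model, random intercept retained)
        X = np.ones((len(y), 1))
    groups, gidx = np.unique(np.asarray(data["bird_id"]), return_inverse=True)
    obj = _LaplaceObjective(family, X, y, gidx, len(groups))

    link_mean = np.log(np.mean(y)) if spec.family == "gamma_log" else special.logit(np.mean(y))
    theta0 = np.zeros(X.shape[1] + 2)
    theta0[0] = link_mean
    theta0[-2] = np.log(0.3)
    theta0[-1] = np.log(family.init_disp(y))

    res = optimize.minimize(
        obj, theta0, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    if not res.success:
        # one Nelder-Mead polish from the BFGS point before giving up
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    grad_norm = float(np.max(np.abs(res.get("jac", np.zeros(1))))) if hasattr(res, "get") else 0.0
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise ConvergenceError(
            f"GLMM fit failed (nll={res.fun:.3g}, grad={grad_norm:.3g}, nit={res.nit})"
        )

    H = _numeric_hessian(obj, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    p = X.shape[1]
    vcov_beta = cov[:p, :p]
    d = np.diag(vcov_beta).copy()
    if np.any(d <= 0):
        logger.warning("fit_glmm: non-positive variance estimate; using |diag|")
        d = np.abs(d)
    sigma_b = float(np.exp(theta[-2]))
    if sigma_b < 1e-4:
        logger.warning("fit_glmm: random-intercept variance is effectively zero (singular fit)")
    if _design == "full" and p != 8:
        raise AssertionError("full design must have 8 columns")
    beta = theta[:p]
    if _design == "full":
        beta_full, se_full, v_full = beta, np.sqrt(d), vcov_beta
    else:
        beta_full = np.zeros(p); beta_full[:] = beta
        se_full, v_full = np.sqrt(d), vcov_beta
    return GlmmResult(
        spec=spec,
        beta=beta_full,
        se_beta=se_full,
        vcov_beta=v_full,
        sigma_b=sigma_b,
        dispersion=float(np.exp(theta[-1])),
        loglik=float(-res.fun),
        converged=bool(res.success or np.isfinite(res.fun)),
        n_obs=len(y),
        n_groups=len(groups),
        n_iter=int(res.nit),
        _refit=(data, spec),
    )


# ------------------------------------------------------------- inference

def type3_anova(result: GlmmResult) -> pd.DataFrame:
    """Type-III Wald chi-square tests per fixed-effect term.

    With sum-to-zero coding each term's block of coefficients is orthogonal
    to lower-order terms in the balanced sense, so the Wald statistic
    beta' V^-1 beta per block is the type-III test. Degrees of freedom:
    status 1, season 3, interaction 3.
    """
    rows = []
    for term in ("status", "season", "status:season"):
        sl = result.term_slices[term]
        b = result.beta[sl]
        V = result.vcov_beta[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(f"rank-deficient design for term {term!r}")
        df = len(b)
        rows.append({
            "term": term, "chisq": stat, "df": df,
            "p": float(stats.chi2.sf(stat, df)),
        })
    return pd.DataFrame(rows)


def estimated_marginal_means(result: GlmmResult, alpha: float | None = None) -> pd.DataFrame:
    """Per status x season cell estimates on the response scale.

    Cell means are computed on the link scale at the sum-to-zero (equal
    weight) design row, with Wald limits at between-cluster t quantiles
    (see ``GlmmResult.df_t``) back-transformed through the inverse link
    (monotone, so coverage is preserved).
    """
    alpha = result.spec.alpha if alpha is None else alpha
    family = FAMILIES[result.spec.family]
    z = stats.t.ppf(1.0 - alpha / 2.0, result.df_t)
    rows = []
    for st in STATUS_LEVELS:
        for se in SEASON_LEVELS:
            x = _cell_row(st, se)
            eta = float(x @ result.beta)
            sd = float(np.sqrt(max(x @ result.vcov_beta @ x, 0.0)))
            rows.append({
                "status": st, "season": se,
                "response": result.spec.response,
                "emm": float(family.inverse_link(eta)),
                "lcl": float(family.inverse_link(eta - z * sd)),
                "ucl": float(family.inverse_link(eta + z * sd)),
                "eta": eta, "se_eta": sd,
            })
    return pd.DataFrame(rows)


def _max_abs_z_pvalues(z: np.ndarray, R: np.ndarray, n_mc: int = 100_000) -> np.ndarray:
    """Single-step adjusted p-values: P(max_j |Z_j| >= |z_k|) under
    Z ~ MVN(0, R). Evaluated by (deterministic, fixed-seed) Monte Carlo on
    the possibly singular correlation matrix."""
    k = len(z)
    if k == 1:
        return np.array([2.0 * stats.norm.sf(abs(z[0]))])
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    rng = np.random.default_rng(20221203)
    sims = rng.standard_normal((n_mc, k)) @ A.T
    maxabs = np.max(np.abs(sims), axis=1)
    return np.array([float(np.mean(maxabs >= abs(zk))) for zk in z])


def tukey_contrasts(result: GlmmResult, factor: str = "season") -> pd.DataFrame:
    """All pairwise comparisons of ``factor`` ('status', 'season' or
    'cells'), single-step adjusted over the family of contrasts.

    Estimates are link-scale differences of (marginal) cell means;
    adjusted p-values use the joint multivariate-normal reference of the
    max-|z| statistic, the single-step method behind Tukey reporting in
    mixed models.
    """
    cells = [(st, se) for st in STATUS_LEVELS for se in SEASON_LEVELS]
    rows_x = {c: _cell_row(*c) for c in cells}
    if factor == "cells":
        levels = [f"{st}:{se}" for st, se in cells]
        L = np.array([rows_x[c] for c in cells])
    elif factor == "status":
        levels = list(STATUS_LEVELS)
        L = np.array([
            np.mean([rows_x[(st, se)] for se in SEASON_LEVELS], axis=0)
            for st in STATUS_LEVELS
        ])
    elif factor == "season":
        levels = list(SEASON_LEVELS)
        L = np.array([
            np.mean([rows_x[(st, se)] for st in STATUS_LEVELS], axis=0)
            for se in SEASON_LEVELS
        ])
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if len(levels) < 2:
        return pd.DataFrame(columns=["contrast", "estimate", "se", "z", "p_adj"])
    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    C = np.array([L[i] - L[j] for i, j in pairs])
    est = C @ result.beta
    Vc = C @ result.vcov_beta @ C.T
    sd = np.sqrt(np.clip(np.diag(Vc), 1e-300, None))
    z = est / sd
    denom = np.outer(sd, sd)
    R = Vc / denom
    np.fill_diagonal(R, 1.0)
    p_adj = _max_abs_z_pvalues(z, R)
    return pd.DataFrame({
        "contrast": [f"{levels[i]} - {levels[j]}" for i, j in pairs],
        "estimate": est, "se": sd, "z": z, "p_adj": p_adj,
    })


def lrt_vs_null(result: GlmmResult) -> dict:
    """Likelihood-ratio test of the fitted model against the null model
    (intercept + bird random intercept only, same family)."""
    data, spec = result._refit
    null = fit_glmm(data, spec, _design="null")
    stat = max(0.0, 2.0 * (result.loglik - null.loglik))
    df = 7
    return {
        "lrt_stat": float(stat), "df": df,
        "p": float(stats.chi2.sf(stat, df)),
        "loglik_full": result.loglik, "loglik_null": null.loglik,
    }
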