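"""Mixed-effects comparison of ODBA across wetland types.

The model is a random-intercept linear mixed model,

    odba_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e)

with one random intercept per bird and treatment-coded wetland contrasts
against other tidal.  It is fitted by maximum likelihood (not REML, since
the interest is in the fixed effects): the variance ratio
lambda = s2_b / s2_e is profiled — generalized least squares gives the
fixed effects and the residual variance in closed form at any lambda, so
the deviance is a 1-D function of lambda, minimized by a coarse grid
followed by golden-section refinement.  The wetland model is compared to an
intercept-only model with a likelihood-ratio test, and per-coefficient
profile-likelihood confidence intervals are computed by bisection on the
profiled deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grids import CLASS_NAMES, REFERENCE_CLASS

log = logging.getLogger(__name__)

NONREFERENCE = tuple(c for c in CLASS_NAMES if c != REFERENCE_CLASS)


@dataclass
class LMMFit:
    """A fitted random-intercept model."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray            # conditional (on lambda-hat) covariance of beta
    sigma2_b: float
    sigma2_e: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool = True

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sqrt(self.cov[j, j]))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": np.asarray(self.beta).tolist(),
            "cov": np.asarray(self.cov).tolist(),
            "sigma2_b": self.sigma2_b,
            "sigma2_e": self.sigma2_e,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested ML fits."""

    chi2: float
    df: int
    p_value: float


def _design(records: pd.DataFrame, wetland_effect: bool):
    names = ["intercept"]
    cols = [np.ones(len(records))]
    if wetland_effect:
        wet = records["wetland"].astype(str).to_numpy()
        unknown = set(wet) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown wetland class(es): {sorted(unknown)}")
        for w in NONREFERENCE:
            names.append(w)
            cols.append((wet == w).astype(float))
    return np.column_stack(cols), names


class _ProfiledLMM:
    """Closed-form GLS machinery for one (y, X, groups) problem."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        codes, uniq = pd.factorize(groups, sort=True)
        self.y = y
        self.X = X
        self.codes = codes
        self.n, self.p = X.shape
        self.n_groups = len(uniq)
        self.sizes = np.bincount(codes).astype(float)

    def _gls(self, lam: float):
        """GLS at variance ratio lam; returns (beta, s2e, loglik)."""
        y, X, codes = self.y, self.X, self.codes
        c = lam / (1.0 + self.sizes * lam)          # per-group shrinkage
        gX = np.empty((self.n_groups, self.p))
        for j in range(self.p):
            gX[:, j] = np.bincount(codes, weights=X[:, j],
                                   minlength=self.n_groups)
        gy = np.bincount(codes, weights=y, minlength=self.n_groups)
        XtVX = X.T @ X - (gX * c[:, None]).T @ gX
        XtVy = X.T @ y - gX.T @ (c * gy)
        beta = np.linalg.solve(XtVX, XtVy)
        r = y - X @ beta
        gr = np.bincount(codes, weights=r, minlength=self.n_groups)
        rss = float(r @ r - gr @ (c * gr))          # r' V0^-1 r
        s2e = rss / self.n
        logdet = float(np.log1p(self.sizes * lam).sum())
        ll = -0.5 * (self.n * (np.log(2 * np.pi * s2e) + 1.0) + logdet)
        return beta, s2e, ll, XtVX

    def deviance(self, log_lam: float) -> float:
        return -2.0 * self._gls(np.exp(log_lam))[2]

    def fit(self, names: list[str]) -> LMMFit:
        # Coarse profile over lambda (including the s2_b = 0 boundary),
        # then golden-section refinement around the grid minimum.
        grid = np.r_[-np.inf, np.linspace(np.log(1e-8), np.log(1e4), 49)]
        dev = np.array([
            -2.0 * self._gls(0.0)[2],
            *(self.deviance(g) for g in grid[1:]),
        ])
        i = int(np.argmin(dev))
        if i == 0:
            lam_hat = 0.0
        else:
            lo = grid[i - 1] if i >= 2 else grid[1] - 2.0
            hi = grid[i + 1] if i + 1 < len(grid) else grid[-1] + 2.0
            log_lam = optimize.golden(self.deviance, brack=(lo, grid[i], hi)) \
                if dev[i] < min(dev[max(i - 1, 1)], dev[min(i + 1, len(dev) - 1)]) \
                else grid[i]
            lam_hat = float(np.exp(log_lam))
            if -2.0 * self._gls(lam_hat)[2] > dev[0]:
                lam_hat = 0.0
        beta, s2e, ll, XtVX = self._gls(lam_hat)
        cov = s2e * np.linalg.inv(XtVX)
        return LMMFit(
            names=names, beta=beta, cov=cov,
            sigma2_b=lam_hat * s2e, sigma2_e=s2e, loglik=ll,
            n_obs=self.n, n_groups=self.n_groups,
        )


def fit_lmm(records: pd.DataFrame, wetland_effect: bool = True) -> LMMFit:
    """ML fit of odba ~ wetland (or ~ 1) with a bird random intercept.

    ``records`` needs columns odba, wetland, bird_id.  At least two birds
    are required, and at least one bird must contribute more than one
    observation (otherwise the two variance components are confounded).
    """
    records = records.dropna(subset=["odba"])
    y = records["odba"].to_numpy(dtype=float)
    X, names = _design(records, wetland_effect)
    groups = records["bird_id"].to_numpy()
    prob = _ProfiledLMM(y, X, groups)
    if prob.n_groups < 2:
        raise ValueError("random intercept unidentifiable with a single bird")
    if np.all(prob.sizes <= 1):
        raise ValueError(
            "one observation per bird: sigma2_b and sigma2_e are confounded")
    if wetland_effect:
        present = set(records["wetland"].astype(str))
        missing = set(CLASS_NAMES) - present
        if missing:
            raise ValueError(f"wetland class(es) absent from data: {sorted(missing)}")
    return prob.fit(names)


def lrt(full: LMMFit, null: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits (chi2 on the df difference)."""
    if set(null.names) - set(full.names) or len(null.names) > len(full.names):
        raise ValueError("null model must be nested in the full model")
    if full.n_obs != null.n_obs:
        raise ValueError("fits are not on the same data")
    if full.loglik < null.loglik - 1e-6:
        raise ValueError("full model log-likelihood below the null: "
                         "non-nested models or non-convergence")
    chi2 = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = len(full.names) - len(null.names)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p_value=p)


def fixed_effect_ci(
    records: pd.DataFrame,
    fit: LMMFit,
    level: float = 0.95,
) -> pd.DataFrame:
    """Profile-likelihood CIs for the fixed effects.

    For each coefficient, the constrained deviance (profiling all other
    fixed effects and both variances) is compared with the unconstrained
    one; the interval endpoints solve profile-deviance difference =
    chi2_1(level) by root bisection.  Falls back to Wald (logged) when
    profiling fails on a side.
    """
    wetland_effect = len(fit.names) > 1
    records = records.dropna(subset=["odba"])
    y = records["odba"].to_numpy(dtype=float)
    X, names = _design(records, wetland_effect)
    groups = records["bird_id"].to_numpy()
    cutoff = stats.chi2.ppf(level, 1)

    rows = []
    for j, name in enumerate(names):
        est = float(fit.beta[j])
        se = float(np.sqrt(fit.cov[j, j]))
        others = [k for k in range(X.shape[1]) if k != j]

        def profile_dev(c: float) -> float:
            sub = _ProfiledLMM(y - c * X[:, j], X[:, others], groups)
            f = sub.fit([names[k] for k in others])
            return -2.0 * f.loglik

        base = -2.0 * fit.loglik

        def diff(c: float) -> float:
            return profile_dev(c) - base - cutoff

        bounds = []
        for sign in (-1.0, 1.0):
            lo_c, hi_c = est, est + sign * 2.0 * max(se, 1e-12)
            found = None
            for _ in range(40):
                if diff(hi_c) > 0:
                    found = optimize.brentq(diff, min(lo_c, hi_c),
                                            max(lo_c, hi_c), xtol=1e-8 * max(se, 1.0))
                    break
                lo_c, hi_c = hi_c, hi_c + sign * 2.0 * max(se, 1e-12)
            if found is None:
                log.warning("profile CI failed for %s; Wald fallback", name)
                found = est + sign * stats.norm.ppf(0.5 + level / 2.0) * se
            bounds.append(found)
        rows.append((name, est, min(bounds), max(bounds)))
    return pd.DataFrame(rows, columns=["term", "estimate", "lower", "upper"])
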