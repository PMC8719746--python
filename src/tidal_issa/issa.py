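"""Integrated step-selection analysis (iSSA).

Each observed 10-min step is paired with available steps drawn from the
bird's own tentative movement kernel — gamma step lengths and von Mises
(mean 0) turn angles fitted to that bird's observed steps.  Habitat
selection is then estimated by conditional logistic regression: within each
stratum (one observed + its matched available steps) the probability that
the observed step was the one taken is

    exp(x_used' b) / sum_j exp(x_j' b)

and the stratified partial log-likelihood is maximized by Newton-Raphson
with analytic gradient/Hessian and step-halving.  Candidate models combining
wetland class at the step's end with a quadratic in time-specific water
depth are compared by AICc; relative selection strength (RSS) between a
wetland class and the reference (other tidal) is computed from the fitted
coefficients with delta-method confidence bands; and the tentative
step-length kernel is corrected with the fitted step-length coefficients to
remove the imprint of habitat selection on movement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .grids import CLASS_NAMES, REFERENCE_CLASS, ElevationGrid, HabitatGrid
from .landscape import TideSeries
from .tracks import _wrap_angle

log = logging.getLogger(__name__)

KAPPA_CAP = 500.0
SEPARATION_BETA = 15.0
NONREFERENCE = tuple(c for c in CLASS_NAMES if c != REFERENCE_CLASS)


# ---------------------------------------------------------------------------
# movement kernels

@dataclass(frozen=True)
class MovementKernel:
    """Gamma step-length x von Mises turn-angle kernel.

    ``kind`` distinguishes the tentative kernel (fitted to raw observed
    steps) from a selection-corrected one.
    """

    shape: float       # gamma k
    scale: float       # gamma theta (m)
    kappa: float       # von Mises concentration, mean direction 0
    kind: str = "tentative"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError("gamma shape must be finite and positive")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("gamma scale must be finite and positive")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and non-negative")

    @property
    def mean_step_length(self) -> float:
        return self.shape * self.scale


def fit_gamma(step_lengths) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) for step lengths.

    Zero lengths are replaced by half the minimum positive length (the
    gamma density is supported on (0, inf)); the replacement is logged.
    """
    x = np.asarray(step_lengths, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 step lengths")
    if np.any(x < 0):
        raise ValueError("step lengths must be non-negative")
    n_zero = int((x == 0).sum())
    if n_zero == x.size:
        raise ValueError("all step lengths are zero; gamma fit undefined")
    if n_zero:
        x = np.where(x == 0, x[x > 0].min() / 2.0, x)
        log.info("fit_gamma: replaced %d zero lengths with half the minimum "
                 "positive length", n_zero)
    if np.ptp(x) == 0:
        raise ValueError("step lengths are constant; gamma fit degenerate")
    k, loc, theta = stats.gamma.fit(x, floc=0)
    if not (np.isfinite(k) and np.isfinite(theta) and k > 0 and theta > 0):
        raise RuntimeError(f"gamma fit failed to converge (k={k}, theta={theta})")
    return float(k), float(theta)


def fit_vonmises(turn_angles) -> float:
    """ML von Mises concentration with the mean direction fixed at 0.

    With a fixed mean, the sufficient statistic is Rbar = mean(cos a) and
    the ML kappa solves A(kappa) = I1(kappa)/I0(kappa) = Rbar.  Rbar <= 0
    gives kappa = 0 (no concentration); near-degenerate data are capped at
    kappa = 500 (logged).
    """
    a = np.asarray(turn_angles, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 10:
        raise ValueError("need at least 10 turn angles")
    rbar = float(np.mean(np.cos(a)))
    if rbar <= 0:
        return 0.0

    def resid(kappa: float) -> float:
        return special.i1e(kappa) / special.i0e(kappa) - rbar

    if resid(KAPPA_CAP) < 0:
        log.info("fit_vonmises: concentration capped at %g (Rbar=%.6f)",
                 KAPPA_CAP, rbar)
        return KAPPA_CAP
    if resid(1e-12) > 0:
        return 0.0
    return float(optimize.brentq(resid, 1e-12, KAPPA_CAP, xtol=1e-10))


def fit_tentative_kernel(observed_steps: pd.DataFrame) -> MovementKernel:
    """Tentative kernel for one bird, from raw observed steps.

    Fitted before any covariate filtering: the kernel describes movement
    capacity, not habitat selection.
    """
    k, theta = fit_gamma(observed_steps["step_length"].to_numpy())
    angles = observed_steps.loc[observed_steps["angle_defined"], "turn_angle"]
    kappa = fit_vonmises(angles.to_numpy())
    return MovementKernel(k, theta, kappa, kind="tentative")


def sample_available(
    observed_steps: pd.DataFrame,
    kernel: MovementKernel,
    n_avail: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pair each observed step with ``n_avail`` kernel-drawn available steps.

    Lengths ~ gamma(k, theta); turn angles ~ von Mises(0, kappa); each
    available end point is projected from the observed start point along
    (previous heading + angle).  Only steps with a defined previous heading
    participate.  Returns observed + available rows in one frame.
    """
    rng = np.random.default_rng() if rng is None else rng
    obs = observed_steps[observed_steps["angle_defined"]].reset_index(drop=True)
    n = len(obs)
    if n == 0:
        return obs.copy()
    lengths = rng.gamma(kernel.shape, kernel.scale, size=(n, n_avail))
    if kernel.kappa > 0:
        angles = rng.vonmises(0.0, kernel.kappa, size=(n, n_avail))
    else:
        angles = rng.uniform(-np.pi, np.pi, size=(n, n_avail))
    heading = _wrap_angle(obs["heading_prev"].to_numpy()[:, None] + angles)
    x_end = obs["x_start"].to_numpy()[:, None] + lengths * np.cos(heading)
    y_end = obs["y_start"].to_numpy()[:, None] + lengths * np.sin(heading)

    rep = obs.loc[obs.index.repeat(n_avail)].reset_index(drop=True)
    avail = rep.assign(
        case="available",
        x_end=x_end.ravel(),
        y_end=y_end.ravel(),
        step_length=lengths.ravel(),
        turn_angle=angles.ravel(),
        heading=heading.ravel(),
    )
    out = pd.concat([obs, avail], ignore_index=True)
    return out.sort_values(["stratum_id", "case"], kind="stable",
                           ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariates and design

def attach_covariates(
    steps: pd.DataFrame,
    habitat: HabitatGrid,
    elev: ElevationGrid,
    tide: TideSeries,
) -> pd.DataFrame:
    """Populate wetland_start, wetland_end and depth_end on step members.

    Available members whose end point falls off-grid (or in a masked-out
    cell) are removed; a stratum whose observed member is off-grid, or left
    with no available member, is dropped (logged).
    """
    g = habitat.geometry
    ix_e, iy_e, in_e = g.cell_index(steps["x_end"].to_numpy(), steps["y_end"].to_numpy())
    code_end = np.where(in_e, habitat.classes[iy_e % g.ny, ix_e % g.nx], -1)
    valid = in_e & (code_end >= 0)

    observed = steps["case"].to_numpy() == "observed"
    bad_obs_strata = set(steps.loc[observed & ~valid, "stratum_id"])
    if bad_obs_strata:
        log.info("attach_covariates: dropping %d strata with off-grid "
                 "observed end points", len(bad_obs_strata))
    kept = steps[valid & ~steps["stratum_id"].isin(bad_obs_strata)].copy()

    g2 = g  # start points share the grid
    ix_s, iy_s, in_s = g2.cell_index(kept["x_start"].to_numpy(), kept["y_start"].to_numpy())
    if not np.all(in_s):
        raise ValueError("step start point outside the grid")
    code_start = habitat.classes[iy_s, ix_s]

    ixk, iyk, _ = g.cell_index(kept["x_end"].to_numpy(), kept["y_end"].to_numpy())
    z_end = elev.values[iyk, ixk]
    h = tide.interpolate(kept["t_end"])
    kept["wetland_end"] = pd.Categorical.from_codes(
        habitat.classes[iyk, ixk], categories=list(CLASS_NAMES))
    kept["wetland_start"] = pd.Categorical.from_codes(code_start, categories=list(CLASS_NAMES))
    kept["depth_end"] = np.asarray(h) - z_end

    if (kept["case"] == "available").any():
        counts = kept.groupby("stratum_id", sort=False)["case"].agg(
            lambda s: (s == "available").sum())
        empty = counts[counts < 1].index
        if len(empty):
            log.info("attach_covariates: dropping %d strata with no "
                     "surviving available member", len(empty))
            kept = kept[~kept["stratum_id"].isin(empty)]
    return kept.reset_index(drop=True)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate conditional-logistic model, as a set of term groups."""

    name: str
    terms: tuple[str, ...]

    _KNOWN = ("wetland", "depth", "depth2", "wetland:depth", "wetland:depth2",
              "movement", "angle")

    def __post_init__(self) -> None:
        for t in self.terms:
            if t not in self._KNOWN:
                raise ValueError(f"unknown model term {t!r}")

    def column_names(self) -> list[str]:
        cols: list[str] = []
        if "wetland" in self.terms:
            cols += list(NONREFERENCE)
        if "depth" in self.terms:
            cols.append("depth")
        if "depth2" in self.terms:
            cols.append("depth2")
        if "wetland:depth" in self.terms:
            cols += [f"{w}:depth" for w in NONREFERENCE]
        if "wetland:depth2" in self.terms:
            cols += [f"{w}:depth2" for w in NONREFERENCE]
        if "movement" in self.terms:
            cols += ["step_length", "ln_step_length"]
            cols += [f"step_length:{w}_start" for w in NONREFERENCE]
            cols += [f"ln_step_length:{w}_start" for w in NONREFERENCE]
        if "angle" in self.terms:
            cols.append("cos_turn_angle")
        return cols


def candidate_set() -> list[ModelSpec]:
    """The seven habitat-selection candidate models (nested in the full)."""
    return [
        ModelSpec("wetland", ("wetland",)),
        ModelSpec("depth", ("depth",)),
        ModelSpec("depth_quadratic", ("depth", "depth2")),
        ModelSpec("wetland_depth", ("wetland", "depth")),
        ModelSpec("wetland_depth_quadratic", ("wetland", "depth", "depth2")),
        ModelSpec("wetland_x_depth", ("wetland", "depth", "wetland:depth")),
        ModelSpec("full", ("wetland", "depth", "depth2",
                           "wetland:depth", "wetland:depth2")),
    ]


def movement_spec(base: ModelSpec | None = None) -> ModelSpec:
    """The behavior model: the full habitat model plus step-length terms."""
    base = base if base is not None else candidate_set()[-1]
    return ModelSpec(base.name + "_movement", base.terms + ("movement",))


def adjusted_spec(base: ModelSpec | None = None) -> ModelSpec:
    """The fully movement-adjusted model: step-length terms plus cos(turn
    angle).

    With available steps sampled from a *fitted* kernel, the likelihood
    weight correcting the gamma misfit is exactly spanned by the step-length
    and ln(step-length) columns, and the one correcting the von Mises misfit
    by cos(turn angle); including all three makes the habitat coefficients
    insensitive to tentative-kernel error.
    """
    base = base if base is not None else candidate_set()[-1]
    return ModelSpec(base.name + "_adjusted",
                     base.terms + ("movement", "angle"))


def design_matrix(steps: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix (other_tidal reference) for one model."""
    for needed in ("wetland_end", "depth_end"):
        if needed not in steps.columns:
            raise ValueError(f"steps missing covariate column {needed!r}")
    wet = steps["wetland_end"].astype(str).to_numpy()
    d = steps["depth_end"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    for w in NONREFERENCE:
        cols[w] = (wet == w).astype(float)
    cols["depth"] = d
    cols["depth2"] = d * d
    for w in NONREFERENCE:
        cols[f"{w}:depth"] = cols[w] * d
        cols[f"{w}:depth2"] = cols[w] * d * d
    if "movement" in spec.terms:
        sl = steps["step_length"].to_numpy(dtype=float)
        lnsl = np.log(np.where(sl > 0, sl, np.nan))
        wstart = steps["wetland_start"].astype(str).to_numpy()
        cols["step_length"] = sl
        cols["ln_step_length"] = lnsl
        for w in NONREFERENCE:
            ws = (wstart == w).astype(float)
            cols[f"step_length:{w}_start"] = sl * ws
            cols[f"ln_step_length:{w}_start"] = lnsl * ws
    if "angle" in spec.terms:
        cols["cos_turn_angle"] = np.cos(steps["turn_angle"].to_numpy(dtype=float))
    names = spec.column_names()
    X = np.column_stack([cols[c] for c in names])
    return X, names


# ---------------------------------------------------------------------------
# conditional logistic likelihood

@dataclass
class ISSAFit:
    """One fitted candidate model for one bird."""

    model: str
    terms: tuple[str, ...]
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    K: int
    n_strata: int
    aicc: float
    converged: bool
    n_iter: int = 0
    unidentifiable: tuple[str, ...] = ()
    message: str = ""

    def coef(self, name: str, default: float | None = None) -> float:
        if name in self.names:
            return float(self.beta[self.names.index(name)])
        if default is not None:
            return default
        raise KeyError(f"no coefficient {name!r} in model {self.model!r}")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "terms": list(self.terms),
            "names": list(self.names),
            "beta": np.asarray(self.beta).tolist(),
            "cov": np.asarray(self.cov).tolist(),
            "loglik": self.loglik,
            "K": self.K,
            "n_strata": self.n_strata,
            "aicc": self.aicc,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "unidentifiable": list(self.unidentifiable),
            "message": self.message,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ISSAFit":
        d = json.loads(Path(path).read_text())
        return cls(
            model=d["model"], terms=tuple(d["terms"]), names=list(d["names"]),
            beta=np.asarray(d["beta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            loglik=d["loglik"], K=d["K"], n_strata=d["n_strata"],
            aicc=d["aicc"], converged=d["converged"], n_iter=d["n_iter"],
            unidentifiable=tuple(d["unidentifiable"]), message=d["message"],
        )


def aicc(loglik: float, K: int, n: int) -> float:
    """AICc = -2 l + 2K + 2K(K+1)/(n - K - 1)."""
    if n - K - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _stratified_arrays(steps: pd.DataFrame, X: np.ndarray):
    """Sort rows into contiguous strata; returns (X, used mask, codes, starts)."""
    codes, _ = pd.factorize(steps["stratum_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    X = X[order]
    used = (steps["case"].to_numpy() == "observed")[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) > 0])
    n_strata = len(starts)
    per = np.bincount(codes)
    n_used = np.bincount(codes, weights=used.astype(float))
    if np.any(n_used != 1):
        raise ValueError("every stratum must contain exactly one observed step")
    if np.any(per < 2):
        raise ValueError("every stratum needs at least one available step")
    return X, used, codes, starts, n_strata


def clogit_loglik(steps: pd.DataFrame, spec: ModelSpec, beta) -> float:
    """Stratified conditional log-likelihood at an arbitrary beta."""
    X, _ = design_matrix(steps, spec)
    X, used, codes, starts, _ = _stratified_arrays(steps, X)
    s = X @ np.asarray(beta, dtype=float)
    smax = np.maximum.reduceat(s, starts)
    denom = np.add.reduceat(np.exp(s - smax[codes]), starts)
    return float(s[used].sum() - (np.log(denom) + smax).sum())


def fit_clogit(
    steps: pd.DataFrame,
    spec: ModelSpec,
    *,
    max_iter: int = 100,
    tol_loglik: float = 1e-9,
    tol_score: float = 1e-6,
) -> ISSAFit:
    """Newton-Raphson fit of one candidate model.

    Iterations use the analytic score and observed information with
    step-halving; the covariance is the inverse information at the optimum.
    A fit wandering beyond |beta| > 15 (or with a non-finite information
    matrix) is flagged non-converged — the signature of complete or
    quasi-separation, e.g. a bird that never uses shellfish.
    """
    X_raw, names = design_matrix(steps, spec)
    if np.isnan(X_raw).any():
        raise ValueError("design matrix contains NaN (zero-length step with "
                         "a log step-length term?)")
    X, used, codes, starts, n_strata = _stratified_arrays(steps, X_raw)
    K = X.shape[1]

    # Within-stratum-constant columns carry no information (the likelihood
    # is invariant to stratum-constant shifts): flag them.
    strat_mean = np.add.reduceat(X, starts, axis=0) / np.diff(np.r_[starts, len(X)])[:, None]
    centered = X - strat_mean[codes]
    unident = tuple(n for j, n in enumerate(names)
                    if np.max(np.abs(centered[:, j])) < 1e-12)

    used_sum = X[used].sum(axis=0)

    # Complete separation: a sign-constant column with zero mass on every
    # used step but positive mass among availables has a monotone
    # likelihood (beta_j -> -inf), e.g. a bird that never uses shellfish.
    separated = []
    for j, name in enumerate(names):
        col = X[:, j]
        same_sign = (col >= 0).all() or (col <= 0).all()
        if same_sign and np.abs(col[used]).max(initial=0.0) == 0.0 \
                and np.abs(col).max() > 0:
            separated.append(name)
    if separated:
        return ISSAFit(
            model=spec.name, terms=spec.terms, names=names,
            beta=np.zeros(K), cov=np.full((K, K), np.nan),
            loglik=-np.inf, K=K, n_strata=n_strata, aicc=np.inf,
            converged=False, n_iter=0, unidentifiable=unident,
            message=("complete separation: no used steps carry "
                     + ", ".join(separated)),
        )

    def evaluate(beta: np.ndarray):
        s = X @ beta
        smax = np.maximum.reduceat(s, starts)
        es = np.exp(s - smax[codes])
        denom = np.add.reduceat(es, starts)
        ll = float(s[used].sum() - (np.log(denom) + smax).sum())
        p = es / denom[codes]
        grad = used_sum - X.T @ p
        M = np.empty((n_strata, K))
        for j in range(K):
            M[:, j] = np.bincount(codes, weights=p * X[:, j], minlength=n_strata)
        info = (X * p[:, None]).T @ X - M.T @ M
        return ll, grad, info

    beta = np.zeros(K)
    ll, grad, info = evaluate(beta)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if not np.all(np.isfinite(info)):
            message = "non-finite information matrix (separation)"
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        step = 1.0
        new_beta = beta + delta
        new_ll, new_grad, new_info = evaluate(new_beta)
        while (not np.isfinite(new_ll)) or new_ll < ll - 1e-12:
            step /= 2.0
            if step < 1e-10:
                break
            new_beta = beta + step * delta
            new_ll, new_grad, new_info = evaluate(new_beta)
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            message = (f"|beta| > {SEPARATION_BETA:g} "
                       "(complete or quasi-separation)")
            break
        if rel_change < tol_loglik and np.max(np.abs(grad)) < tol_score:
            converged = True
            break
    else:
        message = f"no convergence in {max_iter} iterations"

    if converged:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            converged = False
            message = "singular information at the optimum"
    else:
        cov = np.full((K, K), np.nan)
    if unident:
        converged = False
        message = (message + "; " if message else "") + \
            f"unidentifiable (stratum-constant) terms: {', '.join(unident)}"

    return ISSAFit(
        model=spec.name, terms=spec.terms, names=names, beta=beta, cov=cov,
        loglik=ll, K=K, n_strata=n_strata,
        aicc=aicc(ll, K, n_strata), converged=converged, n_iter=it,
        unidentifiable=unident, message=message,
    )


def fit_candidates(steps: pd.DataFrame,
                   specs: list[ModelSpec] | None = None) -> list[ISSAFit]:
    specs = candidate_set() if specs is None else specs
    return [fit_clogit(steps, spec) for spec in specs]


def rank_aicc(fits: list[ISSAFit]) -> pd.DataFrame:
    """AICc model-comparison table: sorted, with delta-AICc and weights."""
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n_strata for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on differing numbers of strata: {ns}")
    df = pd.DataFrame({
        "model": [f.model for f in fits],
        "K": [f.K for f in fits],
        "loglik": [f.loglik for f in fits],
        "AICc": [f.aicc for f in fits],
    })
    df = df.sort_values(["AICc", "K"], kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-df["dAICc"].to_numpy() / 2.0)
    df["weight"] = rel / rel.sum()
    return df


# ---------------------------------------------------------------------------
# relative selection strength

@dataclass
class RSSCurve:
    """log-RSS of one wetland class vs the reference, over a depth grid."""

    wetland: str
    depths: np.ndarray
    log_rss: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def _design_row(spec: ModelSpec, wetland: str, depth: float) -> np.ndarray:
    frame = pd.DataFrame({
        "wetland_end": pd.Categorical([wetland], categories=list(CLASS_NAMES)),
        "depth_end": [depth],
    })
    X, _ = design_matrix(frame, spec)
    return X[0]


def log_rss(
    fit: ISSAFit,
    wetland: str,
    depth_grid,
    reference: str = REFERENCE_CLASS,
    depth_window: tuple[float, float] = (-0.5, 1.0),
    level: float = 0.95,
) -> RSSCurve:
    """Relative selection strength (log scale) vs the reference class.

    log-RSS(w, d) = x(w, d)'b - x(ref, d)'b, with pointwise delta-method
    confidence bands c'b +/- z sqrt(c' Sigma c).  Depths must lie inside the
    fitted window.
    """
    if not fit.converged:
        raise ValueError(f"model {fit.model!r} did not converge")
    if "movement" in fit.terms:
        raise ValueError("log-RSS is defined for habitat terms only")
    depths = np.atleast_1d(np.asarray(depth_grid, dtype=float))
    lo, hi = depth_window
    if depths.min() < lo or depths.max() > hi:
        raise ValueError(f"depth grid outside the fitted window [{lo}, {hi}]")
    spec = ModelSpec(fit.model, fit.terms)
    z = stats.norm.ppf(0.5 + level / 2.0)
    est = np.empty(depths.shape)
    lo_ci = np.empty(depths.shape)
    hi_ci = np.empty(depths.shape)
    for i, d in enumerate(depths):
        c = _design_row(spec, wetland, d) - _design_row(spec, reference, d)
        e = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
        est[i] = e
        lo_ci[i] = e - z * se
        hi_ci[i] = e + z * se
    return RSSCurve(wetland, depths, est, lo_ci, hi_ci)


# ---------------------------------------------------------------------------
# selection-corrected step-length kernel

def corrected_kernel(
    tentative: MovementKernel,
    fit: ISSAFit,
    wetland_start: str,
) -> MovementKernel:
    """Update the tentative gamma kernel with fitted step-length coefficients.

    For a gamma(k, theta) tentative kernel and fitted coefficients b_sl on
    step length and b_lnsl on ln(step length) for steps starting in
    ``wetland_start``:

        k'     = k + b_lnsl
        theta' = 1 / (1/theta - b_sl)

    which removes the imprint of habitat selection from the step-length
    distribution.  The corrected rate 1/theta - b_sl must stay positive.
    """
    if "movement" not in fit.terms:
        raise ValueError("fit lacks step-length terms; use the movement model")
    b_sl = fit.coef("step_length")
    b_lnsl = fit.coef("ln_step_length")
    if wetland_start != REFERENCE_CLASS:
        b_sl += fit.coef(f"step_length:{wetland_start}_start")
        b_lnsl += fit.coef(f"ln_step_length:{wetland_start}_start")
    new_shape = tentative.shape + b_lnsl
    new_rate = 1.0 / tentative.scale - b_sl
    if new_rate <= 0:
        raise ValueError(
            f"corrected step-length rate non-positive for {wetland_start!r} "
            f"(1/theta - b_sl = {new_rate:.3g})")
    if new_shape <= 0:
        raise ValueError(
            f"corrected gamma shape non-positive for {wetland_start!r}")
    return MovementKernel(new_shape, 1.0 / new_rate, tentative.kappa,
                          kind="corrected")
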