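"""Acoustic SCR inference: density surface, likelihood, fitting, model
selection, and abundance with bootstrap intervals.

State process.  Calling group locations on a given day are a realisation
of an inhomogeneous Poisson process with log-linear intensity

    log D(s) = beta0 + beta1 x1(s) + beta2 x2(s) + ...

in spatial covariates measured on a habitat mask.  The expected number of
daily calling groups in a region V is TCG = integral_V D(s) ds, evaluated
as a Riemann sum over the mask.

Observation process.  Each active listening post detects a calling group
at latent location s independently with probability g(d(s, t_l)) (hazard
half-normal by default), and records a bearing with von Mises(kappa)
error.  The latent location is integrated out over the site's local mask.
Days are independent occasions: the model is of groups calling on a given
day, so a group calling on two days contributes two capture histories.

The likelihood is the unconditional (Poisson) SCR form.  With local mask
M_i (cell area a), active posts T_ij on occasion (i, j) and detection
probability by at least one post p.(s), the occasion's expected number of
detected histories is Lambda_ij = a sum_s D(s) p.(s), and the occasion
contributes

    -Lambda_ij + sum_k log[ a sum_s D(s)
         prod_l g(d)^w (1-g(d))^(1-w) prod_{l: w=1} vM(theta_obs | theta(s, t_l)) ].

All parameters (beta, log lambda0, log sigma, log kappa) are estimated
jointly by quasi-Newton maximisation; the covariance matrix comes from
the inverse observed information (finite-difference Hessian).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from .calling import CallingProbData, fit_calling_probability
from .detection import BearingParams, DetectionParams, log_i0
from .mask import HabitatMask


__all__ = [
    "DensitySpec",
    "AscrData",
    "AscrFit",
    "AbundanceEstimate",
    "CoverageError",
    "FitError",
    "design_matrix",
    "density_surface",
    "expected_calling_groups",
    "negative_log_likelihood",
    "fit_model",
    "model_selection",
    "likelihood_ratio_test",
    "bootstrap_abundance",
    "fit_to_json",
]

TWO_PI = 2.0 * np.pi


class CoverageError(ValueError):
    """A model covariate is not available on the prediction mask."""


class FitError(RuntimeError):
    """Optimisation failed to converge after restarts."""


@dataclass
class DensitySpec:
    """Log-linear density model: terms, coefficients and covariate scaling.

    covariate_names : model terms in order; the categorical term
        ``"forest"`` expands to two dummy columns (F2, F3; F1 evergreen is
        the baseline).
    beta : intercept first, then one coefficient per design column, on the
        log-density (groups/km^2) scale, with continuous covariates
        z-standardized per ``standardization``.
    standardization : continuous covariate name -> (mean, sd) used when the
        model was fitted, so predictions apply the identical scaling.
    """

    covariate_names: tuple = ()
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))
    standardization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != 1 + n_model_columns(self.covariate_names):
            raise ValueError("beta length must be 1 + number of design columns")

    @property
    def column_names(self) -> list:
        cols = ["intercept"]
        for t in self.covariate_names:
            cols.extend(["forest_F2", "forest_F3"] if t == "forest" else [t])
        return cols


def n_model_columns(terms) -> int:
    return sum(2 if t == "forest" else 1 for t in terms)


def design_matrix(mask: HabitatMask, terms, standardization=None) -> np.ndarray:
    """Intercept + covariate columns for ``terms`` evaluated on ``mask``."""
    cols = [np.ones(mask.n_points)]
    std = standardization or {}
    for t in terms:
        if t == "forest":
            if "forest_class" not in mask.covariates:
                raise CoverageError("mask lacks covariate 'forest_class'")
            fc = np.asarray(mask.covariates["forest_class"])
            codes = np.array([str(v)[:2] for v in fc])
            cols.append((codes == "F2").astype(float))
            cols.append((codes == "F3").astype(float))
        else:
            if t not in mask.covariates:
                raise CoverageError(f"mask lacks covariate {t!r}")
            v = np.asarray(mask.covariates[t], dtype=float)
            if t in std:
                m, s = std[t]
                v = (v - m) / (s if s > 0 else 1.0)
            cols.append(v)
    return np.column_stack(cols)


def density_surface(mask: HabitatMask, spec: DensitySpec) -> np.ndarray:
    """D(s) = exp(linear predictor), groups/km^2 at every mask point."""
    X = design_matrix(mask, spec.covariate_names, spec.standardization)
    return np.exp(X @ spec.beta)


def expected_calling_groups(mask: HabitatMask, spec: DensitySpec) -> float:
    """TCG: Riemann sum of D(s) times cell area over the prediction mask."""
    return float(density_surface(mask, spec).sum() * mask.cell_area_km2)


# ---------------------------------------------------------------------------
# data container and prepared likelihood structures

@dataclass
class _Site:
    site_id: str
    posts: list
    mask: HabitatMask
    dist: np.ndarray = None     # (M, L) metres, post l in sorted post order
    theta: np.ndarray = None    # (M, L) bearing post -> mask point, radians

    def __post_init__(self) -> None:
        self.posts = sorted(self.posts, key=lambda p: p.post_index)
        px = np.array([p.x for p in self.posts])
        py = np.array([p.y for p in self.posts])
        dx = self.mask.x[:, None] - px[None, :]
        dy = self.mask.y[:, None] - py[None, :]
        self.dist = np.hypot(dx, dy)
        self.theta = np.arctan2(dx, dy)  # clockwise from north

    @property
    def post_indices(self) -> tuple:
        return tuple(p.post_index for p in self.posts)


@dataclass
class AscrData:
    """Capture histories plus per-site local masks, pre-arranged by occasion.

    histories : list of CaptureHistory.
    site_posts : site_id -> list of ListeningPost.
    site_masks : site_id -> local HabitatMask (covariates attached).
    """

    histories: list
    site_posts: dict
    site_masks: dict

    def __post_init__(self) -> None:
        self.sites = {}
        for sid, posts in self.site_posts.items():
            if sid not in self.site_masks:
                raise ValueError(f"no mask supplied for site {sid}")
            self.sites[sid] = _Site(sid, list(posts), self.site_masks[sid])
        occ: dict = {}
        for h in self.histories:
            site = self.sites[h.site_id]
            cols = []
            for pi in h.post_indices:
                if pi not in site.post_indices:
                    raise ValueError(f"history references unknown post {pi} "
                                     f"at site {h.site_id}")
                cols.append(site.post_indices.index(pi))
            occ.setdefault((h.site_id, h.day), []).append((h, tuple(cols)))
        self.occasions = []
        for (sid, day) in sorted(occ):
            pairs = occ[(sid, day)]
            cols = pairs[0][1]
            for h, c in pairs:
                if c != cols:
                    raise ValueError(
                        f"inconsistent active posts among histories at "
                        f"({sid}, day {day})")
            self.occasions.append({
                "site": sid, "day": day, "cols": np.array(cols, dtype=int),
                "histories": [h for h, _ in pairs],
            })
        # occasions with zero detected histories contribute only -Lambda; they
        # are implied by posts' days_active even if no group was heard
        seen = {(o["site"], o["day"]) for o in self.occasions}
        for sid, site in self.sites.items():
            days = set()
            for p in site.posts:
                days |= set(p.days_active)
            for day in sorted(days):
                if (sid, day) in seen:
                    continue
                cols = np.array([i for i, p in enumerate(site.posts)
                                 if day in p.days_active], dtype=int)
                self.occasions.append({"site": sid, "day": day, "cols": cols,
                                       "histories": []})

    @property
    def n_histories(self) -> int:
        return len(self.histories)

    def has_bearings(self) -> bool:
        return any(h.bearings_deg for h in self.histories)


class _Prepared:
    """Model structure frozen for repeated likelihood evaluation.

    Occasions sharing a site and active-post set are batched; per batch the
    detection terms of all histories are evaluated as one (mask x detection)
    array and summed per history with ``add.reduceat``.

    ``bearing_cell_blur`` refines the quadrature of the bearing factor: per
    history, the joint product of von Mises terms is averaged over a 3 x 3
    subgrid of each mask cell (the density and detection factors, smooth at
    the cell scale, stay at the cell centre; the joint average matters
    because a history's bearings constrain one common location).  On masks
    coarser than the bearing-error arc this removes the midpoint-rule
    attenuation of kappa; it converges to the plain likelihood as the
    spacing shrinks.
    """

    N_SUB = 3

    def __init__(self, data: AscrData, terms, standardization,
                 bearing_cell_blur: bool = False):
        self.bearing_cell_blur = bearing_cell_blur
        self.terms = tuple(terms)
        self.sites = {}
        self.theta_sub = {}
        for sid, site in data.sites.items():
            X = design_matrix(site.mask, terms, standardization)
            self.sites[sid] = (site, X, np.log(site.mask.cell_area_km2))
            if bearing_cell_blur:
                self.theta_sub[sid] = self._subgrid_theta(site)
        groups: dict = {}
        for o in data.occasions:
            key = (o["site"], tuple(o["cols"]))
            g = groups.setdefault(key, {"n_occ": 0, "hists": []})
            g["n_occ"] += 1
            g["hists"].extend(o["histories"])
        self.batches = []
        for (sid, cols), g in sorted(groups.items()):
            site, X, log_a = self.sites[sid]
            cols_arr = np.array(cols, dtype=int)
            det_cols, det_obs, starts = [], [], []
            pos = 0
            for h in g["hists"]:
                starts.append(pos)
                for i in np.flatnonzero(h.omega):
                    c = cols_arr[i]
                    det_cols.append(c)
                    det_obs.append(np.radians(h.bearings_deg[site.post_indices[c]]))
                    pos += 1
            batch = {
                "site": sid, "cols": cols_arr, "n_occ": g["n_occ"],
                "K": len(g["hists"]),
                "det_cols": np.array(det_cols, dtype=int),
                "det_obs": np.array(det_obs, dtype=float),
                "starts": np.array(starts, dtype=int),
            }
            if bearing_cell_blur and len(det_cols):
                th = self.theta_sub[sid][:, :, batch["det_cols"]]  # (J, M, nd)
                cosm1 = np.cos(batch["det_obs"][None, None, :] - th) - 1.0
                # per-history sums are kappa-independent: reduce once
                batch["Rsub"] = np.add.reduceat(cosm1, batch["starts"], axis=2)
                batch["_zbuf"] = np.empty_like(batch["Rsub"])  # (J, M, K)
            self.batches.append(batch)
        self.k_beta = 1 + n_model_columns(terms)

    def _subgrid_theta(self, site) -> np.ndarray:
        """(N_SUB^2, M, L) post-to-point bearings at cell subcentres."""
        s = np.sqrt(site.mask.cell_area_km2) * 1000.0
        offs = (np.arange(self.N_SUB) + 0.5) / self.N_SUB * s - s / 2.0
        px = np.array([p.x for p in site.posts])
        py = np.array([p.y for p in site.posts])
        out = []
        for ox in offs:
            for oy in offs:
                dx = (site.mask.x + ox)[:, None] - px[None, :]
                dy = (site.mask.y + oy)[:, None] - py[None, :]
                out.append(np.arctan2(dx, dy))
        return np.stack(out)

    def nll(self, beta, lambda0, sigma, kappa, use_bearings=True) -> float:
        total = 0.0
        cache = {}
        for sid, (site, X, log_a) in self.sites.items():
            log_surv = -lambda0 * np.exp(-0.5 * (site.dist / sigma) ** 2)
            with np.errstate(divide="ignore"):
                log_g = np.log(-np.expm1(log_surv))
            cache[sid] = (log_surv, log_g, X @ beta)
        with_bearings = use_bearings and kappa is not None
        if with_bearings:
            log_c = -np.log(TWO_PI) - log_i0(kappa)
        for b in self.batches:
            site, X, log_a = self.sites[b["site"]]
            log_surv, log_g, logD = cache[b["site"]]
            surv_all = log_surv[:, b["cols"]].sum(axis=1)
            p_dot = -np.expm1(surv_all)
            total += b["n_occ"] * np.exp(log_a) * float(np.exp(logD) @ p_dot)
            if b["K"] == 0:
                continue
            dc = b["det_cols"]
            A = log_g[:, dc] - log_surv[:, dc]
            if with_bearings and not self.bearing_cell_blur:
                A = A + kappa * np.cos(b["det_obs"][None, :]
                                       - site.theta[:, dc]) + log_c
            S = np.add.reduceat(A, b["starts"], axis=1)  # (M, K)
            if with_bearings and self.bearing_cell_blur:
                # joint subcell average per history of the bearing product:
                # log mean_j exp(kappa sum_l (c_jl - 1)), plus the constants
                zs = np.multiply(b["Rsub"], kappa, out=b["_zbuf"])  # (J, M, K)
                np.exp(zs, out=zs)
                mb = zs.mean(axis=0)
                with np.errstate(divide="ignore"):
                    np.log(mb, out=mb)
                n_det_k = np.diff(np.append(b["starts"], len(dc)))
                S = S + mb + (kappa + log_c) * n_det_k[None, :]
            V = S + (logD + surv_all)[:, None]
            total -= float(logsumexp(V, axis=0).sum()) + b["K"] * log_a
        return float(total)


def negative_log_likelihood(spec: DensitySpec, detection: DetectionParams,
                            bearing: BearingParams | None,
                            data: AscrData) -> float:
    """Negative log-likelihood at the given parameters (hazard half-normal).

    ``bearing=None`` (or data without bearings) gives the bearing-free SCR
    likelihood on the same capture histories.
    """
    prep = _Prepared(data, spec.covariate_names, spec.standardization)
    kappa = bearing.kappa if bearing is not None else None
    return prep.nll(spec.beta, detection.lambda0, detection.sigma, kappa,
                    use_bearings=kappa is not None)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class AscrFit:
    density_spec: DensitySpec
    detection: DetectionParams
    bearing: BearingParams | None
    loglik: float
    n_params: int
    aic: float
    vcov: np.ndarray
    param_names: list
    theta: np.ndarray            # MLE on the working scale
    convergence: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.vcov)
        return np.sqrt(np.where(d > 0, d, np.nan))

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = chi2.ppf(level, 1) ** 0.5
        lo = self.theta - z * self.se
        hi = self.theta + z * self.se
        return pd.DataFrame({"estimate": self.theta, "se": self.se,
                             "low": lo, "high": hi}, index=self.param_names)


def _standardization(data: AscrData, terms) -> dict:
    std = {}
    for t in terms:
        if t == "forest":
            continue
        vals = np.concatenate([
            np.asarray(s.mask.covariates[t], dtype=float)
            for s in data.sites.values()])
        sd = vals.std()
        std[t] = (float(vals.mean()), float(sd if sd > 0 else 1.0))
    return std


def _naive_start_density(data: AscrData) -> float:
    area = sum(s.mask.total_area_km2 for s in data.sites.values())
    n_days = max(1, len({(o["site"], o["day"]) for o in data.occasions}))
    n_sites = max(1, len(data.sites))
    per_occ_area = area / n_sites
    d0 = data.n_histories / max(1e-9, (n_days * per_occ_area * 0.5))
    return float(np.clip(d0, 1e-4, 100.0))


def fit_model(data: AscrData, covariate_names=(), use_bearings: str | bool = "auto",
              start: np.ndarray | None = None, max_restarts: int = 3,
              standardize: bool = True, seed: int = 0,
              bearing_cell_blur: bool = False) -> AscrFit:
    """Maximum-likelihood fit of the ASCR model.

    Working scale: identity for beta, log for lambda0, sigma and kappa.
    Starts: beta0 from a naive count-based density, sigma at half the post
    spacing, lambda0 = 2, kappa = 10; jittered restarts on failure.
    Refuses to return estimates when the optimiser does not converge.
    ``bearing_cell_blur`` enables the cell-averaged bearing kernel
    (recommended on masks coarser than ~sigma/5 when bearings are precise).
    """
    terms = tuple(covariate_names)
    std = _standardization(data, terms) if standardize else {}
    prep = _Prepared(data, terms, std, bearing_cell_blur=bearing_cell_blur)
    if use_bearings == "auto":
        use_bearings = data.has_bearings()
    kb = prep.k_beta

    if start is None:
        th0 = np.zeros(kb + 2 + (1 if use_bearings else 0))
        th0[0] = np.log(_naive_start_density(data))
        th0[kb] = np.log(2.0)       # log lambda0
        th0[kb + 1] = np.log(250.0)  # log sigma
        if use_bearings:
            th0[kb + 2] = np.log(10.0)
    else:
        th0 = np.asarray(start, dtype=float).copy()

    def obj(th):
        beta = th[:kb]
        lam0 = np.exp(th[kb])
        sig = np.exp(th[kb + 1])
        kap = np.exp(th[kb + 2]) if use_bearings else None
        val = prep.nll(beta, lam0, sig, kap, use_bearings=use_bearings)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    trace = []
    res = None
    for attempt in range(max_restarts + 1):
        th_start = th0 if attempt == 0 else th0 + rng.normal(0, 0.5, th0.size)
        r = minimize(obj, th_start, method="L-BFGS-B",
                     options={"maxiter": 1000, "ftol": 1e-10, "gtol": 1e-6})
        trace.append({"attempt": attempt, "success": bool(r.success),
                      "message": str(r.message), "fun": float(r.fun)})
        if r.success and np.isfinite(r.fun):
            res = r
            break
    if res is None:
        raise FitError(f"fit did not converge after {max_restarts + 1} attempts: "
                       f"{trace}")

    theta = res.x
    nll_hat = float(res.fun)
    H = _fd_hessian(obj, theta)
    vcov = _safe_inverse(H)
    names = ([f"beta_{c}" for c in DensitySpec(terms, np.zeros(kb), std).column_names]
             + ["log_lambda0", "log_sigma"] + (["log_kappa"] if use_bearings else []))

    beta = theta[:kb]
    det = DetectionParams(float(np.exp(theta[kb])), float(np.exp(theta[kb + 1])))
    bear = BearingParams(float(np.exp(theta[kb + 2]))) if use_bearings else None
    k = theta.size
    fit = AscrFit(
        density_spec=DensitySpec(terms, beta, std),
        detection=det, bearing=bear,
        loglik=-nll_hat, n_params=k, aic=2 * k + 2 * nll_hat,
        vcov=vcov, param_names=names, theta=theta,
        convergence={"trace": trace, "grad_norm": float(np.max(np.abs(res.jac))),
                     "vcov_ok": bool(np.all(np.isfinite(vcov)))},
    )
    return fit


def _fd_hessian(f, x, rel_step: float = 5e-4) -> np.ndarray:
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    vcov = 0.5 * (vcov + vcov.T)
    return vcov


def model_selection(data: AscrData, covariate_pool, **fit_kw) -> pd.DataFrame:
    """Fit every subset of ``covariate_pool`` (forest counts as one variable
    contributing two parameters) and rank by AIC.

    Returns one row per model with covariates, loglik, n_params, aic and
    delta AIC versus the best model; AIC ties (< 1e-6) are broken toward
    fewer parameters.  Failed member fits are flagged, not fatal.
    """
    from itertools import combinations

    pool = list(covariate_pool)
    rows = []
    null_fit = None
    for size in range(len(pool) + 1):
        for terms in combinations(pool, size):
            start = None
            if null_fit is not None:
                kb = 1 + n_model_columns(terms)
                start = np.zeros(kb + (null_fit.theta.size - 1))
                start[0] = null_fit.theta[0]
                start[kb:] = null_fit.theta[1:]
            try:
                f = fit_model(data, terms, start=start, **fit_kw)
                rows.append({"model": terms, "covariates": "+".join(terms) or "~1",
                             "loglik": f.loglik, "n_params": f.n_params,
                             "aic": f.aic, "converged": True, "fit": f})
                if not terms:
                    null_fit = f
            except (FitError, CoverageError) as exc:
                rows.append({"model": terms, "covariates": "+".join(terms) or "~1",
                             "loglik": np.nan, "n_params": np.nan, "aic": np.nan,
                             "converged": False, "fit": None, "error": str(exc)})
    tab = pd.DataFrame(rows)
    best = tab.loc[tab.converged].sort_values(["aic", "n_params"]).iloc[0]
    tab["delta_aic"] = tab["aic"] - best["aic"]
    tab = tab.sort_values(["aic", "n_params"], na_position="last").reset_index(drop=True)
    return tab


def likelihood_ratio_test(full: AscrFit, reduced: AscrFit):
    """LRT between nested fits: statistic 2(l_full - l_reduced), chi-square df
    = parameter-count difference (2 for the forest term)."""
    if not set(reduced.density_spec.covariate_names) <= set(full.density_spec.covariate_names):
        raise ValueError("models are not nested (reduced terms must be a subset)")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        warnings.warn(f"negative LRT statistic {stat:.3g}; clamping to 0")
    stat = max(stat, 0.0)
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    return stat, df, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# abundance and bootstrap

@dataclass
class AbundanceEstimate:
    tcg: float
    tcg_ci: tuple
    tcg_se: float
    tcg_cv: float
    tgg: float
    tgg_ci: tuple
    tgg_se: float
    tgg_cv: float
    mean_daily_calling_density: float
    B: int


class BootstrapError(RuntimeError):
    pass


def _sample_ztb(rng, n: int, p: float) -> int:
    """Draw from the zero-truncated Binomial(n, p) by inverse cdf."""
    ks = np.arange(1, n + 1)
    from scipy.stats import binom
    pmf = binom.pmf(ks, n, p)
    pmf = pmf / pmf.sum()
    return int(rng.choice(ks, p=pmf))


def _mvn_draws(rng, mean, cov, size):
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.any(w < -1e-8 * max(w.max(), 1e-30)):
        raise BootstrapError("vcov is not positive semidefinite; refit the model")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)[None, :]
    z = rng.standard_normal((size, mean.size))
    return mean[None, :] + z @ L.T


def bootstrap_abundance(fit: AscrFit, calling_fit, park_mask: HabitatMask,
                        B: int = 300, seed: int | None = None,
                        calling_data: CallingProbData | None = None) -> AbundanceEstimate:
    """Parametric bootstrap for TCG and TGG.

    Each replicate draws the working-scale parameter vector from
    MVN(MLE, vcov) and recomputes TCG over the park mask; independently,
    daily calling records y*_k are simulated from the zero-truncated
    binomial at p_hat and p re-estimated, giving TGG* = TCG*/p*.
    95% intervals are percentile; SE is the replicate standard deviation;
    CV = SE / point estimate.

    ``calling_fit`` may be a CallingProbFit (with ``calling_data`` to
    resample from) or a bare probability, in which case p is held fixed.
    """
    rng = np.random.default_rng(seed)
    kb = fit.density_spec.beta.size
    tcg_hat = expected_calling_groups(park_mask, fit.density_spec)
    p_fixed = None
    if hasattr(calling_fit, "p_hat"):
        p_hat = calling_fit.p_hat
        if calling_data is None:
            p_fixed = p_hat
    else:
        p_hat = float(calling_fit)
        p_fixed = p_hat
    tgg_hat = tcg_hat / p_hat

    thetas = _mvn_draws(rng, fit.theta, fit.vcov, B)
    tcg_b = np.empty(B)
    tgg_b = np.empty(B)
    for b in range(B):
        spec_b = DensitySpec(fit.density_spec.covariate_names, thetas[b, :kb],
                             fit.density_spec.standardization)
        tcg_b[b] = expected_calling_groups(park_mask, spec_b)
        if p_fixed is not None:
            p_b = p_fixed
        else:
            ys = np.array([_sample_ztb(rng, int(n), p_hat) for n in calling_data.n])
            d_b = CallingProbData(calling_data.group_ids, ys, calling_data.n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_b = fit_calling_probability(d_b).p_hat
        tgg_b[b] = tcg_b[b] / p_b

    def ci(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    area = park_mask.total_area_km2
    return AbundanceEstimate(
        tcg=tcg_hat, tcg_ci=ci(tcg_b), tcg_se=float(tcg_b.std(ddof=1)),
        tcg_cv=float(tcg_b.std(ddof=1) / tcg_hat),
        tgg=tgg_hat, tgg_ci=ci(tgg_b), tgg_se=float(tgg_b.std(ddof=1)),
        tgg_cv=float(tgg_b.std(ddof=1) / tgg_hat),
        mean_daily_calling_density=tcg_hat / area, B=B,
    )


def fit_to_json(fit: AscrFit) -> str:
    """Serialize a fit result (parameters, fit statistics, vcov) to JSON."""
    return json.dumps({
        "model": list(fit.density_spec.covariate_names),
        "beta": fit.density_spec.beta.tolist(),
        "standardization": {k: list(v) for k, v in
                            fit.density_spec.standardization.items()},
        "lambda0": fit.detection.lambda0,
        "sigma": fit.detection.sigma,
        "kappa": fit.bearing.kappa if fit.bearing else None,
        "loglik": fit.loglik, "aic": fit.aic, "n_params": fit.n_params,
        "param_names": fit.param_names,
        "vcov": fit.vcov.tolist(),
    }, indent=2)
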