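"""Independent oracles for the test suite.

Everything here is written with naive nested loops and its own formulas,
deliberately sharing no code path with the package implementation.
"""

import math

import numpy as np
from scipy.special import i0


def brute_force_nll(data, spec, det, bearing):
    """Naive evaluation of the unconditional ASCR negative log-likelihood.

    data : gibbonascr AscrData (used only as a container of sites/occasions)
    spec : DensitySpec; det : DetectionParams; bearing : BearingParams or None.
    """
    def g_of(d):
        z = math.exp(-d * d / (2.0 * det.sigma**2))
        if det.form == "hazard_halfnormal":
            return -math.expm1(-det.lambda0 * z)
        return det.g0 * z

    def log_surv_of(d):
        # log(1 - g) without cancellation (the hazard form's survival is
        # an exact exponential)
        z = math.exp(-d * d / (2.0 * det.sigma**2))
        if det.form == "hazard_halfnormal":
            return -det.lambda0 * z
        return math.log1p(-det.g0 * z)

    def vm_pdf(obs, true):
        k = bearing.kappa
        return math.exp(k * math.cos(obs - true)) / (2.0 * math.pi * i0(k))

    total = 0.0
    for occ in data.occasions:
        site = data.sites[occ["site"]]
        a = site.mask.cell_area_km2
        X = _design(site.mask, spec)
        posts = [site.posts[c] for c in occ["cols"]]
        # Lambda: expected detected histories this occasion
        lam = 0.0
        for m in range(site.mask.n_points):
            D = math.exp(sum(X[m][j] * spec.beta[j] for j in range(len(spec.beta))))
            log_surv = 0.0
            for p in posts:
                d = math.hypot(site.mask.x[m] - p.x, site.mask.y[m] - p.y)
                log_surv += log_surv_of(d)
            lam += a * D * (-math.expm1(log_surv))
        total += lam
        for h in occ["histories"]:
            acc = 0.0
            for m in range(site.mask.n_points):
                D = math.exp(sum(X[m][j] * spec.beta[j] for j in range(len(spec.beta))))
                term = D
                for i, p in enumerate(posts):
                    d = math.hypot(site.mask.x[m] - p.x, site.mask.y[m] - p.y)
                    gg = g_of(d)
                    term *= gg if h.omega[i] == 1 else (1.0 - gg)
                    if h.omega[i] == 1 and bearing is not None:
                        obs = math.radians(h.bearings_deg[p.post_index])
                        true = math.atan2(site.mask.x[m] - p.x, site.mask.y[m] - p.y)
                        term *= vm_pdf(obs, true)
                acc += a * term
            total -= math.log(acc)
    return total


def _design(mask, spec):
    rows = []
    std = spec.standardization or {}
    for m in range(mask.n_points):
        row = [1.0]
        for t in spec.covariate_names:
            if t == "forest":
                cls = str(mask.covariates["forest_class"][m])[:2]
                row.append(1.0 if cls == "F2" else 0.0)
                row.append(1.0 if cls == "F3" else 0.0)
            else:
                v = float(mask.covariates[t][m])
                if t in std:
                    mu, sd = std[t]
                    v = (v - mu) / sd
                row.append(v)
        rows.append(row)
    return rows


def ztb_grid_mle(y, n, step=1e-6):
    """Grid-search MLE for the zero-truncated binomial calling probability."""
    ps = np.arange(step, 1.0, step)
    y = np.asarray(y, float)[:, None]
    n = np.asarray(n, float)[:, None]
    ll = (y * np.log(ps) + (n - y) * np.log1p(-ps)
          - np.log1p(-(1 - ps) ** n)).sum(axis=0)
    return float(ps[np.argmax(ll)])
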