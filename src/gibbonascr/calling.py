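"""Daily calling probability and conversion from calling-group to group density.

An acoustic survey only sees groups on days they call.  The SCR model
therefore estimates the density of groups *calling on a given day*, D(s);
dividing by the daily calling probability p converts to the density of all
groups, D_g(s) = D(s)/p, and likewise TGG = TCG/p for the park total.

p is estimated from the calibration subset of groups heard within 500 m of
a post (their detection given calling is essentially certain, so their
day-by-day calling record is observed directly).  Because a group that
never called during the survey cannot enter the sample, the number of
calling days y_k out of n_k survey days follows a zero-truncated
binomial, and p is the maximum-likelihood estimate under

    y_k ~ ZeroTruncBinom(n_k, p),  1 <= y_k <= n_k.

Calling is assumed independent across days with a common p for all groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .survey import GroupedDetections

__all__ = [
    "CallingProbData",
    "CallingProbFit",
    "select_calibration_groups",
    "ztb_log_likelihood",
    "fit_calling_probability",
    "proportion_calling_over_m_days",
    "convert_to_group_abundance",
]

NEAR_CATEGORIES = ("LT500", "D500")  # "detection distance <= 500 m"


@dataclass
class CallingProbData:
    """Per-group calling-day counts: y[k] days called out of n[k] surveyed."""

    group_ids: np.ndarray
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.group_ids = np.asarray(self.group_ids)
        self.y = np.asarray(self.y, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(self.y < 1) or np.any(self.y > self.n) or np.any(self.n < 1):
            raise ValueError("need 1 <= y_k <= n_k and n_k >= 1")

    @property
    def n_groups(self) -> int:
        return self.y.size


@dataclass
class CallingProbFit:
    p_hat: float
    ci_low: float
    ci_high: float
    n_groups: int
    loglik: float
    se_log_p: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.p_hat <= 1):
            raise ValueError("p_hat must be in (0, 1]")


def select_calibration_groups(grouped: GroupedDetections, histories, posts) -> CallingProbData:
    """Pick persistent groups ever detected at <= 500 m of a post and count
    their calling days.

    y_k = number of distinct days the group was detected (anywhere);
    n_k = number of distinct survey days on which at least one of the posts
    that ever detected the group was active.
    """
    post_map = {(p.site_id, p.post_index): p for p in posts}
    qualifies: set = set()
    days_detected: dict = {}
    detecting_posts: dict = {}
    for (site, day, label), recs in grouped.groups.items():
        pid = grouped.persistent[(site, label)]
        key = (site, pid)
        days_detected.setdefault(key, set()).add(day)
        for r in recs:
            detecting_posts.setdefault(key, set()).add((site, r.post_index))
            if r.distance_category in NEAR_CATEGORIES:
                qualifies.add(key)

    ids, ys, ns = [], [], []
    for key in sorted(qualifies):
        site, pid = key
        y = len(days_detected[key])
        active_days: set = set()
        for pk in detecting_posts[key]:
            active_days |= set(post_map[pk].days_active)
        n = len(active_days)
        ids.append(f"{site}:{pid}")
        ys.append(y)
        ns.append(n)
    if not ids:
        warnings.warn("no calibration groups detected within 500 m")
        return CallingProbData(np.empty(0, dtype=object),
                               np.empty(0, dtype=int), np.empty(0, dtype=int))
    return CallingProbData(np.array(ids, dtype=object), np.array(ys), np.array(ns))


def ztb_log_likelihood(p: float, data: CallingProbData) -> float:
    """Zero-truncated binomial log likelihood (binomial coefficients dropped)."""
    if not (0 < p <= 1):
        return -np.inf
    y, n = data.y.astype(float), data.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        miss = np.where(n > y, (n - y) * np.log1p(-p), 0.0)
        term = y * np.log(p) + miss
        trunc = np.log1p(-(1.0 - p) ** n)
    ll = term - trunc
    return float(np.sum(ll))


def fit_calling_probability(data: CallingProbData, ci_level: float = 0.95) -> CallingProbFit:
    """ZTB maximum likelihood for p with a profile-likelihood CI.

    Groups with n_k = 1 carry no information (P(y=1 | detected) = 1
    regardless of p) and are dropped with a warning.  If every group
    called on every surveyed day the MLE is the boundary p = 1.
    """
    keep = data.n >= 2
    if keep.sum() < data.n_groups:
        warnings.warn(f"dropping {int((~keep).sum())} group(s) with n_k = 1 "
                      "(uninformative under zero-truncation)")
    if keep.sum() == 0:
        raise ValueError("no informative groups (all have n_k = 1)")
    d = CallingProbData(data.group_ids[keep], data.y[keep], data.n[keep])

    if np.all(d.y == d.n):
        warnings.warn("all groups called on every surveyed day: boundary MLE p = 1")
        ll1 = ztb_log_likelihood(1.0, d)
        lo = _profile_bound(d, 1.0, ll1, ci_level, side="lower")
        return CallingProbFit(1.0, lo, 1.0, d.n_groups, ll1, se_log_p=float("nan"))

    res = minimize_scalar(lambda p: -ztb_log_likelihood(p, d),
                          bounds=(1e-9, 1.0 - 1e-12), method="bounded",
                          options={"xatol": 1e-10})
    p_hat = float(res.x)
    ll_hat = -float(res.fun)
    lo = _profile_bound(d, p_hat, ll_hat, ci_level, side="lower")
    hi = _profile_bound(d, p_hat, ll_hat, ci_level, side="upper")
    se = _se_log_p(d, p_hat)
    return CallingProbFit(p_hat, lo, hi, d.n_groups, ll_hat, se_log_p=se)


def _profile_bound(d: CallingProbData, p_hat: float, ll_hat: float,
                   ci_level: float, side: str) -> float:
    drop = chi2.ppf(ci_level, df=1) / 2.0

    def f(p):
        return ztb_log_likelihood(p, d) - (ll_hat - drop)

    if side == "lower":
        a, b = 1e-9, p_hat
        if f(a) > 0:
            return a
        return float(brentq(f, a, b, xtol=1e-10))
    a, b = p_hat, 1.0 - 1e-12
    if p_hat >= 1.0 - 1e-9 or f(b) > 0:
        return 1.0
    return float(brentq(f, a, b, xtol=1e-10))


def _se_log_p(d: CallingProbData, p_hat: float) -> float:
    """Delta-method SE of log p_hat from the numerical observed information."""
    h = 1e-5 * min(p_hat, 1 - p_hat)
    ll = ztb_log_likelihood
    d2 = (ll(p_hat + h, d) - 2 * ll(p_hat, d) + ll(p_hat - h, d)) / h**2
    if d2 >= 0:
        return float("nan")
    var_p = -1.0 / d2
    return float(np.sqrt(var_p) / p_hat)


def proportion_calling_over_m_days(p1: float, m: int) -> float:
    """p(m) = 1 - (1 - p(1))^m, the chance a group calls at least once in m days."""
    if not (0 <= p1 <= 1):
        raise ValueError("p1 must be in [0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return float(-np.expm1(m * np.log1p(-p1))) if p1 < 1 else 1.0


def convert_to_group_abundance(tcg: float, density_surface, p_fit):
    """TGG = TCG / p and D_g(s) = D(s) / p pointwise.

    ``p_fit`` may be a CallingProbFit or a bare probability.
    """
    p = p_fit.p_hat if hasattr(p_fit, "p_hat") else float(p_fit)
    if not (0 < p <= 1):
        raise ValueError("calling probability must be in (0, 1]")
    dg = np.asarray(density_surface, dtype=float) / p
    return tcg / p, dg
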