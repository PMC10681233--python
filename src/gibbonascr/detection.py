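"""Detection and bearing-error models for acoustic SCR.

The survey design places fixed listening posts; a gibbon group duetting at
location ``s`` is heard by a post at ``t`` with probability ``g(d(s, t))``.
Two detection-function forms are supported:

* ``hazard_halfnormal`` — ``g(d) = 1 - exp(-lambda0 * exp(-d^2 / (2 sigma^2)))``.
  For large ``lambda0`` this has a "shoulder": detection is essentially
  certain out to an appreciable distance, which is realistic for loud,
  long-duration duets.
* ``halfnormal`` — ``g(d) = g0 * exp(-d^2 / (2 sigma^2))``, the common
  alternative, which drops away from ``g0`` immediately.

Observers also record a compass bearing to each detected call.  Bearing
measurement error is modelled as von Mises on the circle with concentration
``kappa`` (``kappa = 0`` means bearings carry no information about the true
direction; large ``kappa`` means precise bearings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = [
    "DetectionParams",
    "BearingParams",
    "detection_prob",
    "log_survival_prob",
    "overall_detection_prob",
    "bearing_log_density",
    "wrap_angle",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the detection function.

    lambda0 : hazard scale (dimensionless), > 0.  Governs the shoulder of
        the hazard half-normal form: g(0) = 1 - exp(-lambda0).
    sigma : range scale in metres, > 0.
    form : "hazard_halfnormal" (default) or "halfnormal".
    g0 : intercept probability in (0, 1]; used only by the halfnormal form.
    """

    lambda0: float
    sigma: float
    form: str = "hazard_halfnormal"
    g0: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("hazard_halfnormal", "halfnormal"):
            raise ValueError(f"unknown detection function form {self.form!r}")
        if not (self.lambda0 > 0):
            raise ValueError("lambda0 must be > 0")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if self.form == "halfnormal" and not (0 < self.g0 <= 1):
            raise ValueError("g0 must be in (0, 1] for the halfnormal form")


@dataclass(frozen=True)
class BearingParams:
    """von Mises bearing-error concentration; kappa = 0 is uniform on the circle."""

    kappa: float

    def __post_init__(self) -> None:
        if not (self.kappa >= 0):
            raise ValueError("kappa must be >= 0")


def log_survival_prob(d, params: DetectionParams):
    """log P(not detected) at distance d; exact for the hazard half-normal.

    For the hazard half-normal form 1 - g(d) = exp(-lambda0 e^{-d^2/2sigma^2}),
    so the log survival is available without cancellation at any distance.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    z = np.exp(-0.5 * (d / params.sigma) ** 2)
    if params.form == "hazard_halfnormal":
        return -params.lambda0 * z
    return np.log1p(-params.g0 * z)


def detection_prob(d, params: DetectionParams):
    """Probability that a call at distance ``d`` (metres) is detected.

    Evaluated via expm1 of the exact log-survival so that both tails
    (g near 0 and g near 1) keep full relative precision.
    """
    return -np.expm1(log_survival_prob(d, params))


def overall_detection_prob(s, posts, params: DetectionParams):
    """Probability a group at location ``s`` is detected by at least one post.

    ``s`` is an (x, y) pair or an (n, 2) array; ``posts`` is a sequence of
    objects with ``x``/``y`` attributes, or an (L, 2) coordinate array.
    Posts detect independently given the location, so
    ``p.(s) = 1 - prod_l [1 - g(d(s, t_l))]``.
    """
    pts = _post_coords(posts)
    if pts.shape[0] == 0:
        raise ValueError("post list must be non-empty")
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    s2 = np.atleast_2d(s)
    d = np.hypot(s2[:, None, 0] - pts[None, :, 0], s2[:, None, 1] - pts[None, :, 1])
    log_surv = log_survival_prob(d, params).sum(axis=1)
    p = -np.expm1(log_surv)
    return float(p[0]) if single else p


def _post_coords(posts) -> np.ndarray:
    arr = np.asarray(
        [[p.x, p.y] if hasattr(p, "x") else p for p in posts], dtype=float
    )
    return arr.reshape(-1, 2)


def wrap_angle(theta):
    """Wrap angles (radians) to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = -np.remainder(-theta + np.pi, TWO_PI) + np.pi
    return out


def log_i0(kappa: float) -> float:
    """log of the modified Bessel function I0, stable for large kappa."""
    return float(np.log(i0e(kappa)) + kappa)


def bearing_log_density(theta_obs, theta_true, bp: BearingParams):
    """Log density of an observed bearing given the true direction.

    von Mises: exp(kappa cos(theta_obs - theta_true)) / (2 pi I0(kappa)).
    Symmetric in the sign of the angular error (unbiased bearings).
    """
    if bp.kappa < 0:
        raise ValueError("kappa must be >= 0")
    err = np.asarray(theta_obs, dtype=float) - np.asarray(theta_true, dtype=float)
    out = bp.kappa * np.cos(err) - np.log(TWO_PI) - log_i0(bp.kappa)
    return float(out) if np.isscalar(theta_obs) and np.isscalar(theta_true) else out
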