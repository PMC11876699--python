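"""Mass-action 1:1 binding algebra and titration-curve Kd fitting.

The equilibrium of a single-site interaction R + L <-> RL at total
concentrations comparable to the dissociation constant cannot be described
by the hyperbolic (ligand-excess) isotherm; the exact solution of the
mass-action equation is the "quadratic depletion" root

    [RL] = ((R + L + Kd) - sqrt((R + L + Kd)^2 - 4 R L)) / 2,

the physical branch satisfying 0 <= [RL] <= min(R, L).  This module exposes
that solver, occupancy predictions between affinity variants (e.g. a
wild-type versus interface-mutant subcomplex pair), and nonlinear
least-squares fitting of Kd from thermophoresis-style two-fold dilution
series in which the labelled species is held constant while the titrant is
serially diluted.

Concentrations are molar throughout; Kd is fitted in log space to respect
positivity across the nanomolar-to-micromolar span of typical assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BindingSystem",
    "Titration",
    "KdFit",
    "complex_concentration",
    "fraction_bound",
    "percent_reduction",
    "fit_kd",
]


@dataclass(frozen=True)
class BindingSystem:
    """Totals and affinity of a 1:1 equilibrium.

    Parameters
    ----------
    r_total : float
        Total concentration of the receptor-like species (M). In the
        thermophoresis assays this is the labelled species.
    l_total : float
        Total concentration of the partner/titrant species (M).
    kd : float
        Dissociation constant (M), strictly positive.
    """

    r_total: float
    l_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.r_total < 0:
            raise ValueError(f"r_total must be >= 0, got {self.r_total}")
        if self.l_total < 0:
            raise ValueError(f"l_total must be >= 0, got {self.l_total}")
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")

    def complex_concentration(self) -> float:
        return float(complex_concentration(self.r_total, self.l_total, self.kd))

    def fraction_bound(self, of: str = "R") -> float:
        return float(fraction_bound(self.r_total, self.l_total, self.kd, of=of))


def complex_concentration(r_total, l_total, kd):
    """Equilibrium complex concentration [RL] of a 1:1 interaction (M).

    Uses the numerically stable form 2RL / (S + sqrt(S^2 - 4RL)) with
    S = R + L + Kd, which avoids catastrophic cancellation when
    4RL << S^2.  Accepts scalars or arrays (broadcast).
    """
    r = np.asarray(r_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(r < 0) or np.any(l < 0):
        raise ValueError("total concentrations must be >= 0")
    if np.any(k <= 0):
        raise ValueError("kd must be > 0")
    s = r + l + k
    disc = s * s - 4.0 * r * l
    # disc >= kd^2 > 0 analytically; clip to guard rounding
    root = np.sqrt(np.clip(disc, 0.0, None))
    rl = np.where(s + root > 0, 2.0 * r * l / (s + root), 0.0)
    return rl if rl.ndim else float(rl)


def fraction_bound(r_total, l_total, kd, of: str = "R"):
    """Fraction of a species sequestered in the complex, in [0, 1].

    ``of`` selects the denominator: ``"R"`` -> [RL]/R_total,
    ``"L"`` -> [RL]/L_total.
    """
    if of not in ("R", "L"):
        raise ValueError(f"'of' must be 'R' or 'L', got {of!r}")
    total = np.asarray(r_total if of == "R" else l_total, dtype=float)
    if np.any(total <= 0):
        raise ValueError(f"total of species {of} must be > 0")
    frac = complex_concentration(r_total, l_total, kd) / total
    return np.clip(frac, 0.0, 1.0)


def percent_reduction(kd_a: float, kd_b: float, r_total: float, l_total: float) -> float:
    """Percent loss of equilibrium complex when the affinity weakens a -> b.

    Returns 100 * (1 - [RL]_b / [RL]_a) at fixed totals.  Used to predict
    the drop in subcomplex occupancy when an interface mutation raises Kd.
    """
    rl_a = complex_concentration(r_total, l_total, kd_a)
    rl_b = complex_concentration(r_total, l_total, kd_b)
    if rl_a == 0:
        raise ValueError("reference complex concentration is zero; reduction undefined")
    return 100.0 * (1.0 - rl_b / rl_a)


@dataclass(frozen=True)
class Titration:
    """A dilution-series binding measurement.

    ``titrant_total``: descending titrant concentrations (M);
    ``response``: measured signal (a.u.); ``labeled_total``: the constant
    concentration of the labelled species (M).
    """

    titrant_total: np.ndarray
    response: np.ndarray
    labeled_total: float

    def __post_init__(self) -> None:
        t = np.asarray(self.titrant_total, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "titrant_total", t)
        object.__setattr__(self, "response", r)
        if t.size < 6:
            raise ValueError(f"titration needs >= 6 points, got {t.size}")
        if t.shape != r.shape:
            raise ValueError("titrant_total and response must have equal length")
        if np.any(t <= 0):
            raise ValueError("titrant totals must be strictly positive")
        if not self.labeled_total > 0:
            raise ValueError("labeled_total must be > 0")


@dataclass
class KdFit:
    """Result of fitting the quadratic 1:1 depletion model to a titration."""

    kd: float
    s_free: float
    s_bound: float
    se_kd: float
    se_s_free: float
    se_s_bound: float
    residual_norm: float
    valid: bool = True
    message: str = ""
    n_points: int = 0
    covariance: np.ndarray | None = field(default=None, repr=False)


def _model(log_kd: float, s_free: float, s_bound: float, conc, labeled: float):
    frac = fraction_bound(labeled, conc, np.exp(log_kd), of="R")
    return s_free + (s_bound - s_free) * frac


def fit_kd(titration: Titration) -> KdFit:
    """Fit Kd, s_free and s_bound to a dilution series.

    The response model is s_free + (s_bound - s_free) * fraction_bound of
    the labelled species under quadratic depletion.  Kd is parameterized as
    log Kd.  Initialisation: endpoint responses for the plateaus and the
    half-maximal-response concentration for Kd.  Non-convergence or a Kd
    estimate pinned at the search box is flagged ``valid=False`` rather
    than returned silently.
    """
    conc = titration.titrant_total
    resp = titration.response
    if np.allclose(resp, resp[0]):
        raise ValueError("responses are all equal; Kd is unidentifiable")

    order = np.argsort(conc)
    c_sorted, r_sorted = conc[order], resp[order]
    s_free0 = float(np.mean(r_sorted[:2]))
    s_bound0 = float(np.mean(r_sorted[-2:]))
    half = 0.5 * (s_free0 + s_bound0)
    # first concentration whose response crosses the half level
    crossing = np.nonzero(
        np.sign(r_sorted - half) != np.sign(r_sorted[0] - half)
    )[0]
    kd0 = float(c_sorted[crossing[0]]) if crossing.size else float(np.median(c_sorted))
    lo, hi = np.log(conc.min()) - np.log(1e5), np.log(conc.max()) + np.log(1e5)
    p0 = np.array([np.clip(np.log(kd0), lo, hi), s_free0, s_bound0])

    def residuals(p):
        return _model(p[0], p[1], p[2], conc, titration.labeled_total) - resp

    ls = optimize.least_squares(
        residuals, p0, bounds=([lo, -np.inf, -np.inf], [hi, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    log_kd, s_free, s_bound = ls.x
    valid = bool(ls.status > 0)
    message = ls.message
    margin = 1e-6 * (hi - lo)
    if log_kd <= lo + margin or log_kd >= hi - margin:
        valid = False
        message = "fitted Kd pinned at the search bound"
    if not (conc.min() <= np.exp(log_kd) <= conc.max()):
        # an affinity outside the titrated range is an extrapolation, not
        # a measurement
        valid = False
        message = "fitted Kd outside the titrated concentration range"
    if np.isclose(s_bound, s_free):
        valid = False
        message = "degenerate fit: s_bound == s_free"

    n, p = conc.size, 3
    dof = max(n - p, 1)
    jac = ls.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * (2.0 * ls.cost / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(3, np.nan)
        valid = False
        message = "singular Jacobian; standard errors unavailable"

    kd = float(np.exp(log_kd))
    return KdFit(
        kd=kd,
        s_free=float(s_free),
        s_bound=float(s_bound),
        se_kd=float(kd * se[0]),  # delta method from log-space SE
        se_s_free=float(se[1]),
        se_s_bound=float(se[2]),
        residual_norm=float(np.sqrt(2.0 * ls.cost)),
        valid=valid,
        message=message,
        n_points=int(n),
        covariance=cov,
    )
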