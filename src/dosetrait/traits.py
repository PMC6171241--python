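"""Dosage traits of a fitted dose-response curve.

Four traits summarize a unimodal-above-baseline response curve f on the
dose domain [0, L]:

* ``p_max`` — maximum potential dosage: the dosage at which f attains its
  maximum (stationary point of f, located by root-finding on the analytic
  derivative after a dense grid scan);
* ``t_max`` — maximum tolerance dosage: the dosage beyond the peak at
  which f falls back to the control level f(0); doses above it depress
  the response below the unsupplemented culture;
* ``mu`` — mean safe dosage: the f-weighted mean dosage over [0, t_max],
  mu = int x f / int f  (f acts as an unnormalized density);
* ``sigma`` — breadth of the mean safe dosage: the f-weighted standard
  deviation of dosage over [0, t_max].

Note on ``t_max``: read literally, "the least dosage with
f(t_max) >= f(0)" is satisfied by dose 0 itself.  The operational meaning
— and what the study's printed values correspond to — is the *largest*
dosage at or above the peak for which the response still matches the
control, i.e. the down-crossing of f through f(0) beyond the peak.  That
is what this module computes.

All functions accept any curve object exposing ``mean(x)``, ``domain``
and optionally ``mean_derivative(x)`` (see :class:`CallableCurve` for
wrapping a plain function), so the same code computes fitted traits and
ground-truth traits of synthetic mean curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq

__all__ = [
    "TraitConfig",
    "TraitSet",
    "CallableCurve",
    "find_p_max",
    "find_t_max",
    "safe_dose_moments",
    "extract_traits",
]


@dataclass(frozen=True)
class TraitConfig:
    """Numerical settings for trait extraction.

    grid_n: dense-scan / quadrature resolution over the domain (forced odd
    for composite Simpson).  root_tol: absolute dosage tolerance of the
    root brackets, in percent-points.  derivative: "analytic" uses the
    curve's own derivative when available, "central" always uses central
    differences with the given step.
    """

    grid_n: int = 2001
    root_tol: float = 1e-5
    derivative: str = "analytic"
    fd_step: float = 1e-4

    def __post_init__(self) -> None:
        if self.grid_n < 101:
            raise ValueError("grid_n must be >= 101")
        if self.root_tol <= 0:
            raise ValueError("root_tol must be > 0")
        if self.derivative not in ("analytic", "central"):
            raise ValueError("derivative must be 'analytic' or 'central'")

    @property
    def odd_grid_n(self) -> int:
        return self.grid_n if self.grid_n % 2 == 1 else self.grid_n + 1


@dataclass(frozen=True)
class TraitSet:
    """The four dosage traits plus the fitted responses at p_max and mu.

    Dosage fields are in percent-points; ``f_at_pmax``/``f_at_mu`` are in
    response units.  ``flags`` records degenerate situations (boundary
    maximum, no tolerance limit within the tested range, undefined traits).
    """

    p_max: float
    t_max: float | None
    mu: float | None
    sigma: float | None
    f_at_pmax: float
    f_at_mu: float | None
    domain_end: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.t_max is not None:
            if not (0 < self.p_max <= self.t_max + 1e-9 <= self.domain_end + 1e-9):
                if "boundary maximum" not in " ".join(self.flags):
                    raise ValueError(
                        f"trait ordering violated: p_max={self.p_max}, "
                        f"t_max={self.t_max}, domain_end={self.domain_end}"
                    )
        if self.mu is not None and self.t_max is not None:
            if not (0 < self.mu < self.t_max):
                raise ValueError(f"mu={self.mu} outside (0, t_max={self.t_max})")
        if self.sigma is not None and self.t_max is not None:
            # Popoviciu bound for any distribution supported on [0, t_max]
            if not (0 < self.sigma <= self.t_max / 2 + 1e-9):
                raise ValueError(f"sigma={self.sigma} violates (0, t_max/2]")

    def rounded(self, ndigits: int = 2) -> dict:
        """Traits rounded to the reporting precision (2 decimals)."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "p_max": rnd(self.p_max),
            "t_max": rnd(self.t_max),
            "mu": rnd(self.mu),
            "sigma": rnd(self.sigma),
        }


@dataclass(frozen=True)
class CallableCurve:
    """Adapter giving a plain positive function the curve interface."""

    fn: object
    domain: tuple[float, float]
    dfn: object | None = None

    @property
    def domain_end(self) -> float:
        return self.domain[1]

    def mean(self, x):
        return np.asarray(self.fn(np.asarray(x, float)), float)

    def mean_derivative(self, x):
        if self.dfn is None:
            raise AttributeError("no analytic derivative")
        return np.asarray(self.dfn(np.asarray(x, float)), float)


def _derivative_fn(curve, cfg: TraitConfig):
    if cfg.derivative == "analytic" and hasattr(curve, "mean_derivative"):
        try:
            curve.mean_derivative(np.array([curve.domain[0]]))
            return lambda x: curve.mean_derivative(x)
        except AttributeError:
            pass
    h = cfg.fd_step
    return lambda x: (curve.mean(np.asarray(x) + h) - curve.mean(np.asarray(x) - h)) / (2 * h)


def find_p_max(curve, cfg: TraitConfig | None = None) -> tuple[float, tuple[str, ...]]:
    """Locate the maximum potential dosage (global maximizer of f).

    Dense grid scan over the domain, then the stationary point is polished
    by bracketed root-finding on f'.  Boundary maxima are returned as-is
    with an explanatory flag (the stationarity condition has no interior
    solution there).  Among ties the smallest dosage wins.
    """
    cfg = cfg or TraitConfig()
    lo, hi = curve.domain
    xs = np.linspace(lo, hi, cfg.odd_grid_n)
    fs = curve.mean(xs)
    if not np.all(np.isfinite(fs)):
        raise ValueError("non-finite curve predictions on the domain grid")
    i = int(np.argmax(fs))  # argmax returns the first (smallest-dose) maximizer
    flags: tuple[str, ...] = ()
    if i == 0 or i == len(xs) - 1:
        return float(xs[i]), ("boundary maximum: stationarity condition not met",)
    dfn = _derivative_fn(curve, cfg)
    a, b = xs[i - 1], xs[i + 1]
    da, db = float(dfn(np.array([a]))[0]), float(dfn(np.array([b]))[0])
    if da > 0 > db:
        root = brentq(lambda t: float(dfn(np.array([t]))[0]), a, b, xtol=cfg.root_tol)
        # guard against polishing onto a stationary saddle below the scan max
        if curve.mean(np.array([root]))[0] >= fs[i] - 1e-12 * abs(fs[i]):
            return float(root), flags
    return float(xs[i]), flags


def find_t_max(curve, p_max: float, cfg: TraitConfig | None = None
               ) -> tuple[float | None, tuple[str, ...]]:
    """Locate the maximum tolerance dosage beyond the peak.

    Returns the down-crossing of f through the control level f(0) on
    [p_max, domain_end], bisected to ``root_tol``.  If f never drops below
    f(0) the domain end is returned with a flag; if the curve never
    exceeds the control at all the trait is undefined (None).
    """
    cfg = cfg or TraitConfig()
    lo, hi = curve.domain
    f0 = float(curve.mean(np.array([lo]))[0])
    fp = float(curve.mean(np.array([p_max]))[0])
    if fp < f0 - 1e-12 * abs(f0):
        return None, ("undefined: curve never exceeds the control level",)
    xs = np.linspace(p_max, hi, cfg.odd_grid_n)
    g = curve.mean(xs) - f0
    below = np.nonzero(g < 0)[0]
    if len(below) == 0:
        return float(hi), ("no tolerance limit observed within the dose range",)
    j = int(below[0])
    if j == 0:  # peak already at/below control within tolerance
        return float(xs[0]), ("tolerance limit coincides with the peak",)
    root = brentq(lambda t: float(curve.mean(np.array([t]))[0]) - f0,
                  xs[j - 1], xs[j], xtol=cfg.root_tol)
    return float(root), ()


def safe_dose_moments(curve, t_max: float, cfg: TraitConfig | None = None
                      ) -> tuple[float, float]:
    """f-weighted mean and SD of dosage over [0, t_max] (Simpson quadrature).

    The fitted curve acts as an unnormalized density over the tolerated
    dose range: mu = int_0^t x f(x) dx / int_0^t f(x) dx and sigma is the
    corresponding standard deviation.
    """
    cfg = cfg or TraitConfig()
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    xs = np.linspace(0.0, t_max, cfg.odd_grid_n)
    f = curve.mean(xs)
    # a single zero at an endpoint (e.g. an analytic oracle like f(x) = x)
    # does not affect the integrals; anything more violates positivity
    if (f < 0).any() or (f[1:-1] <= 0).any() or (f == 0).sum() > 1:
        raise ValueError("non-positive integrand: curve must be positive on [0, t_max]")
    mass = simpson(f, x=xs)
    mu = simpson(xs * f, x=xs) / mass
    var = simpson((xs - mu) ** 2 * f, x=xs) / mass
    return float(mu), float(np.sqrt(var))


def extract_traits(curve, cfg: TraitConfig | None = None) -> TraitSet:
    """Compute the full trait set of a fitted (or analytic) curve."""
    cfg = cfg or TraitConfig()
    p_max, flags_p = find_p_max(curve, cfg)
    f_at_pmax = float(curve.mean(np.array([p_max]))[0])
    t_max, flags_t = find_t_max(curve, p_max, cfg)
    flags = flags_p + flags_t
    if t_max is None:
        return TraitSet(p_max=p_max, t_max=None, mu=None, sigma=None,
                        f_at_pmax=f_at_pmax, f_at_mu=None,
                        domain_end=curve.domain[1], flags=flags)
    mu, sigma = safe_dose_moments(curve, t_max, cfg)
    f_at_mu = float(curve.mean(np.array([mu]))[0])
    return TraitSet(p_max=p_max, t_max=t_max, mu=mu, sigma=sigma,
                    f_at_pmax=f_at_pmax, f_at_mu=f_at_mu,
                    domain_end=curve.domain[1], flags=flags)
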