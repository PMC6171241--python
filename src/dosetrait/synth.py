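"""Synthetic dose-response data with analytically known traits.

The generator emulates the qualitative features of the observed curves:
a positive baseline (the unsupplemented control), a single skewed peak at
an intermediate dosage, and multiplicative replicate noise.  The default
mean-curve family is

    m(x) = b * (1 + s * (x/theta)^p * exp(p * (1 - x/theta)))

with baseline b > 0, relative amplitude s > 0, peak location theta and
shape p >= 1.  The bracketed factor equals 1 exactly at x = theta and its
derivative vanishes only there, so the maximum potential dosage of the
family is theta by construction — one trait is analytically known, which
makes parameter-recovery tests sharp.  Replicates are Gamma distributed
with mean m(x) and shape kappa (coefficient of variation 1/sqrt(kappa)),
matching the positive, right-skewed observation model of the fitting
engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DoseResponseTable
from .traits import CallableCurve, TraitConfig, TraitSet, extract_traits

__all__ = ["SyntheticSpec", "TrueTraits", "generate", "true_traits", "peaked_mean"]

#: the dose grid used throughout the study (percent-points, incl. control)
STUDY_DOSE_GRID = (0.0, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)


def peaked_mean(x, b: float, s: float, theta: float, p: float):
    """Skewed unimodal mean curve with baseline b and peak at theta."""
    x = np.asarray(x, float)
    t = x / theta
    with np.errstate(over="ignore"):
        bump = np.where(t > 0, t**p * np.exp(p * (1.0 - t)), 0.0)
    return b * (1.0 + s * bump)


def peaked_mean_derivative(x, b: float, s: float, theta: float, p: float):
    x = np.asarray(x, float)
    t = x / theta
    with np.errstate(over="ignore", invalid="ignore"):
        dbump = np.where(
            t > 0, (p / theta) * t ** (p - 1.0) * np.exp(p * (1.0 - t)) * (1.0 - t), 0.0
        )
    return b * s * dbump


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic dose-response experiment.

    noise_cv is the replicate coefficient of variation (Gamma shape
    kappa = 1/noise_cv^2); the study's triplicate SDs correspond to
    roughly 5% CV.  noise_cv=0 switches noise off.
    """

    b: float = 9.5
    s: float = 0.7
    theta: float = 0.55
    p: float = 1.5
    dose_grid: tuple = STUDY_DOSE_GRID
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    carbon_source: str = "synthetic"
    response_kind: str = "biomass"

    def __post_init__(self) -> None:
        if self.b <= 0 or self.s <= 0 or self.theta <= 0 or self.p < 1:
            raise ValueError("require b>0, s>0, theta>0, p>=1")
        grid = np.asarray(self.dose_grid, float)
        if grid.min() != 0:
            raise ValueError("dose grid must include the control (dose 0)")
        if self.noise_cv < 0 or self.noise_cv > 0.5:
            raise ValueError(
                "noise CV above 50% refused: a Gamma fit to triplicates would "
                "be meaningless at that noise level"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def domain_end(self) -> float:
        return float(max(self.dose_grid))

    def mean(self, x):
        return peaked_mean(x, self.b, self.s, self.theta, self.p)

    def mean_derivative(self, x):
        return peaked_mean_derivative(x, self.b, self.s, self.theta, self.p)

    def curve(self) -> CallableCurve:
        return CallableCurve(fn=self.mean, domain=(0.0, self.domain_end),
                             dfn=self.mean_derivative)


@dataclass(frozen=True)
class TrueTraits:
    """Ground-truth traits of a synthetic mean curve (not from any fit)."""

    p_max: float
    t_max: float | None
    mu: float | None
    sigma: float | None
    f_at_pmax: float
    f_at_mu: float | None
    domain_end: float
    flags: tuple[str, ...] = ()


def generate(spec: SyntheticSpec) -> DoseResponseTable:
    """Draw a replicate-level dose-response table from the spec.

    Responses are Gamma(kappa, scale=m(x)/kappa); reproducible given the
    seed, with no global random state touched.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for d in spec.dose_grid:
        m = float(spec.mean(np.array([d]))[0])
        for rep in range(1, spec.n_replicates + 1):
            if spec.noise_cv == 0:
                val = m
            else:
                kappa = 1.0 / spec.noise_cv**2
                val = rng.gamma(shape=kappa, scale=m / kappa)
            rows.append({"dose": float(d), "response": val, "replicate": rep})
    return DoseResponseTable(
        carbon_source=spec.carbon_source,
        response_kind=spec.response_kind,
        frame=pd.DataFrame(rows),
        dose_unit="% w/v",
        response_unit="g L^-1" if spec.response_kind == "biomass" else "",
    )


def true_traits(spec: SyntheticSpec, grid_n: int = 1_000_001) -> TrueTraits:
    """Traits of the known mean curve m(x), on a dense grid.

    p_max is pinned to theta analytically (the family's only interior
    stationary point); t_max, mu, sigma come from the same trait machinery
    applied to m(x) at high resolution.  For the default family m(x) > b
    for every x > 0, so the curve never drops below the baseline and
    t_max is the end of the tested dose range (flagged accordingly).
    """
    curve = spec.curve()
    ts = extract_traits(curve, TraitConfig(grid_n=grid_n))
    # analytic stationary point overrides the numerical polish when interior
    p_max = spec.theta if spec.theta < spec.domain_end else ts.p_max
    return TrueTraits(
        p_max=float(p_max),
        t_max=ts.t_max,
        mu=ts.mu,
        sigma=ts.sigma,
        f_at_pmax=float(spec.mean(np.array([p_max]))[0]),
        f_at_mu=ts.f_at_mu,
        domain_end=spec.domain_end,
        flags=ts.flags,
    )
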