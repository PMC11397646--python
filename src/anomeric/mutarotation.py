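"""Mutarotation time-course analysis.

A freshly dissolved anomerically pure sugar (or sugar imine) relaxes to
its anomeric equilibrium.  With acyclic and oxazolidine intermediates
below NMR detection, the process is a reversible two-state
interconversion alpha <-> beta, whose beta-percentage follows
single-exponential approach-to-equilibrium kinetics:

    beta(t) = beta_eq + (beta_0 - beta_eq) * exp(-k t)

where ``k`` is the sum of forward and reverse first-order rate constants
(the observed relaxation rate, per hour here).  Series that are already
flat — the common case in pyridine, where anomerization is fast — are
detected before fitting and summarized by a trimmed mean instead of a
meaningless rate estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .thermo import (
    A_OH_CYCLOHEXANE,
    AnomerEquilibrium,
    AnomericStabilization,
    AValue,
    ThermoConstants,
    anomeric_stabilization,
)

__all__ = [
    "MutarotationSeries",
    "MutarotationFit",
    "FitConvergenceError",
    "fit_equilibration",
    "is_equilibrated",
    "equilibrium_to_stabilization",
]

#: Default flatness tolerance (percentage points of beta-anomer).  Chosen
#: so a series spanning up to 3.5 points — ordinary NMR integration
#: scatter — counts as equilibrated from the start.
DEFAULT_FLAT_TOL = 3.5


class FitConvergenceError(RuntimeError):
    """Kinetic fit failed to converge; carries the best grid estimate."""

    def __init__(self, message: str, best_estimate=None):
        super().__init__(message)
        self.best_estimate = best_estimate


@dataclass(frozen=True)
class MutarotationSeries:
    """Time course of the beta-anomer percentage for one compound."""

    compound_id: str
    solvent: str
    points: tuple[tuple[float, float], ...]  # (time in hours, % beta)

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(b)) for t, b in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValueError("a mutarotation series needs at least 3 points")
        times = [t for t, _ in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        # a freshly dissolved pure anomer legitimately reads 0 or 100%
        if any(not (0.0 <= b <= 100.0) for _, b in pts):
            raise ValueError("percent_beta values must lie in [0, 100]")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def percents(self) -> np.ndarray:
        return np.array([b for _, b in self.points])


@dataclass(frozen=True)
class MutarotationFit:
    """Fitted two-state equilibration parameters."""

    beta_eq: float          # equilibrium % beta
    beta_0: float           # extrapolated initial % beta
    rate_k: float           # observed relaxation rate, 1/h
    residual_rms: float     # percentage points
    equilibrated_from_start: bool

    def __post_init__(self) -> None:
        if self.rate_k < 0:
            raise ValueError("rate_k must be >= 0")
        if not (0.0 < self.beta_eq < 100.0):
            raise ValueError("beta_eq must lie in (0, 100)")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


def is_equilibrated(series: MutarotationSeries, tol: float = DEFAULT_FLAT_TOL) -> bool:
    """True iff the beta-percentage span (max - min) does not exceed ``tol``."""
    b = series.percents
    return float(b.max() - b.min()) <= tol


def _noise_estimate(percents: np.ndarray) -> float:
    """Point noise sigma from successive differences (robust to slow drift)."""
    diffs = np.diff(percents)
    if len(diffs) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(diffs - np.median(diffs))) / math.sqrt(2))


def _model(t: np.ndarray, beta_eq: float, beta_0: float, k: float) -> np.ndarray:
    return beta_eq + (beta_0 - beta_eq) * np.exp(-k * t)


def fit_equilibration(
    series: MutarotationSeries, flat_tol: float = DEFAULT_FLAT_TOL
) -> MutarotationFit:
    """Fit beta(t) = beta_eq + (beta_0 - beta_eq) exp(-k t) by least squares.

    A flatness test runs first: if the series span is within ``flat_tol``
    (or within twice the successive-difference noise estimate), the series
    is declared equilibrated from the start, ``beta_eq`` is a 20% trimmed
    mean and ``rate_k`` is 0 — fitting a rate to a flat series would only
    return noise.  Otherwise a bounded least-squares fit with multi-start
    over log-spaced rates is used.
    """
    t = series.times
    b = series.percents
    span = float(b.max() - b.min())
    if span <= flat_tol or span < 2.0 * _noise_estimate(b):
        beta_eq = float(stats.trim_mean(b, 0.2))
        rms = float(np.sqrt(np.mean((b - beta_eq) ** 2)))
        return MutarotationFit(beta_eq, beta_eq, 0.0, rms, True)

    def residuals(p):
        return _model(t, *p) - b

    t_scale = max(float(t[-1] - t[0]), 1e-12)
    best = None
    for k0 in np.geomspace(0.1 / t_scale, 100.0 / t_scale, 8):
        p0 = [float(b[-1]), float(b[0]), float(k0)]
        try:
            res = optimize.least_squares(
                residuals, p0,
                bounds=([1e-6, 0.0, 0.0], [100.0 - 1e-6, 100.0, np.inf]),
                ftol=1e-13, xtol=1e-13, gtol=1e-13,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        est = None if best is None else tuple(best.x)
        raise FitConvergenceError(
            f"kinetic fit did not converge for {series.compound_id!r}", est
        )
    beta_eq, beta_0, k = best.x
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return MutarotationFit(float(beta_eq), float(beta_0), float(k), rms, False)


def equilibrium_to_stabilization(
    fit: MutarotationFit,
    a: AValue = A_OH_CYCLOHEXANE,
    constants: ThermoConstants = ThermoConstants(),
    compound_id: str = "",
    solvent: str = "",
    temperature: float = 298.0,
) -> AnomericStabilization:
    """Anomeric stabilization E_an from a fitted equilibrium beta-percentage.

    Bridges the kinetic fit to the equilibrium thermodynamics: the fitted
    ``beta_eq`` defines the anomer populations fed to the E_an relation.
    """
    eq = AnomerEquilibrium(
        compound_id=compound_id,
        solvent=solvent,
        temperature=temperature,
        percent_beta=fit.beta_eq,
    )
    return anomeric_stabilization(eq, a, constants)
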