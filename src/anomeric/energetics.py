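"""Structure-derived energetics consumed as tables.

Three independent tools, each operating on quantities computed elsewhere
(quantum-chemistry geometries, NBO listings, dihedral-scan energies):

* an empirical hydrogen-bond strength from the donor...acceptor distance,
  ``E_HB (kcal/mol) = 5.554e5 * exp(-4.12 d)`` with d in Angstrom,
  returned as a positive stabilization magnitude (bond formation is
  stabilizing; the sign convention is carried separately);
* the NBO second-order perturbative donor->acceptor stabilization
  ``E2 = -q F^2 / (eps_i - eps_j)``, inputs in atomic units, output in
  kcal/mol;
* periodic torsional-profile analysis: stationary-point location with
  quadratic vertex refinement (reported minima commonly fall between
  grid nodes of a 15-degree scan) and a periodicity score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "HBOND_PREFACTOR",
    "HBOND_DECAY",
    "HARTREE_KCAL",
    "HBondGeometry",
    "NBOInteraction",
    "TorsionProfile",
    "StationaryPoint",
    "hbond_energy",
    "hbond_distance",
    "nbo_e2",
    "scan_extrema",
    "periodicity_score",
]

#: Empirical H-bond prefactor, kcal/mol.
HBOND_PREFACTOR = 5.554e5
#: Empirical H-bond exponential decay, 1/Angstrom.
HBOND_DECAY = 4.12
#: Conversion, kcal/mol per hartree.
HARTREE_KCAL = 627.5095

#: Sanity window for O...N donor-acceptor distances, Angstrom.
_D_MIN, _D_MAX = 1.5, 5.0


@dataclass(frozen=True)
class HBondGeometry:
    """Donor...acceptor heavy-atom distance for one hydrogen bond."""

    donor_label: str
    acceptor_label: str
    d_da: float  # Angstrom

    def __post_init__(self) -> None:
        if self.d_da <= 0:
            raise ValueError("distance must be positive")


@dataclass(frozen=True)
class NBOInteraction:
    """One donor->acceptor orbital interaction from an NBO listing (a.u.)."""

    donor_orbital: str
    acceptor_orbital: str
    occupancy_q: float
    fock_f_ij: float
    eps_donor: float
    eps_acceptor: float

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy_q <= 2.0):
            raise ValueError("orbital occupancy must lie in (0, 2]")
        if self.eps_donor == self.eps_acceptor:
            raise ValueError("degenerate donor/acceptor orbital energies")


@dataclass(frozen=True)
class TorsionProfile:
    """Relative energies on a uniform dihedral grid in [0, 360).

    Angles are reduced modulo 360 and sorted on construction; energies
    are shifted so the minimum is zero.
    """

    angles: tuple[float, ...]    # degrees
    energies: tuple[float, ...]  # kcal/mol, relative
    period_hint: float | None = None

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float) % 360.0
        en = np.asarray(self.energies, dtype=float)
        if ang.size != en.size:
            raise ValueError("angles and energies differ in length")
        if ang.size < 4:
            raise ValueError("need at least 4 grid points")
        order = np.argsort(ang)
        ang, en = ang[order], en[order]
        if np.unique(ang).size != ang.size:
            raise ValueError("duplicate grid angles after reduction mod 360")
        steps = np.diff(ang)
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise ValueError("grid must be uniform")
        en = en - en.min()
        object.__setattr__(self, "angles", tuple(ang))
        object.__setattr__(self, "energies", tuple(en))

    @property
    def step(self) -> float:
        return self.angles[1] - self.angles[0]


@dataclass(frozen=True)
class StationaryPoint:
    angle: float       # degrees, refined
    energy: float      # kcal/mol, refined
    kind: Literal["minimum", "maximum"]


def hbond_energy(geom: HBondGeometry, strict: bool = False) -> float:
    """Empirical hydrogen-bond stabilization magnitude in kcal/mol.

    ``5.554e5 * exp(-4.12 d)``; a distance of ~2.74-2.76 A maps to the
    6.5-7 kcal/mol range typical of a moderate O-H...N bond.  Distances
    outside the 1.5-5.0 A sanity window warn (or raise in strict mode)
    but the value is still computed.
    """
    if not (_D_MIN < geom.d_da < _D_MAX):
        msg = (f"d_DA = {geom.d_da} A outside the {_D_MIN}-{_D_MAX} A "
               "sanity window for heavy-atom H-bond contacts")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return HBOND_PREFACTOR * math.exp(-HBOND_DECAY * geom.d_da)


def hbond_distance(energy: float) -> float:
    """Donor...acceptor distance (A) implied by an H-bond magnitude (kcal/mol)."""
    if energy <= 0:
        raise ValueError("H-bond stabilization magnitude must be positive")
    return math.log(HBOND_PREFACTOR / energy) / HBOND_DECAY


def nbo_e2(x: NBOInteraction, inputs_in_kcal: bool = False) -> float:
    """Second-order NBO stabilization E2 = -q F^2 / (eps_i - eps_j), kcal/mol.

    With atomic-unit inputs (default) the hartree result is converted by
    627.5095; ``inputs_in_kcal`` passes pre-converted tables through
    unscaled.  E2 is positive for the usual case of a filled donor below
    an empty acceptor (eps_i - eps_j < 0).
    """
    e2 = -x.occupancy_q * x.fock_f_ij**2 / (x.eps_donor - x.eps_acceptor)
    return e2 if inputs_in_kcal else e2 * HARTREE_KCAL


def _refine(theta: float, step: float, e_prev: float, e0: float, e_next: float):
    """Parabolic vertex through a grid point and its two neighbours."""
    denom = e_prev - 2.0 * e0 + e_next
    if denom == 0.0:
        return theta, e0
    offset = 0.5 * step * (e_prev - e_next) / denom
    energy = e0 - 0.125 * (e_prev - e_next) ** 2 / denom
    return (theta + offset) % 360.0, energy


def scan_extrema(profile: TorsionProfile) -> list[StationaryPoint]:
    """Locate minima and maxima of a periodic torsion profile.

    The grid wraps around 360 degrees.  Each strict grid extremum is
    refined by fitting a parabola through it and its two neighbours,
    since true minima usually fall between grid nodes.  A flat profile
    yields an empty list.
    """
    e = np.asarray(profile.energies)
    a = np.asarray(profile.angles)
    if np.ptp(e) == 0.0:
        return []
    n = e.size
    out: list[StationaryPoint] = []
    for i in range(n):
        prev_e, next_e = e[(i - 1) % n], e[(i + 1) % n]
        if e[i] < prev_e and e[i] < next_e:
            kind = "minimum"
        elif e[i] > prev_e and e[i] > next_e:
            kind = "maximum"
        else:
            continue
        ang, en = _refine(a[i], profile.step, prev_e, e[i], next_e)
        out.append(StationaryPoint(ang, en, kind))
    return out


def periodicity_score(profile: TorsionProfile, period: float) -> float:
    """How well E(theta) repeats every ``period`` degrees, in [0, 1].

    1 - RMS(E(theta) - E(theta + period)) normalized by the profile's
    peak-to-peak range and clamped to [0, 1]; 1 means exact periodicity.
    The period must be a multiple of the grid step and divide 360.
    """
    if period <= 0 or abs(360.0 / period - round(360.0 / period)) > 1e-9:
        raise ValueError("period must divide 360 degrees")
    shift = period / profile.step
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError("period must be a multiple of the grid step")
    e = np.asarray(profile.energies)
    rng = float(np.ptp(e))
    if rng == 0.0:
        return 1.0
    shifted = np.roll(e, -int(round(shift)))
    rms = float(np.sqrt(np.mean((e - shifted) ** 2)))
    return max(0.0, 1.0 - rms / rng)
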