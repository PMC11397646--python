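"""Equilibrium thermodynamics of anomeric mixtures.

The anomeric stabilization ``E_an`` of a pyranose is the non-steric
preference of the anomeric substituent for the axial (alpha) orientation.
It is obtained by correcting the observed axial/equatorial free-energy
balance with the steric penalty of an axial substituent (its A-value):

    E_an = dG_an - dG_steric = -RT ln(K_an) + A_X,     K_an = [beta]/[alpha]

A positive ``E_an`` means the axial anomer is stabilized beyond what
sterics alone predict (the classical anomeric effect).  For 2-iminoaldose
Schiff bases the equatorial (beta) anomer instead dominates, and the
*reverse* anomeric effect (RAE) is quantified against a reference
tetrahydropyranol equilibrium:

    dG_rae = E_an(reference) - E_an(imine)

Two RT conventions are supported.  ``paper_rounded`` reproduces the
rounded coefficients customary in the printed literature analysis
(RT = 0.6 kcal/mol for anomeric equilibria at 298 K, 0.002*T for
A-value derivations); ``exact`` uses R = 1.987e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "GAS_CONSTANT_KCAL",
    "AnomerEquilibrium",
    "AValue",
    "ThermoConstants",
    "AnomericStabilization",
    "RAEResult",
    "InvalidPopulationError",
    "k_an",
    "delta_g_anomeric",
    "a_value_from_population",
    "a_value_cyclohexane_to_thp",
    "anomeric_stabilization",
    "rae_magnitude",
    "beta_fraction_from_dg",
    "dg_from_beta_fraction",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3

RingSystem = Literal["cyclohexane", "tetrahydropyran"]
RTMode = Literal["paper_rounded", "exact"]


class InvalidPopulationError(ValueError):
    """Anomer population outside the open interval (0, 100)%."""


@dataclass(frozen=True)
class AnomerEquilibrium:
    """Observed alpha/beta anomer populations for one compound in one solvent.

    ``percent_alpha`` may be omitted and is then filled as
    ``100 - percent_beta``.  Populations must be strictly inside (0, 100)
    and sum to 100 within 0.2 (printed-rounding tolerance).
    """

    compound_id: str
    solvent: str = ""
    temperature: float = 298.0
    percent_beta: float = 50.0
    percent_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.percent_alpha is None:
            object.__setattr__(self, "percent_alpha", 100.0 - self.percent_beta)
        if not (0.0 < self.percent_beta < 100.0):
            raise InvalidPopulationError(
                f"percent_beta={self.percent_beta} outside (0, 100)"
            )
        if not (0.0 < self.percent_alpha < 100.0):
            raise InvalidPopulationError(
                f"percent_alpha={self.percent_alpha} outside (0, 100)"
            )
        if abs(self.percent_alpha + self.percent_beta - 100.0) > 0.2:
            raise InvalidPopulationError(
                f"populations sum to {self.percent_alpha + self.percent_beta}, "
                "not 100 (tolerance 0.2)"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature={self.temperature} K must be > 0")


@dataclass(frozen=True)
class AValue:
    """Conformational free-energy preference (kcal/mol) of a substituent.

    The axial->equatorial free-energy penalty on a named ring system,
    positive when the equatorial arrangement is favored.
    """

    substituent: str
    ring_system: RingSystem
    value: float

    def __post_init__(self) -> None:
        if self.ring_system not in ("cyclohexane", "tetrahydropyran"):
            raise ValueError(f"unknown ring_system {self.ring_system!r}")
        if not math.isfinite(self.value):
            raise ValueError("A-value must be finite")


#: Hydroxyl A-value on cyclohexane (kcal/mol), from the 89:11
#: equatorial:axial cyclohexanol population in water.
A_OH_CYCLOHEXANE = AValue("OH", "cyclohexane", 1.25)

#: Hydroxyl A-value extrapolated to tetrahydropyran (kcal/mol).
A_OH_THP = AValue("OH", "tetrahydropyran", 1.93)


@dataclass(frozen=True)
class ThermoConstants:
    """RT handling for free-energy conversions.

    In ``paper_rounded`` mode the anomeric-equilibrium coefficient at
    298 K is fixed at 0.6 kcal/mol and A-value derivations use 0.002*T;
    ``exact`` uses gas_constant * T throughout.
    """

    gas_constant: float = GAS_CONSTANT_KCAL
    rt_mode: RTMode = "paper_rounded"

    def __post_init__(self) -> None:
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be > 0")
        if self.rt_mode not in ("paper_rounded", "exact"):
            raise ValueError(f"unknown rt_mode {self.rt_mode!r}")

    def rt_anomeric(self, temperature: float) -> float:
        """RT (kcal/mol) used for anomeric equilibrium free energies."""
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.rt_mode == "paper_rounded":
            # 0.6 at 298 K, scaled proportionally away from 298 K
            return 0.6 * temperature / 298.0
        return self.gas_constant * temperature

    def rt_steric(self, temperature: float) -> float:
        """RT (kcal/mol) used for A-value (steric) derivations."""
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.rt_mode == "paper_rounded":
            return 0.002 * temperature
        return self.gas_constant * temperature


@dataclass(frozen=True)
class AnomericStabilization:
    """Anomeric stabilization E_an (kcal/mol) and its provenance."""

    compound_id: str
    e_an: float
    a_value_used: AValue
    mode: Literal["eq4_cyclohexane", "eq7_thp"]


@dataclass(frozen=True)
class RAEResult:
    """Reverse-anomeric-effect magnitude dG_rae = E_an(ref) - E_an(imine)."""

    compound_id: str
    e_an_reference: float
    e_an_imine: float
    dg_rae: float


def k_an(eq: AnomerEquilibrium) -> float:
    """Anomerization equilibrium constant K_an = [beta]/[alpha].

    Strictly positive; the type invariants guarantee both populations lie
    in (0, 100).
    """
    return eq.percent_beta / eq.percent_alpha


def delta_g_anomeric(
    eq: AnomerEquilibrium, constants: ThermoConstants = ThermoConstants()
) -> float:
    """Observed anomeric free-energy change dG_an = -RT ln(K_an) in kcal/mol.

    Negative when the beta (equatorial) anomer dominates.
    """
    return -constants.rt_anomeric(eq.temperature) * math.log(k_an(eq))


def a_value_from_population(
    percent_equatorial: float,
    temperature: float = 298.0,
    constants: ThermoConstants = ThermoConstants(),
) -> AValue:
    """A-value (kcal/mol) from an observed equatorial population on cyclohexane.

    A = RT ln(eq/ax); positive when the equatorial conformer predominates.
    The canonical worked case is cyclohexanol: 89% equatorial at 298 K
    gives A_OH = 0.002*298*ln(89/11) = 1.25 kcal/mol.
    """
    if not (0.0 < percent_equatorial < 100.0):
        raise InvalidPopulationError(
            f"percent_equatorial={percent_equatorial} outside (0, 100); "
            "a pure conformer implies an infinite A-value"
        )
    rt = constants.rt_steric(temperature)
    value = rt * math.log(percent_equatorial / (100.0 - percent_equatorial))
    return AValue("from_population", "cyclohexane", value)


def a_value_cyclohexane_to_thp(a: AValue) -> AValue:
    """Extrapolate a cyclohexane A-value to tetrahydropyran.

    Empirical linear map A_THP = 1.53 * A_cyclohexane + 0.02 (kcal/mol),
    reflecting the shorter C-O bonds of the pyran ring which tighten 1,3-
    diaxial contacts.  Refuses tetrahydropyran input (no double conversion).
    """
    if a.ring_system != "cyclohexane":
        raise ValueError("A-value already refers to tetrahydropyran")
    return AValue(a.substituent, "tetrahydropyran", 1.53 * a.value + 0.02)


def anomeric_stabilization(
    eq: AnomerEquilibrium,
    a: AValue = A_OH_CYCLOHEXANE,
    constants: ThermoConstants = ThermoConstants(),
) -> AnomericStabilization:
    """Anomeric stabilization E_an = -RT ln(K_an) + A_X in kcal/mol.

    With the cyclohexane hydroxyl A-value (1.25) this is the
    ``-0.6 ln K_an + 1.25`` relation at 298 K in paper_rounded mode; with
    the tetrahydropyran value (1.93) the THP variant.  The reference
    tetrahydropyranol equilibrium 47.1% beta / 52.9% alpha yields
    E_an = 1.32 kcal/mol.
    """
    e_an = delta_g_anomeric(eq, constants) + a.value
    mode = "eq7_thp" if a.ring_system == "tetrahydropyran" else "eq4_cyclohexane"
    return AnomericStabilization(eq.compound_id, e_an, a, mode)


def rae_magnitude(
    e_an_reference: float, e_an_imine: float, compound_id: str = ""
) -> RAEResult:
    """Reverse-anomeric-effect magnitude dG_rae = E_an(ref) - E_an(imine).

    Positive dG_rae means the imine equilibrium is shifted toward the
    equatorial anomer beyond the reference anomeric effect, i.e. the RAE
    is operative.
    """
    if not (math.isfinite(e_an_reference) and math.isfinite(e_an_imine)):
        raise ValueError("E_an inputs must be finite")
    return RAEResult(
        compound_id, e_an_reference, e_an_imine, e_an_reference - e_an_imine
    )


def beta_fraction_from_dg(
    dg: float,
    temperature: float = 298.0,
    constants: ThermoConstants = ThermoConstants(gas_constant=GAS_CONSTANT_KCAL, rt_mode="exact"),
) -> float:
    """Boltzmann beta-anomer percentage from a relative free energy.

    [beta]% = 100 * exp(-dG/RT) / (1 + exp(-dG/RT)) with the convention
    dG = G(beta) - G(alpha): negative dG favors beta.  Smooth logistic in
    dG; returns 50 at dG = 0.
    """
    rt = constants.rt_anomeric(temperature)
    # logistic written to avoid overflow for large |dg|
    x = -dg / rt
    if x >= 0:
        return 100.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return 100.0 * e / (1.0 + e)


def dg_from_beta_fraction(
    percent_beta: float,
    temperature: float = 298.0,
    constants: ThermoConstants = ThermoConstants(gas_constant=GAS_CONSTANT_KCAL, rt_mode="exact"),
) -> float:
    """Exact inverse of :func:`beta_fraction_from_dg` (kcal/mol)."""
    if not (0.0 < percent_beta < 100.0):
        raise InvalidPopulationError(
            f"percent_beta={percent_beta} outside (0, 100)"
        )
    rt = constants.rt_anomeric(temperature)
    return -rt * math.log(percent_beta / (100.0 - percent_beta))
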