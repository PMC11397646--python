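"""Synthetic-data generators for every analysis stage.

Each generator emits tables with the statistical structure the analysis
assumes, together with the ground truth used to produce them, so that
round-trip recovery (generate -> analyze -> compare) is testable without
any external data.  The distributional choices (gaussian observables,
uniform anomeric stabilization, log-uniform rates) are fixture
conventions of this package, not claims about real spectra:

* equilibrium tables — draw an anomeric stabilization ``E_an``, invert
  ``E_an = -RT ln(K_an) + A`` to populations;
* mutarotation series — two-state exponential approach to equilibrium
  starting from a pure anomer (freshly dissolved crystals), plus
  gaussian integration noise;
* NMR observables — bimodal per-class gaussians centred on the standard
  diagnostic reference values (3J ~ 3.8 vs 8.0 Hz, 1J ~ 170 vs 160 Hz
  free / 177 vs 166 acetylated, rotations ~ +120 vs +35 deg in pyridine);
* torsion profiles — sums of cosine wells on a 15-degree grid; even
  multiplicities give exact 180-degree periodicity.

A single seeded :class:`numpy.random.Generator` drives every table, so a
seed fixes the entire output stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mutarotation import MutarotationSeries
from .nmr import NMRObservables
from .energetics import TorsionProfile
from .thermo import ThermoConstants

__all__ = [
    "SimulationConfig",
    "gen_equilibrium_dataset",
    "gen_mutarotation_series",
    "gen_nmr_observables",
    "gen_torsion_profile",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data stream; defaults are the study conditions."""

    seed: int = 0
    n_compounds: int = 20
    e_an_range: tuple[float, float] = (-1.0, 1.4)   # kcal/mol
    a_value: float = 1.25                           # kcal/mol
    temperature: float = 298.0                      # K
    rt_mode: str = "paper_rounded"
    noise_sigma_points: float = 0.5                 # % beta points
    rate_range: tuple[float, float] = (0.05, 5.0)   # 1/h
    beta_eq_range: tuple[float, float] = (75.0, 95.0)  # % beta
    sampling_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 72.0, 120.0)
    # (mean, sd) per observable, per class
    nmr_alpha_params: dict = field(default_factory=lambda: {
        "j_h1_h2": (3.8, 0.4),
        "one_bond_j_c1_h1": (170.0, 2.0),
        "one_bond_j_c1_h1_ac": (177.0, 2.0),
        "optical_rotation_d": (120.0, 15.0),
    })
    nmr_beta_params: dict = field(default_factory=lambda: {
        "j_h1_h2": (8.0, 0.7),
        "one_bond_j_c1_h1": (160.0, 2.0),
        "one_bond_j_c1_h1_ac": (166.0, 2.0),
        "optical_rotation_d": (35.0, 10.0),
    })
    torsion_terms: tuple[tuple[float, float, float], ...] = ((2.0, 2, 45.0),)
    torsion_step: float = 15.0                      # degrees
    torsion_noise_sigma: float = 0.0                # kcal/mol

    def __post_init__(self) -> None:
        for name in ("e_an_range", "rate_range", "beta_eq_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if self.noise_sigma_points < 0 or self.torsion_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def constants(self) -> ThermoConstants:
        return ThermoConstants(rt_mode=self.rt_mode)


def _beta_from_e_an(e_an: float, cfg: SimulationConfig) -> float:
    """Invert E_an = -RT ln(K_an) + A to the beta percentage."""
    rt = cfg.constants().rt_anomeric(cfg.temperature)
    k = np.exp(-(e_an - cfg.a_value) / rt)
    return 100.0 * k / (1.0 + k)


def gen_equilibrium_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Anomer-equilibrium table with known anomeric stabilizations.

    Draws ``E_an`` uniformly in ``e_an_range`` per compound and inverts
    the stabilization relation to populations.  Draws implying beta
    outside (0.1, 99.9)% are resampled and counted in the frame's
    ``attrs['n_resampled']``.  Columns include the ``true_e_an`` ground
    truth alongside the observable populations.
    """
    rng = cfg.rng() if rng is None else rng
    rows = []
    n_resampled = 0
    lo, hi = cfg.e_an_range
    for i in range(cfg.n_compounds):
        while True:
            e_an = float(rng.uniform(lo, hi))
            beta = _beta_from_e_an(e_an, cfg)
            if 0.1 < beta < 99.9:
                break
            n_resampled += 1
        rows.append({
            "compound_id": f"sim-{i:03d}",
            "solvent": "DMSO-d6",
            "temperature_K": cfg.temperature,
            "percent_beta": beta,
            "percent_alpha": 100.0 - beta,
            "true_e_an": e_an,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_resampled"] = n_resampled
    return df


def gen_mutarotation_series(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    compound_id: str = "sim-kin",
) -> tuple[MutarotationSeries, dict]:
    """One noisy approach-to-equilibrium series plus its ground truth.

    The start is a pure anomer (beta_0 = 100 or 0, as crystallized
    imines dissolve anomerically pure); beta_eq and the relaxation rate
    are drawn from the configured ranges, the rate log-uniformly.
    """
    rng = cfg.rng() if rng is None else rng
    beta_eq = float(rng.uniform(*cfg.beta_eq_range))
    k = float(np.exp(rng.uniform(np.log(cfg.rate_range[0]),
                                 np.log(cfg.rate_range[1]))))
    beta_0 = float(rng.choice([100.0, 0.0]))
    t = np.asarray(cfg.sampling_times, dtype=float)
    beta = beta_eq + (beta_0 - beta_eq) * np.exp(-k * t)
    beta = beta + rng.normal(0.0, cfg.noise_sigma_points, size=t.size)
    beta = np.clip(beta, 0.0, 100.0)
    series = MutarotationSeries(
        compound_id, "DMSO-d6", tuple(zip(t.tolist(), beta.tolist()))
    )
    truth = {"beta_eq": beta_eq, "beta_0": beta_0, "rate_k": k}
    return series, truth


def gen_nmr_observables(
    cfg: SimulationConfig,
    n: int = 100,
    rng: np.random.Generator | None = None,
    acetylated: bool = False,
    in_pyridine: bool = True,
) -> pd.DataFrame:
    """Labelled NMR-observable table with bimodal alpha/beta structure.

    Each row carries its ``true_anomer`` label; couplings are truncated
    at zero (physical bound).  Per-class parameters come from the
    config's ``nmr_alpha_params`` / ``nmr_beta_params``.
    """
    rng = cfg.rng() if rng is None else rng
    labels = rng.choice(["alpha", "beta"], size=n)
    rows = []
    key_1j = "one_bond_j_c1_h1_ac" if acetylated else "one_bond_j_c1_h1"
    for i, lab in enumerate(labels):
        p = cfg.nmr_alpha_params if lab == "alpha" else cfg.nmr_beta_params
        j12 = max(0.0, float(rng.normal(*p["j_h1_h2"])))
        j1 = max(0.0, float(rng.normal(*p[key_1j])))
        rot = float(rng.normal(*p["optical_rotation_d"]))
        rows.append({
            "species_id": f"nmr-{i:05d}",
            "j_h1_h2": j12,
            "one_bond_j_c1_h1": j1,
            "optical_rotation_d": rot,
            "rotation_solvent": "pyridine" if in_pyridine else "",
            "acetylated": acetylated,
            "true_anomer": lab,
        })
    return pd.DataFrame(rows)


def observables_from_row(row) -> NMRObservables:
    """Build :class:`NMRObservables` from one generated table row."""
    return NMRObservables(
        species_id=str(row["species_id"]),
        j_h1_h2=float(row["j_h1_h2"]),
        one_bond_j_c1_h1=float(row["one_bond_j_c1_h1"]),
        optical_rotation_d=float(row["optical_rotation_d"]),
        rotation_solvent=str(row["rotation_solvent"]),
        acetylated=bool(row["acetylated"]),
    )


def gen_torsion_profile(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TorsionProfile, dict]:
    """Periodic torsion profile from cosine wells, with true extrema.

    ``E(theta) = sum_i a_i (1 - cos(m_i (theta - phi_i)))`` sampled on the
    configured grid, optionally with gaussian noise.  True minima are
    located on a fine (0.01 degree) grid of the noiseless form.
    """
    if not cfg.torsion_terms:
        raise ValueError("torsion_terms must be non-empty")
    rng = cfg.rng() if rng is None else rng
    grid = np.arange(0.0, 360.0, cfg.torsion_step)

    def energy(theta):
        th = np.deg2rad(theta)
        e = np.zeros_like(th, dtype=float)
        for amp, mult, phase in cfg.torsion_terms:
            e += amp * (1.0 - np.cos(mult * (th - np.deg2rad(phase))))
        return e

    e = energy(grid)
    if cfg.torsion_noise_sigma > 0:
        e = e + rng.normal(0.0, cfg.torsion_noise_sigma, size=grid.size)
    profile = TorsionProfile(tuple(grid), tuple(e))

    fine = np.arange(0.0, 360.0, 0.01)
    ef = energy(fine)
    interior_min = (ef < np.roll(ef, 1)) & (ef < np.roll(ef, -1))
    interior_max = (ef > np.roll(ef, 1)) & (ef > np.roll(ef, -1))
    truth = {
        "minima_deg": fine[interior_min].tolist(),
        "maxima_deg": fine[interior_max].tolist(),
        "flat": bool(np.ptp(ef) < 1e-12),
    }
    return profile, truth
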