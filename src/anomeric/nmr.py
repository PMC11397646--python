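"""Rule-based anomer assignment and imine-geometry flags from NMR observables.

Diagnostics encoded here are the standard ones for pyranoid 2-aminoaldose
Schiff bases:

* ``3J(H1,H2)`` — small (~3.8 Hz) for the alpha anomer (equatorial H-1),
  large (~7-9 Hz) for beta (trans-diaxial H-1/H-2).
* ``1J(C1,H1)`` — ~170 Hz (alpha) vs ~160 Hz (beta) for free sugars,
  ~177 vs ~166 Hz for per-O-acetylated derivatives.
* specific rotation — alpha anomers typically [a]_D > +100 deg in
  pyridine, beta below +50 deg.
* ``J(CH=CH)`` ~16 Hz marks a trans (E) ethylene bridge;
  ``J(CH-CH=N)`` ~8.8 Hz an antiperiplanar imine/ethylene proton pair;
  paired 1H/13C signals at ~5-6 ppm / ~90-97 ppm would betray an
  oxazolidine ring.

Classification is a weighted vote.  3J(H1,H2) dominates (weight 2): it is
the diagnostic that settles cases where 1J(C1,H1) falls between the two
reference values.  Ties and all-abstain cases are reported as ambiguous,
never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "NMRObservables",
    "AnomerCall",
    "ClassifierWindows",
    "InsufficientEvidenceError",
    "classify_anomer",
    "geometry_flags",
]


class InsufficientEvidenceError(ValueError):
    """No diagnostic observable available for classification."""


@dataclass(frozen=True)
class NMRObservables:
    """Per-species spectroscopic observables; unknown fields stay ``None``."""

    species_id: str = ""
    j_h1_h2: float | None = None            # Hz
    one_bond_j_c1_h1: float | None = None   # Hz
    delta_c1: float | None = None           # ppm
    j_ch_eq_ch: float | None = None         # Hz, ethylene CH=CH
    j_ch_chn: float | None = None           # Hz, CH-CH=N
    optical_rotation_d: float | None = None  # degrees
    rotation_solvent: str = ""
    acetylated: bool = False
    extra_h_shifts: tuple[float, ...] | None = None  # ppm
    extra_c_shifts: tuple[float, ...] | None = None  # ppm

    def __post_init__(self) -> None:
        for name in ("j_h1_h2", "one_bond_j_c1_h1", "j_ch_eq_ch", "j_ch_chn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} Hz must be >= 0")
        for name in ("extra_h_shifts", "extra_c_shifts"):
            v = getattr(self, name)
            if v is not None and not isinstance(v, tuple):
                object.__setattr__(self, name, tuple(v))


@dataclass(frozen=True)
class ClassifierWindows:
    """Numeric decision windows; defaults separate every reference case."""

    j12_alpha_max: float = 4.5      # Hz: alpha if 3J(H1,H2) below
    j12_beta_min: float = 6.5       # Hz: beta if above; abstain between
    one_bond_ref_alpha: float = 170.0   # Hz, free sugars
    one_bond_ref_beta: float = 160.0
    one_bond_ref_alpha_ac: float = 177.0  # Hz, per-O-acetylated
    one_bond_ref_beta_ac: float = 166.0
    one_bond_band: float = 4.0      # Hz: confident if within band of a reference
    one_bond_abstain: float = 10.0  # Hz: abstain if farther than this from both
    rotation_alpha_min: float = 100.0   # deg, pyridine only
    rotation_beta_max: float = 50.0
    j12_weight: int = 2
    one_bond_weight: int = 1
    rotation_weight: int = 1


@dataclass(frozen=True)
class AnomerCall:
    """Classification outcome with its evidence trail.

    ``evidence`` lists (rule_name, observed_value, vote) for every rule
    that saw data; ``call`` is ambiguous exactly when the weighted votes
    tie or every rule abstains.
    """

    species_id: str
    call: str  # "alpha" | "beta" | "ambiguous"
    evidence: tuple[tuple[str, float, str], ...] = ()
    flags: tuple[str, ...] = ()


def _vote_j12(obs: NMRObservables, w: ClassifierWindows) -> str | None:
    if obs.j_h1_h2 is None:
        return None
    if obs.j_h1_h2 < w.j12_alpha_max:
        return "alpha"
    if obs.j_h1_h2 > w.j12_beta_min:
        return "beta"
    return "abstain"


def _vote_one_bond(obs: NMRObservables, w: ClassifierWindows) -> str | None:
    j = obs.one_bond_j_c1_h1
    if j is None:
        return None
    ref_a = w.one_bond_ref_alpha_ac if obs.acetylated else w.one_bond_ref_alpha
    ref_b = w.one_bond_ref_beta_ac if obs.acetylated else w.one_bond_ref_beta
    da, db = abs(j - ref_a), abs(j - ref_b)
    if da > w.one_bond_abstain and db > w.one_bond_abstain:
        return "abstain"
    if da <= w.one_bond_band and da < db:
        return "alpha"
    if db <= w.one_bond_band and db < da:
        return "beta"
    # between the bands: nearest-reference vote
    if da == db:
        return "abstain"
    return "alpha" if da < db else "beta"


def _vote_rotation(obs: NMRObservables, w: ClassifierWindows) -> str | None:
    if obs.optical_rotation_d is None:
        return None
    if obs.rotation_solvent.strip().lower() != "pyridine":
        return None
    if obs.optical_rotation_d > w.rotation_alpha_min:
        return "alpha"
    if obs.optical_rotation_d < w.rotation_beta_max:
        return "beta"
    return "abstain"


def classify_anomer(
    obs: NMRObservables, windows: ClassifierWindows = ClassifierWindows()
) -> AnomerCall:
    """Assign alpha/beta anomeric configuration by weighted rule vote.

    Requires at least one of 3J(H1,H2), 1J(C1,H1) or an optical rotation;
    raises :class:`InsufficientEvidenceError` otherwise.  The result is
    deterministic in the observables and window settings.
    """
    rules = (
        ("j_h1_h2", obs.j_h1_h2, _vote_j12(obs, windows), windows.j12_weight),
        ("one_bond_j_c1_h1", obs.one_bond_j_c1_h1,
         _vote_one_bond(obs, windows), windows.one_bond_weight),
        ("optical_rotation", obs.optical_rotation_d,
         _vote_rotation(obs, windows), windows.rotation_weight),
    )
    if all(vote is None for _, _, vote, _ in rules):
        raise InsufficientEvidenceError(
            f"species {obs.species_id!r}: no diagnostic observable "
            "(need 3J(H1,H2), 1J(C1,H1) or a rotation in pyridine)"
        )
    evidence = []
    score = {"alpha": 0, "beta": 0}
    for name, observed, vote, weight in rules:
        if vote is None:
            continue
        evidence.append((name, float(observed), vote))
        if vote in score:
            score[vote] += weight
    if score["alpha"] > score["beta"]:
        call = "alpha"
    elif score["beta"] > score["alpha"]:
        call = "beta"
    else:
        call = "ambiguous"
    return AnomerCall(
        obs.species_id, call, tuple(evidence), geometry_flags(obs)
    )


def geometry_flags(obs: NMRObservables) -> tuple[str, ...]:
    """Geometry findings derivable without an anomer call.

    * ``E_double_bond`` — J(CH=CH) in [14, 18] Hz (trans ethylene).
    * ``antiperiplanar_imine`` — J(CH-CH=N) in [7.5, 10] Hz.
    * ``oxazolidine_suspected`` — paired 1H signal in 5-6 ppm and 13C
      signal in 90-97 ppm; ``oxazolidine_absent`` when both shift lists
      were supplied but the windows are not jointly hit.
    """
    flags: list[str] = []
    if obs.j_ch_eq_ch is not None and 14.0 <= obs.j_ch_eq_ch <= 18.0:
        flags.append("E_double_bond")
    if obs.j_ch_chn is not None and 7.5 <= obs.j_ch_chn <= 10.0:
        flags.append("antiperiplanar_imine")
    if obs.extra_h_shifts is not None and obs.extra_c_shifts is not None:
        h_hit = any(5.0 <= h <= 6.0 for h in obs.extra_h_shifts)
        c_hit = any(90.0 <= c <= 97.0 for c in obs.extra_c_shifts)
        flags.append("oxazolidine_suspected" if (h_hit and c_hit)
                     else "oxazolidine_absent")
    return tuple(flags)
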