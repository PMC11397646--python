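# Methods

## Thermodynamic model

The package treats every anomeric mixture as a two-state equilibrium
alpha (axial) ⇌ beta (equatorial) with `K_an = [beta]/[alpha]` taken
directly from observed populations; the populations themselves (NMR
integrals) are accepted as given, with no propagation of integration
error. The anomeric stabilization is the steric-corrected axial
preference

    E_an = −RT ln K_an + A_X,

with the A-value playing the role of the steric free-energy penalty
`ΔG°_steric = −A_X`. The reverse-anomeric-effect magnitude is the
difference `ΔG°_rae = E_an(reference) − E_an(imine)` against a
reference tetrahydropyranol equilibrium (default 47.1% beta in DMSO,
giving `E_an = 1.32 kcal/mol` with `A_OH = 1.25`); positive values mean
the imine is shifted toward the equatorial anomer beyond the reference
anomeric effect.

**RT conventions.** The literature analysis this package supports mixes
two rounded RT coefficients at 298 K: 0.6 kcal/mol for anomeric
equilibria and 0.002·T (= 0.596) for A-value derivations. Both are
retained behind `ThermoConstants(rt_mode=...)`: `paper_rounded`
(default) reproduces printed two-decimal values bit-for-bit;
`exact` uses R = 1.987×10⁻³ kcal/(mol·K) throughout. For populations
between 10 and 90% the two conventions differ by less than
0.02 kcal/mol (asserted in the test suite). In `paper_rounded` mode the
0.6 coefficient is scaled by T/298 away from 298 K so temperature
remains meaningful.

**Sign conventions.** `ΔG°_an = −RT ln([β]/[α])` is negative when beta
dominates. The Boltzmann beta-fraction uses `ΔG = G(β) − G(α)`, so
negative ΔG yields beta-majorities; it returns exactly 50% at ΔG = 0
and round-trips its closed-form inverse to 1e-9 over ±5 kcal/mol.
Its default RT convention is `exact`, since it serves computed
free-energy tables rather than printed worked values.

**A-value extrapolation.** `A^THP = 1.53·A^cyclohexane + 0.02`
(kcal/mol). The operation refuses input already on tetrahydropyran so
the linear map cannot be applied twice. Using the tetrahydropyran
hydroxyl value (1.93) instead of the cyclohexane one (1.25) raises any
`E_an` by exactly 0.68 kcal/mol; both variants are reported by the
pipeline because which one a given tabulation assumes is often
ambiguous in practice.

## Anomer classification

A deterministic weighted vote over three rules, with all windows
configurable (`ClassifierWindows`):

| rule | alpha | beta | abstains | weight |
|---|---|---|---|---|
| ³J(H1,H2) | < 4.5 Hz | > 6.5 Hz | between | 2 |
| ¹J(C1,H1) | within 4 Hz of 170 (177 acetylated) | within 4 Hz of 160 (166) | > 10 Hz from both | 1 |
| [α]_D (pyridine only) | > +100° | < +50° | between | 1 |

A ¹J value between the reference bands votes for the nearest reference.
`³J(H1,H2)` carries double weight because it settles exactly the cases
where ¹J is intermediate (e.g. a genuine alpha species with
³J = 3.3 Hz but ¹J = 165.5 Hz). The rotation rule is restricted to
pyridine because the thresholds are solvent-specific. Ties and
all-abstain cases return `ambiguous` — there is no hidden tie-break.
With conflicting evidence, dropping the dominant observable can
legitimately change a call; the no-direct-flip property is therefore
asserted for concordant evidence (all present rules voting the same
way), which is the regime the generator's class distributions occupy.

Geometry flags are independent of the anomer call: a trans (E) ethylene
bridge from J(CH=CH) in 14–18 Hz, an antiperiplanar imine/ethylene
proton pair from J(CH–CH=N) in 7.5–10 Hz, and an oxazolidine suspicion
only when a ¹H signal in 5–6 ppm and a ¹³C signal in 90–97 ppm co-occur.

## Mutarotation kinetics

Model: `β(t) = β_eq + (β₀ − β_eq)·e^(−kt)`, the closed-form solution of
reversible first-order two-state interconversion; k is the sum of the
forward and reverse rate constants (units 1/h; day-labelled inputs are
converted on read, 1 d = 24 h; an untimed final reading is ingested at
7 d by convention and flagged). Multi-species kinetics (acyclic or
oxazolidine intermediates) are out of scope because such species stay
below NMR detection in the systems this models.

**Flatness gate.** Fitting a rate to an already-equilibrated series
returns noise, so a flatness test precedes the fit: a series is flat
when its span (max − min) is within `flat_tol` — default 3.5 points,
sized to ordinary NMR integration scatter — or within twice a robust
noise estimate (1.4826·MAD of successive differences / √2). A span
threshold alone is used as the primary gate because realistic flat
series of 5–10 points routinely span more than twice the
point-to-point noise sigma. Flat series report a 20% trimmed mean as
`β_eq`, `k = 0`, and `equilibrated_from_start = True`.

**Optimizer.** Bounded trust-region least squares (`scipy
least_squares`, ftol/xtol/gtol 1e-13) with multi-start over eight
log-spaced rate guesses spanning 0.1–100 relaxations per observation
window; `β_eq` is constrained to (0, 100), `β₀` to [0, 100] (a pure
anomer reading of exactly 0 or 100% is physical at t = 0). Noiseless
data are recovered to ~1e-6; under gaussian noise the β_eq error is
noise-limited (median < 1 point at σ = 0.5 on the default sampling
grid) and grows monotonically with σ, as the simulation tests assert.

## Structure-derived energetics

All inputs here are tables produced elsewhere (quantum-chemistry
geometries, NBO listings, scan energies); no electronic-structure
computation is performed.

* **H-bond strength**: `E_HB = 5.554×10⁵·exp(−4.12·d_DA)` kcal/mol with
  d in Å. The relationship is conventionally written with a leading
  minus (bond formation is stabilizing); the function returns the
  positive magnitude and the reports carry the stabilizing-sign
  convention explicitly. Distances outside a 1.5–5.0 Å sanity window
  warn (or raise in strict mode). The closed-form inverse round-trips
  to 1e-9.
* **NBO E2**: `−q·F²/(ε_i − ε_j)` with atomic-unit inputs converted by
  627.5095 kcal/mol per hartree; a pass-through mode serves
  pre-converted tables. Degenerate orbital energies are rejected.
* **Torsion profiles**: uniform periodic grids (default 15°); energies
  are re-zeroed to the grid minimum on construction and angle labels
  reduced mod 360, so shifted labellings give identical results. Grid
  extrema (strict cyclic comparisons) are refined by a parabolic vertex
  through the point and its two neighbours, which recovers minima lying
  between grid nodes to well under 2°. Plateaus (exactly equal
  neighbours) are not reported as extrema. The periodicity score is
  `1 − RMS(E(θ) − E(θ+period)) / (max−min)`, clamped to [0, 1]; flat
  profiles score 1 and return no extrema, with the flat case flagged.

## Synthetic data

The generators emit fixtures with the statistical structure the
analyses assume, plus ground truth, from one seeded numpy Generator, so
a seed fixes every table. Defaults describe the modelled study
conditions: equilibria from `E_an` uniform on (−1.0, 1.4) kcal/mol
(spanning strongly RAE-shifted imines up to reference-like values) with
resampling outside 0.1–99.9% beta; kinetics from pure-anomer starts
(β₀ ∈ {100, 0}), β_eq uniform on 75–95%, rates log-uniform on
0.05–5 /h, gaussian noise σ = 0.5 points on a 0–120 h sampling grid;
NMR observables as per-class gaussians centred on the diagnostic
reference values in the classifier table above, truncated at zero;
torsion profiles as sums of cosine wells `a(1 − cos m(θ−φ))`.

What the generators deliberately do **not** emulate: correlated errors
between observables of one species, solvent- and
substituent-dependent shifts of the NMR reference centres, baseline or
phasing artefacts, multi-exponential kinetics, and scan noise models
beyond i.i.d. gaussians. Passing round-trip tests therefore
demonstrates internal consistency of the estimators under the stated
model, not performance on real spectra.

## Pipeline and I/O

CSV in (UTF-8, comma, "." decimal, case-insensitive headers), JSON/CSV
reports out. Every row is validated against the type invariants; bad
rows go to an error report with reasons, and a file with more than 50%
invalid rows fails hard. Reports carry full-precision values plus
2-decimal display fields (matching tabulation practice in the field), a
provenance block with the package version and a config hash, and are
byte-identical across reruns of the same inputs. Per-compound failures
are isolated; one bad compound never aborts a run. Equilibrium
populations must be strictly inside (0, 100) and sum to 100 within 0.2
(printed-rounding tolerance); mutarotation points admit the closed
interval, since a freshly dissolved pure anomer legitimately reads
100%.

## Problem sizes

The test suite runs classifier-accuracy checks on 10,000 generator
draws, Monte-Carlo fitter calibrations on 25–40 replicate series, and
1,000-case property sweeps for the thermodynamic identities; these
sizes make the whole suite complete in well under a minute while
leaving the Monte-Carlo tolerances comfortably resolved.

## Known limitations

* A-values are inputs, never estimated from structure; no solvent-model
  corrections are applied to them.
* The RAE quantification inherits the arbitrariness of any
  steric/electronic decomposition; `rt_mode` and the A-value choice are
  exposed precisely because reasonable conventions differ at the
  0.01–0.05 kcal/mol level.
* The classifier encodes windows for pyranoid 2-amino sugars and their
  acetates; other ring sizes or substitution patterns need retuned
  windows.
* The kinetic model cannot represent catalysis (acid/base-dependent
  rates) except implicitly through k.
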