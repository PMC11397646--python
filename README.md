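# anomeric

Quantitative analysis of anomeric equilibria in pyranose sugars and
their Schiff bases (2-iminoaldoses), built for carbohydrate NMR and
conformational-analysis work: given observed alpha/beta anomer
populations, the package separates the stereoelectronic part of the
axial/equatorial preference from the steric part, quantifies the
*reverse anomeric effect* (RAE), and supports that analysis with
rule-based anomer assignment from NMR observables, mutarotation
kinetics, and structure-derived energetics consumed as tables.

## The model

For an alpha (axial) ⇌ beta (equatorial) anomeric equilibrium with
`K_an = [beta]/[alpha]`, the **anomeric stabilization** is the axial
preference left after removing sterics:

```
E_an = ΔG°_an − ΔG°_steric = −RT ln K_an + A_X
```

where `A_X` is the substituent's conformational A-value
(`A = RT ln(eq/ax)` from a model cyclohexane population; for hydroxyl,
89% equatorial cyclohexanol gives `A_OH = 1.25 kcal/mol`, extrapolated
to tetrahydropyran by `A^THP = 1.53·A + 0.02 = 1.93`). Sugar imines
show beta-dominant equilibria — the opposite of the classical anomeric
effect — because an intramolecular O–H…N hydrogen bond in the alpha
anomer quenches the exo-anomeric donation. The RAE magnitude is

```
ΔG°_rae = E_an(reference) − E_an(imine)
```

against a reference tetrahydropyranol equilibrium (47.1% beta in DMSO,
`E_an = 1.32 kcal/mol`). Around this core the package provides:

* Boltzmann beta-fractions from relative free energies,
  `[β]% = 100·exp(−ΔG/RT)/(1+exp(−ΔG/RT))`, and the exact inverse;
* a weighted-vote anomer classifier from `³J(H1,H2)`, `¹J(C1,H1)` and
  specific rotation, plus imine-geometry flags;
* single-exponential approach-to-equilibrium fits
  `β(t) = β_eq + (β₀ − β_eq)e^(−kt)` with flat-series detection;
* the empirical H-bond strength `E_HB = 5.554×10⁵ exp(−4.12 d_DA)`,
  NBO second-order stabilization `E2 = −q F²/(ε_i − ε_j)`, and
  periodic dihedral-scan analysis (refined extrema, periodicity score);
* seeded synthetic-data generators with ground truth for every stage.

## Worked example

```python
from anomeric import (AnomerEquilibrium, ThermoConstants,
                      a_value_from_population, anomeric_stabilization,
                      rae_magnitude)

constants = ThermoConstants(rt_mode="paper_rounded")
a_oh = a_value_from_population(89.0, 298.0, constants)   # 1.25 kcal/mol

ref = AnomerEquilibrium("reference", "DMSO-d6", 298.0, 47.1, 52.9)
imine = AnomerEquilibrium("heptose-imine", "pyridine-d5", 298.0, 86.7, 13.3)
e_ref = anomeric_stabilization(ref, a_oh, constants).e_an    # 1.32
e_imi = anomeric_stabilization(imine, a_oh, constants).e_an  # 0.13
print(rae_magnitude(e_ref, e_imi).dg_rae)                    # 1.19
```

Output `1.19 kcal/mol`: the imine's equatorial preference exceeds the
steric-plus-anomeric expectation by more than 1 kcal/mol — the reverse
anomeric effect. The scripts in `examples/` walk through each
capability (`python examples/quantify_anomeric_effect.py` prints the
numbers above with the intermediate `K_an` and `ΔG°_an`).

A thin CLI mirrors the library: `anomeric thermo|assign|mutarotate|
scan|hbond|nbo|simulate|pipeline` read CSV tables and write JSON/CSV
reports (`anomeric simulate --seed 0 --out sim/` writes a full
synthetic fixture bundle with ground truth).

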