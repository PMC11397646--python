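"""Structure-derived energetics: H-bond strength and NBO stabilization.

Evaluates the empirical donor-acceptor distance relationship for the
O-H...N bond that quenches the exo-anomeric effect in alpha anomers,
and the second-order NBO stabilization of representative donor->acceptor
orbital interactions.
"""

from anomeric import (
    HBondGeometry,
    NBOInteraction,
    hbond_distance,
    hbond_energy,
    nbo_e2,
)

print("Empirical H-bond strength E_HB = 5.554e5 exp(-4.12 d):")
for d in (2.738, 2.756, 2.90):
    e = hbond_energy(HBondGeometry("O(anomeric OH)", "N(imine)", d))
    print(f"  d = {d:.3f} A -> {e:.2f} kcal/mol")
print("The 2.74-2.76 A contacts give 6.5-7 kcal/mol: a moderate-strength")
print(f"O-H...N bond.  Inverse: 6.5 kcal/mol -> {hbond_distance(6.5):.3f} A")

print("\nSecond-order NBO stabilization E2 = -q F^2 / (eps_i - eps_j):")
interactions = [
    NBOInteraction("n(O_ring)", "sigma*(C1-O_exo)", 2.0, 0.072, -0.50, 0.02),
    NBOInteraction("n(O_exo)", "sigma*(C1-O_ring)", 2.0, 0.0798, -0.53, 0.0),
]
for x in interactions:
    print(f"  {x.donor_orbital} -> {x.acceptor_orbital}: "
          f"E2 = {nbo_e2(x):.1f} kcal/mol")
print("The second row is an exo-anomeric-type donation in the 15-17")
print("kcal/mol band; its loss in the H-bonded alpha anomer is what the")
print("reverse anomeric effect quantifies thermodynamically.")
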