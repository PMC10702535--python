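# sasamc

Coarse-grained, implicit-water/implicit-salt Monte Carlo simulation of
small associating solutes, with the analysis layers that recover full
ternary (water–solute–salt) solution thermodynamics: Kirkwood–Buff
inversion and vapor-pressure-osmometry (VPO) style salting-out
analysis.  The default molecule is caffeine, the textbook example of a
solute whose self-association (face-to-face ring stacking) modulates
how strongly Hofmeister salts salt it in or out.

## The model

A molecule is a rigid body of spherical beads (for caffeine: two
heterocyclic rings, three methyls, two carbonyl oxygens, one −N=CH−
group).  The potential energy couples a purely repulsive
Weeks–Chandler–Andersen core to a solvent-accessible-surface-area
(SASA) pair term and a one-body transfer term,

    U = Σ u_WCA(r_ab) + Σ (γ_ab + ε_ab,TFE·c_s)·ΔA_ab(r_ab)
        + N·c_s·Σ_i ε_i,TFE·A_i^ref

where ΔA_ab is the two-sphere overlap (lens) area change of
probe-inflated beads, γ is a microscopic surface tension (attraction in
neat water, 0.0572 kJ/mol/Å² on the ring beads), and ε_TFE is a
salt-specific transfer free energy per area and molar salt
concentration — positive for salting-out (Na₂SO₄: 0.0178), negative for
salting-in (NaSCN: −0.008).  Sampling runs in the canonical or grand
canonical ensemble with translation/rotation, cluster and
insertion/deletion moves; estimators include RDFs and Kirkwood–Buff
integrals, preferential binding Γ₂₃, virtual-volume pressure and
osmotic coefficient φ, and Widom / grand-canonical excess chemical
potentials.

On top sits an analytic thermodynamic layer: the solute activity model

    ln γ₂ = A₂m₂ + B₂m₂² + (C₁ + C₂m₂)·m₃,    k_s(m₂) = C₁ + C₂m₂

with a Gibbs–Duhem-exact water activity, ternary Kirkwood–Buff
inversion (all six G_ij from activity derivatives, partial molar
volumes and compressibility), and the osmometry pipeline
ΔOsm = Osm(m₂,m₃) − Osm(m₂,0) − Osm(0,m₃) = (C₁+C₂m₂)m₂m₃ with
error-propagated generalized-least-squares fits.  See
`docs/methods.md` for the science, conventions and limitations.

## Worked example

Recover the full caffeine–salt interaction from a fitted activity model
via an in-silico osmometry experiment and KB inversion:

```python
import numpy as np
from sasamc import ActivityModel, in_silico_vpo, kb_invert, SolutionComposition

model = ActivityModel(A2=-7.2399, B2=24.9741, C1=0.8061, C2=-8.0176,
                      A3=-0.3506, B3=0.2087, nu3=3)   # a salting-out salt
out = in_silico_vpo(model, np.linspace(0.01, 0.05, 5), np.linspace(0.05, 0.5, 6))
fit = out["ks_fit"]
print(f"C1 = {fit.C1:.4f}  C2 = {fit.C2:.4f}")
print(f"k_s(m2=0.00) = {float(fit.ks(0.0)):.3f} /molal")
print(f"k_s(m2=0.05) = {float(fit.ks(0.05)):.3f} /molal")
kb = kb_invert(SolutionComposition(0.03, 0.3), model, vbar=(18.14, 145.9, 16.62))
print("G22 =", round(kb.G[1, 1], 1), "A^3 |", round(kb.G[1, 1] * 6.02214076e-4, 2), "L/mol")
```

prints

```
C1 = 0.8061  C2 = -8.0176
k_s(m2=0.00) = 0.806 /molal
k_s(m2=0.05) = 0.405 /molal
G22 = 17662.4 A^3 | 10.64 L/mol
```

The osmometry pipeline returns exactly the generating caffeine–salt
coefficients (the ΔOsm surface of the model is identically
(C₁+C₂m₂)m₂m₃), the salting-out constant k_s weakens linearly with
caffeine molality — salts grip the monomer hardest, self-associated
caffeine less — and the inverted KB integral G22 quantifies
caffeine–caffeine clustering at (m₂, m₃) = (0.03, 0.3) mol/kg.

Simulations run through the same package:

```sh
sasamc run --config run.yaml --seed 1 --out out/
sasamc vpo --osm table.csv --out fits.json
sasamc calibrate tfe --target dmu.csv --activity 0.026 --out eps.json
sasamc analyze --model model.json --out kb.csv
```

where `run.yaml` defaults to the canonical study protocol (250 Å box,
0.25 Å RDF bins, 5 Å³ virtual-volume perturbation, 6.5 Å cluster
threshold, 25 Widom insertions per sampling event).

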