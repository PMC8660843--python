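"""Coulomb coupling and rigid-sphere overlap for a toy pigment pair.

Two net-neutral 4-atom chromophores are separated along z; the transition-
charge Coulomb coupling falls off as the dipole-dipole 1/r^3 law at long
range while the sphere-overlap parameter vanishes as soon as the vdW
spheres lose contact.
"""

import numpy as np

import lhcquench as lq

print(f"{'r (A)':>7} {'V (cm^-1)':>12} {'overlap (A^3)':>14}")
for r in (3.0, 3.5, 4.0, 6.0, 10.0, 50.0):
    pair = lq.generate_pigment_pair(separation=r, rotation=20.0)
    v = lq.coulomb_coupling(pair.coords_a, pair.charges_a.charges_e,
                            pair.coords_b, pair.charges_b.charges_e)
    o = lq.overlap_parameter(pair.coords_a, pair.elements_a,
                             pair.coords_b, pair.elements_b)
    print(f"{r:7.1f} {v:12.4f} {o:14.4f}")
# The overlap hits zero once atom spheres separate (> 2 x 1.7 A for carbon)
# while the Coulomb term persists at long range — the geometric picture
# behind short-range vs Coulomb quenching channels.

rs = np.geomspace(50, 500, 12)
vs = [abs(lq.coulomb_coupling(p.coords_a, p.charges_a.charges_e,
                              p.coords_b, p.charges_b.charges_e))
      for p in (lq.generate_pigment_pair(r) for r in rs)]
slope = np.polyfit(np.log(rs), np.log(vs), 1)[0]
print(f"\nfar-field log-log slope of |V| vs r: {slope:.4f} (dipole-dipole: -3)")
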