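# Reduced-model energy parameters, version 1.
# Lennard-Jones per atom class as (eps kcal/mol, rmin Angstrom); pair
# coefficients combine geometrically on A = eps*rmin^12 and B = 2*eps*rmin^6.
# Charges are partial charges (e); electrostatics use 332*q_i*q_j/(D*r).
# Torsion barriers as (u0 kcal/mol, periodicity n, phase theta0 deg).
# Hydrogen bond 12-10 coefficients tuned to a ~2 kcal/mol well at 2.9 A.
version: "1"
lj:
  N:  {eps: 0.16, rmin: 3.60}
  CA: {eps: 0.11, rmin: 3.70}
  C:  {eps: 0.11, rmin: 3.70}
  O:  {eps: 0.20, rmin: 3.20}
  H:  {eps: 0.02, rmin: 2.20}
  CB: {eps: 0.14, rmin: 4.00}
  SC: {eps: 0.14, rmin: 4.00}
charges:
  N: -0.35
  H: 0.25
  CA: 0.10
  C: 0.45
  O: -0.45
  CB: 0.0
  SC: 0.0
dielectric: 2.0
coulomb_constant: 332.0
torsion:
  phi: {u0: 1.0, n: 3, theta0: 0.0}
  psi: {u0: 1.0, n: 3, theta0: 0.0}
  omega: {u0: 20.0, n: 2, theta0: 180.0}
  chi: {u0: 2.8, n: 3, theta0: 0.0}
hbond:
  a: 3538000.0
  b: 504800.0
clash_radius: 1.0e-06
clash_penalty: 1.0e+06
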