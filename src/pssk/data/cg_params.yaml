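# One-bead-per-residue coarse-grained parameters.
#
# lambda: per-residue hydropathy-scale stickiness in [0, 1] (pairwise values
#   combined by arithmetic mean); sigma_nm: per-residue diameter in nm
#   (pairwise arithmetic mean); mass_amu: residue masses; charge_e: fixed
#   charges of the cg scheme (His +0.5e).
# The phosphoresidue entries (pS, pT) are provisional defaults: charge -2e,
# diameters enlarged by the phosphate group, lambda lowered towards the
# charged/hydrophilic end of the scale.
# eps_lj is the LJ well depth in kJ/mol; lambda_arg_arg_override replaces the
# combined Arg-Arg lambda AFTER pair combination so excluded volume is not
# lost for the zero-lambda arginine pair.

eps_lj: 0.8368
lambda_arg_arg_override: 0.01
bond_k: 1000.0        # kJ/mol/nm^2
bond_r0: 0.38         # nm
debye_length: 1.0     # nm
dielectric: 80.0
coulomb_cutoff: 3.5   # nm
lj_cutoff_sigmas: 3.0

residues:
  A: {lambda: 0.730, sigma_nm: 0.504, mass_amu: 71.08, charge_e: 0.0}
  R: {lambda: 0.000, sigma_nm: 0.656, mass_amu: 156.19, charge_e: 1.0}
  N: {lambda: 0.432, sigma_nm: 0.568, mass_amu: 114.10, charge_e: 0.0}
  D: {lambda: 0.378, sigma_nm: 0.558, mass_amu: 115.09, charge_e: -1.0}
  C: {lambda: 0.595, sigma_nm: 0.548, mass_amu: 103.14, charge_e: 0.0}
  Q: {lambda: 0.514, sigma_nm: 0.602, mass_amu: 128.13, charge_e: 0.0}
  E: {lambda: 0.459, sigma_nm: 0.592, mass_amu: 129.12, charge_e: -1.0}
  G: {lambda: 0.649, sigma_nm: 0.450, mass_amu: 57.05, charge_e: 0.0}
  H: {lambda: 0.514, sigma_nm: 0.608, mass_amu: 137.14, charge_e: 0.5}
  I: {lambda: 0.973, sigma_nm: 0.618, mass_amu: 113.16, charge_e: 0.0}
  L: {lambda: 0.973, sigma_nm: 0.618, mass_amu: 113.16, charge_e: 0.0}
  K: {lambda: 0.514, sigma_nm: 0.636, mass_amu: 128.17, charge_e: 1.0}
  M: {lambda: 0.838, sigma_nm: 0.618, mass_amu: 131.19, charge_e: 0.0}
  F: {lambda: 1.000, sigma_nm: 0.636, mass_amu: 147.18, charge_e: 0.0}
  P: {lambda: 1.000, sigma_nm: 0.556, mass_amu: 97.12, charge_e: 0.0}
  S: {lambda: 0.595, sigma_nm: 0.518, mass_amu: 87.08, charge_e: 0.0}
  T: {lambda: 0.676, sigma_nm: 0.562, mass_amu: 101.10, charge_e: 0.0}
  W: {lambda: 0.946, sigma_nm: 0.678, mass_amu: 186.21, charge_e: 0.0}
  Y: {lambda: 0.865, sigma_nm: 0.646, mass_amu: 163.18, charge_e: 0.0}
  V: {lambda: 0.892, sigma_nm: 0.586, mass_amu: 99.13, charge_e: 0.0}
  pS: {lambda: 0.090, sigma_nm: 0.620, mass_amu: 167.06, charge_e: -2.0}
  pT: {lambda: 0.140, sigma_nm: 0.660, mass_amu: 181.08, charge_e: -2.0}
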