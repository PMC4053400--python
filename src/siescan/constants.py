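"""Physical constants and calibrated default parameters.

All energies are kcal/mol, distances Angstrom, charges elementary charge
units unless stated otherwise.
"""

#: Coulomb conversion constant, kcal mol^-1 A e^-2.
COULOMB_CONSTANT = 332.0637

#: Gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT = 1.9872e-3

#: Bulk water relative dielectric constant.
WATER_DIELECTRIC = 78.4

#: Default solvent probe radius for surface-area calculations, A.
PROBE_RADIUS = 1.4

# ---------------------------------------------------------------------------
# SIE calibration (Naim et al. standard parameterization, as distributed with
# the sietraj rescoring program).  dg_bind = alpha*(E_c + E_vdw + G_R +
# gamma*dMSA) + C, with atomic vdW radii linearly scaled by rho before the
# reaction-field / surface-area evaluations.
# ---------------------------------------------------------------------------
SIE_ALPHA = 0.1048
SIE_DIELECTRIC_IN = 2.25
SIE_RADIUS_SCALE = 1.1
SIE_GAMMA = 0.0129          # kcal mol^-1 A^-2
SIE_CONSTANT = -2.89        # kcal mol^-1

# ---------------------------------------------------------------------------
# Empirical hydrogen-bond energy model (12-10 form in the H...acceptor
# distance d):  E(d) = A/d^12 - B/d^10, calibrated A = 5.571, B = 668.580.
# ---------------------------------------------------------------------------
HBOND_A12 = 5.571
HBOND_B10 = 668.580

# ---------------------------------------------------------------------------
# Sigmoidal distance-dependent dielectric (Mehler-Solmajer parameterization
# as implemented in the AutoDock 3.0.5 docking program):
#   eps(r) = A + B / (1 + k * exp(-lambda * B * r)),  B = eps0 - A
# ---------------------------------------------------------------------------
MS_EPS0 = 78.4
MS_A = -8.5525
MS_LAMBDA = 0.003627
MS_K = 7.7839

#: Overall scale applied to the screened-Coulomb per-residue polar energy.
POLAR_SCALE = 1.558

#: C-H bond length used when truncating a side chain, A.
CH_BOND_LENGTH = 1.09

#: Default hydrogen-bond detection criteria.
HBOND_DONOR_ACCEPTOR_MAX = 3.5   # A, donor heavy atom ... acceptor
HBOND_ANGLE_MIN = 120.0          # degrees, donor-H...acceptor
HBOND_OCCUPANCY_MIN = 0.5        # fraction of frames

#: Hydrophobic contact cutoff between nonpolar (C/S) heavy atoms, A.
HYDROPHOBIC_CUTOFF = 3.9

#: Maximum covalent bond length used to attach hydrogens to donors, A.
COVALENT_H_MAX = 1.25
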