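# Heavy-atom nonbonded parameters for the built-in desk energy backend.
# radius: van der Waals radius (A, Bondi-like); well_depth: Lennard-Jones
# epsilon (energy units); solvation_dG: per-atom transfer free energy used by
# the Gaussian-exclusion solvation term (negative = hydrophobic, burial
# favorable); charge: default partial charge (specific backbone / side-chain
# charges are assigned by atom name in code and override this column).
atom_type	radius	well_depth	solvation_dG	charge
C	1.70	0.120	-0.35	0.0
N	1.55	0.170	0.40	0.0
O	1.52	0.210	0.45	0.0
S	1.80	0.250	-0.45	0.0
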