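# AutoDock 4 style per-atom-type Lennard-Jones parameters.
# Rii: equilibrium internuclear separation of the homo-pair, Angstrom.
# epsii: well depth of the homo-pair, kcal/mol.
# "X" is the excluded atom type: zero partial charge, vanishing well depth,
# Rii equal to the calibrated monolayer default (see forcefield.calibrate_excluded_type).
# type	Rii	epsii
C	4.00	0.150
A	4.00	0.150
N	3.50	0.160
NA	3.50	0.160
O	3.20	0.200
OA	3.20	0.200
H	2.00	0.020
HD	2.00	0.020
HS	2.00	0.020
S	4.00	0.200
SA	4.00	0.200
P	4.20	0.200
F	3.09	0.080
Cl	4.09	0.276
Br	4.33	0.389
I	4.72	0.550
X	3.60	0.0001
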