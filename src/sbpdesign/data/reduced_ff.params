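# Reduced heavy-atom force field, version 1.
# Units: sigma in Angstrom; epsilon, charges, well depths in reduced energy units.
#
# LJ <element> <sigma> <epsilon>
LJ C 3.55 0.07
LJ N 3.25 0.17
LJ O 2.96 0.21
LJ S 3.55 0.25
LJ H 2.50 0.03
LJ P 3.74 0.20

# Backbone template charges (all residues)
# CHARGE <resname|*> <atomname> <q>
CHARGE * N -0.40
CHARGE * CA 0.30
CHARGE * C 0.55
CHARGE * O -0.45
CHARGE * CB 0.00

# Hydroxyl / thiol side chains
CHARGE SER CB 0.40
CHARGE SER OG -0.40
CHARGE THR CB 0.40
CHARGE THR OG1 -0.40
CHARGE TYR CZ 0.40
CHARGE TYR OH -0.40
CHARGE CYS CB 0.20
CHARGE CYS SG -0.20
CHARGE MET CG 0.10
CHARGE MET SD -0.20
CHARGE MET CE 0.10

# Amides
CHARGE ASN CB 0.45
CHARGE ASN CG 0.55
CHARGE ASN OD1 -0.55
CHARGE ASN ND2 -0.45
CHARGE GLN CG 0.45
CHARGE GLN CD 0.55
CHARGE GLN OE1 -0.55
CHARGE GLN NE2 -0.45

# Carboxylates (net -1)
CHARGE ASP CG 0.60
CHARGE ASP OD1 -0.80
CHARGE ASP OD2 -0.80
CHARGE GLU CD 0.60
CHARGE GLU OE1 -0.80
CHARGE GLU OE2 -0.80

# Basic side chains (net +1)
CHARGE LYS CE 0.35
CHARGE LYS NZ 0.65
CHARGE ARG CZ 0.40
CHARGE ARG NE 0.00
CHARGE ARG NH1 0.30
CHARGE ARG NH2 0.30

# Neutral histidine / tryptophan
CHARGE HIS CG 0.20
CHARGE HIS ND1 -0.40
CHARGE HIS CD2 0.20
CHARGE HIS CE1 0.40
CHARGE HIS NE2 -0.40
CHARGE TRP CD1 0.15
CHARGE TRP NE1 -0.30
CHARGE TRP CE2 0.15

# Heteroatom (ligand) element fallbacks; carbon bonded to O gets HETC_POLAR
HETCHARGE O -0.40
HETCHARGE N -0.30
HETC_POLAR 0.40

# Nonbonded model
DIELECTRIC_SLOPE 4.0
COULOMB_CONSTANT 332.0637
CUTOFF 10.0
SWITCH_START 8.0
SCALE_14 0.5
HBOND_WELL_DEPTH 1.0
TORSION_BARRIER 0.10
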