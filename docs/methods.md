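# Methods

## Scope and model of the problem

The package automates a structure-based redesign: replace the natural ligand
of a solute-binding protein (the hexitol allitol) with its C3 epimer
(sorbitol) by pure geometry, then redesign the contacting residues so the new
ligand is held at least as well as the old one, and quantify the change with
a ΔΔG binding cycle. Three modelling commitments shape everything else:

* **Heavy atoms only.** Crystal structures of this class carry no hydrogens,
  so hydrogen bonds are detected and scored through heavy-atom geometric
  proxies, and the force field is a united-atom reduced model.
* **Rigid receptor during docking.** The epimer is placed solely by
  superposing its carbon backbone on the crystallographic ligand pose; no
  physics enters until scoring/design. Pose quality is therefore inherited
  from the crystal pose, which is exactly the premise of an epimer swap.
* **Reduced, self-contained energetics.** Published absolute scores for this
  system come from an unnamed external scorefunction and are not
  reproducible; they are treated as opaque inputs to the ΔΔG arithmetic. The
  package's own reduced energies (dimensionless, REU-like) are meaningful
  only as differences within one parameter set.

## Ligand model

Alditols are built in the extended all-anti conformation on an ideal
tetrahedral backbone (C–C 1.54 Å, C–O 1.43 Å, C–H 1.09 Å). Each internal
carbon's free tetrahedral slots take the hydroxyl O and the H; the builder
then perceives the CIP descriptor of every internal center from the 3-D
coordinates (rdkit, `AssignStereochemistryFrom3D` + the CIP labeller) and
swaps O↔H wherever the perceived label differs from the requested one, so the
returned molecule realises the requested configuration exactly rather than
relying on hand-derived priority rules. Descriptors are indexed along the
named backbone C1…C6; sorbitol is (2S,3R,4R,5R) and allitol (2S,3S,4R,5R) in
this convention — the C3 epimer pair. Pseudoasymmetric centers (lowercase
r/s; they arise in odd-length alditols such as pentitols, never in hexitols)
are accepted and matched case-insensitively. Bond perception uses covalent
radii + 0.45 Å; the backbone is the longest carbon path, oriented by atom
names when present, otherwise by the lower-serial end.

## Docking

Backbone superposition is the closed-form Kabsch solution (SVD with the
determinant sign fix); reflections are structurally forbidden because an
improper transform would silently invert the stereochemistry the whole
exercise is about. Both correspondence directions (C1→C1 and C1→C6) are
scored and the better kept, since chain numbering direction is a convention.
Hydroxyl refinement is cyclic coordinate descent over the backbone C–C
torsions; each one-dimensional subproblem (sum of squared distances of
rotated oxygens to fixed targets as a function of the rotation angle) is
A − B·cos θ − C·sin θ and is solved analytically by θ* = atan2(C, B). The
epimeric hydroxyl (C3 by default) is excluded from the objective — its
position *should* differ. Alignment and refinement alternate until the
backbone RMSD changes by < 1e-4 Å (these convergence tolerances are
engineering choices; the original procedure was interactive and had none).

## Polar contacts

A polar contact is a donor/acceptor heavy-atom pair (N, O; S of cysteine as
donor) separated by 2.4–3.5 Å where every covalent antecedent of both atoms
makes an angle ≥ 90° with the contact vector. Defaults live in
`ContactCriteria` (pocket cutoff 4.0 Å) and are deliberately exposed:
published per-residue bond counts from visualization tools are sensitive to
these thresholds, so reproducing a specific printed count against a real
structure is a calibration exercise, not a constant of nature. Side-chain
typing follows the standard table (ARG/LYS/TRP donors; ASP/GLU acceptors;
SER/THR/TYR/HIS both; ASN/GLN split); backbone N (donor, except proline) and
O (acceptor) are included by default and can be switched off.

## Reduced energy model

`score` = LJ + Coulomb + H-bond + torsion, over heavy atoms:

* **LJ 12-6** per element (σ, ε from the shipped parameter file;
  Lorentz–Berthelot mixing), 10 Å cutoff with a smooth 8–10 Å switch.
* **Coulomb** with template partial charges per residue (neutral residues sum
  to 0, ASP/GLU to −1, LYS/ARG to +1; ligand hydroxyls O −0.4 / C +0.4) and a
  distance-dependent dielectric ε(r) = 4r — the standard cheap surrogate for
  solvent screening in hydrogen-free models.
* **H-bond**: square well of −1.0 reduced unit per geometric polar contact,
  using the same criteria as the reporting, so the design pressure and the
  polar-bond bookkeeping cannot disagree.
* **Torsion**: 0.1·(1 + cos 3φ) over all bonded quadruples.

Topology comes from residue templates plus peptide links (het groups:
distance perception within the group only), so a planted clash between
non-bonded groups stays repulsive instead of being misread as a bond. 1-2 and
1-3 pairs are excluded, 1-4 scaled by 0.5. The neighbor-list path is verified
against an O(N²) brute-force double loop.

## Design

Fixed-backbone design: a move replaces one residue's side chain (built in
ideal internal coordinates from N/CA/C, with the CB torsion fixed to the
L-configuration) with a new identity/rotamer; backbone N-CA-C-O never move.
The rotamer library samples every rotatable χ at {−60°, 60°, 180°} (proline:
its two ring puckers), which is coarse but sufficient for the desk-scale
pockets this runs on, and swappable. The Metropolis walk accepts downhill
moves always and uphill moves with exp(−ΔE/kT); cooling is geometric from
kT 100 to 0.3 over 50 steps per designable residue by default. The
fixed-temperature preset (kT = 1, n = 20 independent sweeps, best kept) is
exposed as `repeat_optimize`. Exhaustive enumeration over the full assignment
space is available and is the oracle for small problems; ties break toward
the lexicographically smallest (identity, rotamer) pair. All walks are
bit-reproducible given the seed. Proline is allowed as a design identity
(with approximate ring geometry) since fixed-backbone packers traditionally
permit it; disulfide bookkeeping for cysteine is not modelled.

`minimize` is cyclic coordinate descent over side-chain χ torsions (coarse
grid + parabolic refinement, moves accepted only if energy drops, so energy
is monotone non-increasing). `relax` ramps the LJ repulsive term
(0.2 → 0.6 → 1.0), repacking (NATAA) and minimizing at each stage, keeping
the best full-repulsion structure — the standard trick for escaping clashed
starting points, verified on a fixture with a planted side-chain/ligand
overlap.

## Thermodynamic cycle

`ddg_bind` = G_C* − G_P* − G_C + G_P. The free-ligand energy is modelled as
*optional-with-unknown* rather than silently zero: ΔG_bind without G_L raises,
ΔΔG never needs it. The pipeline enforces the pairing contract that wild-type
energies are taken before any minimization of the wild-type structure
(minimizing the apo protein first would lower G_P and fake a favorable ΔΔG).

## Synthetic fixtures

`make_pocket` plants single-residue "shells" around a built hexitol. Contact
residues are placed by construction: the contact atom sits on a sphere of the
target radius around a chosen ligand hydroxyl, along the extended C–O
direction (so the ligand-side antecedent angle is exactly 180°), with the
residue's lone-pair direction facing the ligand (so protein-side antecedent
angles open well past 90°). Overflow sites anchor off the chain termini.
Residues are de-collided by rolling each about its planting axis — a motion
that provably leaves every planted distance and antecedent angle unchanged —
maximizing mutual clearance by coordinate ascent. Ground truth (contact
count, per-residue distances, pocket membership) is therefore analytic, and
every generated fixture is re-verified against the analysis operations before
being returned. Default fixture: five contact residues (HIS, ARG, ARG, ASP,
GLN at 2.8–3.1 Å — the chemotypes reported in real alditol pockets) plus PHE
and VAL spectators inside the 4 Å shell. The gain-of-contact fixture plants
an alanine whose backbone admits exactly one identity/rotamer that reaches a
free ligand hydroxyl, making "design adds a polar bond" true by construction.

What these fixtures do **not** emulate: a folded chain (residues are
disconnected), crystallographic disorder, waters, alternate conformers, or
realistic packing density. Green tests on them certify the algorithms'
contracts (optimality, invariances, bookkeeping), not predictive accuracy on
real proteins; the real-structure run remains an external validation
requiring a downloaded crystal structure, with the contact criteria as the
calibration knobs.

## Problem sizes and determinism

Test-suite and acceptance runs use the synthetic pockets (7–9 residues,
~80-atom models) and the built hexitols; design walks are 20–350 steps;
exhaustive oracles stay under a few hundred assignments; the Metropolis
calibration uses 1e5 trials. Every stochastic component takes an explicit
seed and is reproducible bit-for-bit; the pipeline manifest records the seed,
criteria, scores and file lineage of each run.

## Known limitations

* The reduced force field has no solvation term beyond the distance-dependent
  dielectric, no explicit hydrogens, and element-level LJ typing; its
  absolute numbers are not comparable to any published scorefunction.
* Rotamers at three χ values cannot represent strained conformers; packing
  real pockets would need a finer library (the class is constructed for
  replacement).
* Docking assumes a six-carbon backbone correspondence; ligands of different
  chain length are rejected rather than partially matched.
* Full-scale relax on a complete protein is outside the intended scale; the
  protocol is tuned for pocket-sized models.
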