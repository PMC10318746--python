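# sbpdesign

In-silico binding-pocket redesign for an alditol-binding ABC-transporter
solute-binding protein (SBP).

Bacterial SBPs clamp small solutes between two domains ("Venus flytrap"
mechanism). The *Agrobacterium vitis* SBP binds the hexitol **allitol**;
**sorbitol** (D-glucitol) is its C3 epimer — same formula C6H14O6, the same
six-carbon chain with one hydroxyl per carbon, differing only in the
configuration of the C3 hydroxyl. A protein engineered to prefer sorbitol is a
candidate "molecular sponge" for sequestering excess sorbitol in tissue.
This package implements the full computational workflow for that redesign:

1. **Prepare** — read the crystal dimer (PDB format), keep one monomer and its
   bound ligand (`structure_io`).
2. **Build the epimer** — construct ideal-geometry sorbitol from CIP stereo
   descriptors, with R/S assignment perceived from 3-D coordinates
   (`ligand_model`, rdkit-backed CIP).
3. **Dock by superposition** — least-squares (Kabsch) alignment of the
   six-carbon backbones, cyclic-coordinate-descent refinement of the hydroxyl
   torsions (excluding the epimeric C3 hydroxyl), iterated to convergence;
   then swap the ligands (`pocket_docking`).
4. **Analyse contacts** — pocket residues within 4 Å of the ligand and
   donor–acceptor polar contacts (heavy-atom distance 2.4–3.5 Å, antecedent
   angle ≥ 90°), reported per residue across pipeline states
   (`contact_analysis`).
5. **Redesign** — fixed-backbone Metropolis simulated annealing over residue
   identities and rotamers under a resfile-style NATRO/NATAA/ALLAA spec, plus
   torsion-space minimization and a ramped repack-and-minimize relax protocol
   (`pocket_design`), scored by a reduced heavy-atom force field
   (`energy_model`).
6. **Evaluate** — the binding thermodynamic cycle (`thermo_cycle`):

   ```
   ΔG_bind  = G_C  − (G_P  + G_L)
   ΔG*_bind = G_C* − (G_P* + G_L)
   ΔΔG_bind = ΔG*_bind − ΔG_bind = G_C* − G_P* − G_C + G_P
   ```

   where G_C/G_P/G_L are complex, apo-protein and free-ligand state energies
   and starred quantities refer to the designed (mutated) system. G_L cancels
   in ΔΔG; ΔΔG < 0 means the design binds more favorably. The wild-type
   energies must be taken *before* any minimization of the wild-type
   structure, or the cycle is biased.

Every stage is also exercised on analytic synthetic fixtures
(`synthetic_data`): pockets of planted residues around a built hexitol whose
contact distances, pocket membership, clashes, and designable
gain-of-contact sites are exact by construction.

## Worked example

```bash
sbpdesign ddg --gc -140.67 --gp -171.51 --gcs -224.80 --gps -228.27
```

prints

```
ddG_bind = -27.37 (favorable)
```

i.e. for the published state energies of the selectively redesigned
sorbitol-bound complex, (−224.80) − (−228.27) − (−140.67) + (−171.51) =
−27.37 < 0: the five-residue redesign binds sorbitol more favorably than the
starting protein. (Those four inputs come from an external scorefunction and
are consumed as opaque cycle inputs — this package's own reduced energies are
comparable only with each other.)

Running the whole pipeline on the built-in synthetic preset:

```bash
sbpdesign run --seed 1 --out pipeline_out
```

```
ddG = -0.620 (favorable); manifest: pipeline_out/manifest.json
```

The manifest records the full file lineage (`protein.pdb` → `proall.pdb` →
`prosor.pdb` → `finprosor.pdb` / `minprosor.pdb` / `fastprosor.pdb`), the
pocket residues, per-state polar-bond totals, all five cycle energies, and
the seed. On the synthetic preset, docking the epimer into the allitol pocket
preserves every planted polar bond except the one anchored on the epimeric C3
hydroxyl (4 of 5 survive) — the geometric premise of the redesign, visible in
`pipeline_out/contacts.tsv`.

Other subcommands: `prepare`, `build-ligand`, `dock`, `contacts`, `score`,
`design`, `minimize`, `relax`, `simulate` (fixture generator). To run the
preparation/docking/contact analysis against the real crystal structure,
download PDB entry 4WT7 and run `sbpdesign run --in 4wt7.pdb --ligand X9X`;
the published pocket (18 residues within 4 Å; 7 polar bonds over residues
61, 89, 187, 268, 290) depends on the contact criteria, which are exposed in
`ContactCriteria` for calibration.

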