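# oligoface

Quantitative structural and sequence analysis of oligomeric photosystem I
(PSI) assemblies.

Cyanobacterial PSI occurs as monomers, trimers and — in heterocyst-forming
cyanobacteria and their relatives — tetramers organized as a
dimer-of-dimers with two distinct interface classes. Characterizing such an
assembly means answering a set of linked quantitative questions: which
amino acids form each monomer–monomer interface, how the chlorophyll
network spans those interfaces (the Mg–Mg distances that gate excitation
energy transfer), how much surface each interface buries, how large the
central cavity is and how many lipids it could hold, which non-covalent
forces stabilize each interface, and which conserved regions of the PsaL
subunit track the oligomeric state across cyanobacterial lineages.
`oligoface` implements this analysis chain as a tested, reusable library
with a thin CLI, for structural biologists working with mmCIF/PDB models
of multi-monomer membrane complexes.

## What it computes

- **Interface residues** — a residue belongs to the interface of monomers
  *M₁*, *M₂* if its Cα lies within a cutoff (default 12 Å) of the partner
  monomer (`ca_to_ca` or `ca_to_any` criterion).
- **Chlorophyll networks** — all chlorophyll pairs with Mg–Mg distance
  strictly below a threshold (10/15/20 Å), classified within-monomer vs
  cross-interface, plus detection of near-parallel porphyrin planes (least
  squares through the four pyrrole nitrogens).
- **SASA / BSA** — Shrake–Rupley solvent-accessible surface area with a
  1.4 Å probe; buried surface area
  `BSA = SASA(M₁) + SASA(M₂) − SASA(M₁∪M₂)`.
- **Cavity volume and lipid capacity** — grid flood-fill: voxels within
  `r_vdW + probe` of any atom are occupied, the exterior is flood-filled
  from the box boundary, the largest enclosed free component is the
  cavity; lipids per leaflet = `⌊(V/2)/v_lipid⌋` with `v_lipid = 1250 Å³`.
- **Interface energetics** — screened Coulomb with distance-dependent
  dielectric `ε(r) = 4r` (`E = 332.0636·q₁q₂/(ε(r)·r)` kcal/mol), 12-6
  Lennard-Jones over united-atom element classes, optional atomic-solvation
  desolvation term. Protonation states of Asp/Glu/His/Lys/Arg/Tyr/Cys are
  sampled by Metropolis Monte Carlo
  (`E = Σᵢ xᵢ·2.303·RT₀·(pH − pKaᵢ) + Σᵢⱼ E_coul`), and the resulting
  Boltzmann occupancies weight the site charges in the electrostatic sum.
- **PsaL conservation** — BLAST outfmt-6 ortholog filtering (identity ≥ 40 %,
  coverage ≥ 35 %, e ≤ 1e−10), per-column information content
  `Rᵢ = log₂20 − Hᵢ − eₙ` of group alignments, and conserved-region
  segmentation (maximal runs of high-bit, low-gap columns, e.g. CR-I…CR-V).

Every stage has a synthetic-data generator (`oligoface.synthetic_data`)
that plants ground truth exactly — interface residues at known distances,
chlorophyll pairs at exact Mg–Mg separations and plane angles, hollow
shells of analytic volume, enumerable protonation systems, alignments with
planted conserved blocks — and records it in a manifest that the test
suite holds the pipeline to.

## Worked example

Generate a synthetic dimer with five residue pairs planted at 8 Å across
the A–B interface, a chlorophyll pair at 14 Å, and a hollow shell of inner
radius 20 Å, then analyze it:

```
$ oligoface simulate assembly --seed 7 --out demo
$ oligoface interfaces --structure demo/assembly.pdb --map demo/chains.tsv
{
  "A-B": {
    "n_side1": 5,
    "n_side2": 5,
    "n_total": 10
  }
}
$ oligoface cavity --structure demo/assembly.pdb --chains C
{
  "volume": 27056.0,
  "principal_extents": [38.13, 38.09, 38.08],
  "bounding_box_extents": [38.0, 38.0, 37.0],
  "lipids_per_leaflet": 10,
  ...
}
```

The interface report recovers exactly the five planted residues on each
side (`n_total = 10`). The cavity volume of 27,056 Å³ agrees with the
probe-eroded analytic interior of the shell, (4/3)·π·(20 − 1.4)³ ≈
26,954 Å³, to 0.4 %; the extents are the eroded diameter ≈ 37.2 Å along
all three principal axes, as expected for a sphere. On a real tetramer
model the same verbs (`interfaces`, `chl-network`, `bsa`, `cavity`,
`energetics`, plus `run` for the whole pipeline) take the deposited
mmCIF and a two-column chain→monomer TSV map.

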