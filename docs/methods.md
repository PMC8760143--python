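# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Structure model

Coordinate files (mmCIF or PDB) are parsed with gemmi and flattened into
plain atom/residue/chain containers keyed by **author** chain ids, so that
chain→monomer maps can be written in the naming a publication uses.
Alternate locations are resolved to the highest-occupancy conformer, ties
broken by file order — deterministic and standard. Hydrogens are kept when
present and never required (cryo-EM models typically have none). All
coordinates are ångström; nothing in the package converts units.

Monomer assignment is a user-supplied two-column TSV (`chain_id`,
`label`); entries naming absent chains warn rather than fail so one map
can serve related depositions. When no curated map exists,
`infer_monomers` clusters chain centroids with seeded k-means — monomers
of an oligomer are compact and mutually separated, so centroid clustering
recovers the grouping; interface identity (which pair is the tight dimer)
should then be established from the data, e.g. by ranking interfaces by
residue count or buried area, rather than trusted from cluster labels.

Cofactors are recognized by residue name through an editable table
(CLA → chlorophyll a, BCR → β-carotene, PQN → phylloquinone, SF4/FES →
Fe–S cluster, LHG → phosphatidylglycerol). This is configuration, not
code, because depositions differ in which cofactors they include — a model
may omit carotenoids and lipids entirely, so no fixed cofactor census is
assumed. Each chlorophyll must contain exactly one Mg atom, its anchor in
all distance analyses; chlorophylls without one are excluded with a
warning.

## Interface geometry

A residue is an interface residue of the pair (M₁, M₂) iff its Cα lies
strictly within the cutoff (default 12 Å) of the partner monomer. The
partner target is either the partner's Cα set (`ca_to_ca`, default) or
all partner polymer atoms (`ca_to_any`); both are exposed because "within
12 Å of the amino acids" is ambiguous between the two readings, and the
reported totals count both sides. Cofactor residues never count as
interface residues. All distance comparisons in the package are strict
(`<`): a pair exactly at a threshold is excluded, so thresholds compose
cleanly (the <10 Å set is a subset of the <15 Å set).

Chlorophyll pairs are all unordered Mg–Mg pairs below the threshold,
classified within-monomer vs cross-interface by the partition label of
their chains. Porphyrin planes are least-squares planes (SVD) through the
four pyrrole nitrogens NA/NB/NC/ND; the pair angle is the acute angle
between plane normals, so it lies in [0°, 90°] by construction.

Neighbour queries use a k-d tree (scipy `cKDTree`). Correctness is
guaranteed by tests against an exhaustive O(n²) reference implementation
that ships in the package, not by the index itself.

## Surfaces and cavity

SASA is Shrake–Rupley with a quasi-uniform Fibonacci (golden-spiral)
point lattice, default 960 points per atom and a 1.4 Å water probe.
Default van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80, Mg 1.73,
P 1.80, H 1.20, Fe 1.40, fallback 1.70 Å (editable TSV). At 960 points
the total changes by < 1 % under point doubling and agrees with a
10⁵-sample Monte Carlo surface oracle to well under 2 % on random
clusters; the single-atom value is exact.

The cavity estimator is a grid flood fill, not an alpha-shape pocket
decomposition: atoms are stamped onto a cubic grid (default 1.0 Å
spacing, valid range 0.25–2.0 Å) as spheres of radius `r_vdW + probe`, so
the free region is the space accessible to **probe centres**; free voxels
are labelled by 6-connectivity, components touching the padded box
boundary are exterior solvent, and the largest enclosed component is the
cavity. The probe-erosion convention matters for analytic comparisons: a
shell with van der Waals interior radius R yields a measured volume of
(4/3)·π·(R − probe)³. Extents are reported both along the cavity's
principal axes (PCA of voxel centres) and as the axis-aligned bounding
box, since published "width × depth" figures rarely state which
convention they use. A structure whose interior communicates with the
exterior yields an empty report with a diagnostic instead of a number.

Lipid capacity divides half the cavity volume (one leaflet) by a
per-lipid volume of 1250 Å³ — a typical thylakoid galactolipid volume,
exposed as a flag. A membrane composition of 47/23/21/9
MGDG/DGDG/SQDG/PG is recorded as metadata only; no bilayer is built.

## Energetics

The paper-scale continuum treatment (Poisson–Boltzmann) is deliberately
replaced by a screened Coulomb potential with distance-dependent
dielectric ε(r) = k·r, k = 4 by default. Consequently interface energy
components are meaningful in **sign and relative magnitude** — whether
dispersion or electrostatics dominates — not as absolute free energies;
no parameter table should be tuned to reproduce solver-specific numbers.

Titratable sites (Asp 3.65, Glu 4.25, His 6.5, Lys 10.53, Arg 12.5,
Tyr 10.07, Cys 8.3) are two-state; the charged state distributes the
formal charge over the ionizable-group atoms (e.g. −0.5 on each
carboxylate oxygen), the neutral state carries zero there, and the charge
is renormalized to the formal value when group atoms are missing from the
model. The microstate energy is

    E(x) = Σᵢ xᵢ · 2.303·R·T₀·(pH − pKaᵢ)  +  Σᵢ<ⱼ cᵢcⱼ·Jᵢⱼ,

with xᵢ the protonation indicator, cᵢ the charged-state indicator and
Jᵢⱼ the screened Coulomb coupling between charged sites. The pH term uses
the **reference** temperature T₀ = 298.15 K: it is a standard-condition
free energy in kcal/mol, while the sampling temperature enters only the
Metropolis acceptance. This keeps the two knobs orthogonal — at pH = pKa
an isolated site titrates to 0.5 at any temperature, and raising the
sampling temperature flattens coupled distributions as it should.

Sampling is single-site-flip Metropolis (default 10⁵ steps, 10⁴ burn-in,
numpy `default_rng(seed)`, fully deterministic per seed). For ≤ 20 sites
an exact enumerator over all 2^k microstates is available and is the test
oracle; sampled occupancies agree with it to < 0.01 at the default chain
length.

Interface energies sum over cross-interface atom pairs within the 12 Å
cutoff (matching the interface-extraction radius; no long-range
correction): the electrostatic term uses occupancy-weighted charges on
titratable groups and a small dipolar fixed-charge table on backbone
atoms (net-neutral per residue, hydrogens absent), and the van der Waals
term is 12-6 Lennard-Jones over coarse united-atom element classes with
Lorentz–Berthelot combining (editable TSVs; the force-field provenance of
published analyses is named but not parameterized, so these are the
package's own coarse values). A pair distance below 0.5 Å is treated as
degenerate geometry and rejected. The optional desolvation term is
Σ σ(element)·ΔASAᵢ with atomic solvation parameters (hydrophobic burial
favourable, polar burial unfavourable).

Side-chain rotamer sampling is out of scope; only protonation is sampled.

## Conservation analysis

Ortholog candidates come from BLAST outfmt-6 tables (12 standard columns,
or 14 with qlen/slen for coverage); the filter keeps hits with identity
≥ 40 %, query coverage ≥ 35 % and e-value ≤ 1e−10, boundaries inclusive
exactly as written. A separate length filter drops sequences shorter than
180 residues (ungapped) unless their id is an exempt anchor — the
published description of this step is self-contradictory (it reads as
"shorter sequences were included"), so the package implements the only
reading consistent with the filtering intent, exclusion-below-threshold
with anchor exemption, and makes both the threshold and the exemption
list explicit inputs. Corpus-level ortholog counts from any particular
database snapshot are therefore not reproduced and not claimed.

Per-column information content follows sequence-logo convention:
probabilities renormalized over the 20 amino acids, gaps ('-', '.') and X
counted into a separately-reported gap fraction, Rᵢ = log₂20 − Hᵢ − eₙ
with the small-sample correction eₙ = 19/(2·ln2·n) on by default (n =
residues observed in the column), clamped at zero; letter heights are
pₐ·Rᵢ. All-gap columns get Rᵢ = 0 and a flag. Conserved regions are
maximal runs of ≥ 3 consecutive columns with Rᵢ ≥ 2.0 bits and gap
fraction ≤ 0.5. Region names (CR-I…CR-V) are a labelling convention
assigned positionally from a user-supplied list, because exact region
boundaries are published only graphically; cross-group comparison then
reduces to a presence/absence matrix with per-region mean bits.

## Synthetic fixtures

The generators plant ground truth by **exact placement**, never sampling:
planted interface pairs sit at their stated Cα–Cα distance to machine
precision, planted chlorophylls at their stated Mg–Mg distance and plane
angle, and decoy geometry (bulk helices, other plants) is kept beyond
thresholds by ≥ 2 Å margins, so expected counts are exact integers.
Monomers are rigid ideal α-helix Cα traces placed on a line (≤ 2
monomers) or regular polygon, 100 Å apart by default. Hollow shells place
one dummy atom per Å² of shell surface so a 1.4 Å probe cannot leak.
Alignments draw background columns i.i.d. from stated frequencies and
repeat a consensus letter in block columns, with optional mutation and
gap rates. BLAST tables contain exactly the requested number of passing
rows, with boundary rows on both sides of each threshold. Fixtures are
written in the real external formats (PDB, aligned FASTA, outfmt-6 TSV)
so tests exercise the true I/O paths.

What the fixtures do **not** emulate: real protein folds and packing
density, heterogeneous B-factors/occupancies, correlated substitution
patterns or phylogenetic structure in alignments, and the spatial
complexity of a real 44-chain assembly. Passing the synthetic suite
therefore demonstrates algorithmic correctness against exact ground
truth, not biological fidelity; the deposited-model checks in
`tests/test_acceptance.py` cover the latter when the model file is
available locally or downloadable.

## Problem sizes

Default test and acceptance runs use: assemblies of 2–4 monomers with
20–30 bulk residues each (≤ 5,000 atoms, within the exhaustive-oracle
regime), shells of ~5,800 atoms on a 1 Å grid, 8–10 coupled titratable
sites (2^k enumerable), 2×10⁵ Monte Carlo steps, alignments of 24
sequences × 120 columns, and 10-row BLAST tables. These sizes were chosen
so every oracle (O(n²) geometry, 10⁵-sample Monte Carlo surface
integration, exhaustive microstate enumeration) is itself cheap and
trustworthy.

## Known limitations

- The cavity estimator reports probe-centre-accessible volume; tools
  using alpha-shape or surface-based definitions will differ by a
  probe-layer's worth of volume, so cross-tool comparisons are tolerance
  bands, not equalities.
- The screened-Coulomb dielectric is a first-order stand-in for continuum
  electrostatics; absolute interface energies are not comparable across
  methods.
- BSA from point-sampled SASA carries ~1 % sampling noise; symmetric by
  construction, clamped at zero.
- `infer_monomers` assumes spatially compact, well-separated monomers; it
  is a fallback, not a substitute for a curated chain map.
- Conservation profiles treat alignment columns independently; no
  phylogenetic weighting of sequences is applied.
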