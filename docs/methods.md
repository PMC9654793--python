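# Methods

`hingedock` is a desk-scale structure-based virtual-screening toolkit
built around an empirical protein–ligand binding free energy function
whose distinguishing feature is a solvent-contact dehydration term.
This note records the model, its assumptions, the tunable constants,
what the synthetic test systems do and do not demonstrate, and the
design choices made where the design was genuinely open.

## The binding free energy function

The score of a ligand pose against a rigid receptor is

```
ΔG = W_vdw  Σ_ij (A_ij/r_ij^12 − B_ij/r_ij^6)
   + W_hb   Σ_ij E(t) (C_ij/r_ij^12 − D_ij/r_ij^10)
   + W_elec Σ_ij q_i q_j / (ε(r_ij) r_ij)
   + W_tor  N_tor
   + W_sol  Σ_i S_i (Occ_i^max − Σ_{j≠i} V_j e^{−r_ij²/2σ²})
```

* **van der Waals** — a 12-6 potential per receptor–ligand atom pair.
  Pair constants come from an AMBER-derived per-type table (`Rii`,
  `eps` in `data/atom_types.txt`) under Lorentz–Berthelot combination.
* **Hydrogen bond** — a deeper, shorter-ranged 12-10 well between a
  donor heavy atom and an acceptor (default equilibrium 2.9 Å, depth
  5 kcal/mol).  A pair eligible for this term is excluded from the
  van der Waals sum so nothing is double-counted.  The directionality
  weight `E(t) = max(0, cos(t − 180°))²` uses the donor–H⋯acceptor
  angle of the donor's best-aligned explicit polar hydrogen and falls
  back to `E = 1` when the donor carries no explicit hydrogen (both
  the ideal angle and the exponent are configurable).
* **Electrostatics** — screened Coulomb with the sigmoidal
  distance-dependent dielectric
  `ε(r) = a + (ε_bulk − a)/(1 + k e^{−λ(ε_bulk − a) r})`
  (defaults ε_bulk = 78.4, λ = 0.003627, k = 7.7839, a = −8.5525) and
  the conversion constant 332.06 kcal·Å/(mol·e²).
* **Torsional entropy** — `W_tor · N_tor`, pose-independent.  `N_tor`
  counts acyclic single bonds between heavy atoms that each carry a
  further heavy neighbor (terminal methyls do not rotate, amides are
  excluded); terminal hydroxyl/amine rotors are counted by default and
  can be excluded (`include_polar_h=False`).
* **Dehydration** — for every ligand atom *i*, the Gaussian-weighted
  volume of its solute neighbors (receptor atoms plus the ligand's
  other atoms) is subtracted from the atom's maximum occupancy
  `Occ_i^max`; the deficit is clamped at zero so full burial cannot
  flip the term's sign, and scaled by the atomic solvation parameter
  `S_i`.  σ defaults to 3.5 Å.

Every pair sum applies a 12 Å nonbonded cutoff.  Intra-ligand van der
Waals and electrostatics are evaluated for atom pairs at least four
bonds apart whose path crosses a rotatable bond; pairs inside one
rigid fragment contribute a pose-independent constant and are skipped.
Receptor–ligand contacts below 1.6 Å set a clash flag on the returned
energy decomposition; the energy is still reported.

### Parameter provenance — what is, and is not, reproducible

The published application of this functional form used term weights
and solvation parameters (`S_i`, `V_i`, `Occ_i^max`) fitted elsewhere
and never printed, together with a homology-built receptor model and
wet-lab assays.  Per-complex binding energies of that study (values
near −26 kcal/mol) and any IC50 are therefore **not reproducible** from
this package and are not targets of its tests.  What the package
guarantees instead is the exact functional form (checked against an
independently written brute-force oracle to 1e-9 kcal/mol) and the
documented qualitative behavior of each term.

The shipped constants are honest surrogates, declared as such in
`ParameterSet.provenance`:

* weights `(0.1485, 0.0656, 0.1146, 0.3113, 0.1711)` — the classic
  free-energy-calibrated docking coefficients;
* the solvation block is a placeholder table.  `S` acts as a
  dehydration-penalty density, largest for charged/polar nitrogen and
  oxygen (+0.004 … +0.009 kcal/(mol·Å³)) and small for carbon
  (+0.0008), so that a polar moiety buried in a pocket worsens the
  score relative to an equally sized nonpolar one — the stated purpose
  of replacing a cruder hydration term.  `Occ^max ≈ 350 Å³`
  approximates the Gaussian-weighted neighbor volume of a fully buried
  heavy atom at σ = 3.5 Å (~0.044 atoms/Å³ × ~13 Å³ × (2πσ²)^{3/2}).
  Swapping in a calibrated table is a data change, not a code change.

## Receptor preparation

PDB models are read with Biopython (one model; highest-occupancy
altloc; waters/hetero dropped unless kept).  Protonation of titratable
residues is rule-based and geometric, using a heavy-atom distance
limit of 3.5 Å ("pointing toward" is operationalized as pure distance;
an angle gate can be enabled):

* Asp/Glu are neutral iff a carboxylate O lies within the limit of a
  hydrogen-bond acceptor atom (it must then be donating);
* Lys is +1 unless its amine nitrogen lies near a donor atom (which
  would force the amine into the acceptor role);
* His follows the same neighborhood logic: a donor near exactly one
  imidazole nitrogen puts the hydrogen on the other; acceptors near
  both nitrogens mark the ring protonated; the ambiguous default is
  the neutral Nε–H tautomer.  Arg is always charged.

Decisions are logged per residue and written as `REMARK` records by
the PDB writer, and the assignment is a pure function of heavy-atom
geometry (hence idempotent and rigid-motion invariant).  Hydrogens are
placed at ideal internal coordinates from per-residue templates
adjusted by the assigned state; there is no minimization, because the
model feeds a scoring function, not a refinement engine.  Chain
termini are treated as ordinary residues (no OXT protonation logic).

## Grids and pose search

Affinity maps are precomputed on a rectilinear box: one map per
(ligand atom type, effective donor/acceptor role) probe storing the
summed 12-6/12-10 receptor interaction, an electrostatic potential map
per unit charge, and a receptor-occupancy map for the dehydration
term.  Poses are scored by trilinear interpolation plus exact torsion
and intra-ligand terms.  Grid hydrogen bonding is isotropic (`E = 1`);
the direct scorer applies the angular weight, so rescoring final poses
directly is the accurate route when explicit polar hydrogens are
present.  Interpolation error falls roughly quadratically with
spacing; at 0.25 Å it is below 0.1 kcal/mol on the bundled test
complexes, except on hard-clash geometries where the r⁻¹² wall makes
interpolation meaningless.

The search is a genetic algorithm over translation, orientation
(quaternion) and torsion offsets: tournament selection, uniform
crossover, Gaussian mutations with occasional heavy-tailed resets of
the orientation or a torsion (narrow orientational funnels are
otherwise reachable only by luck), elitism, and Nelder–Mead refinement
of basin-diverse finalists of each run (candidates must differ by at
least 1.5 Å in translation, so the local optimizer visits distinct
basins).  Half of each initial population is seeded near the box
center — boxes are centered on the site of interest, and uniform
sampling of a 12 Å box rarely lands inside a small pocket
(``SearchConfig.center_bias``).  Runs are independent and
deterministic: run *k* of seed *s* draws from `default_rng([s, k])`,
so results are identical regardless of execution order, and a docking
with more runs can only improve the best pose.  Defaults: population
50, 100 generations, 2 elite, refinement of the top 4.  Box spacing
defaults to the conventional 0.375 Å; a `whole_domain` constructor
reproduces blind whole-receptor searches.

## Screening and de novo growth

The screening pipeline is a monotone three-stage filtration: (1)
Rule-of-Five (pass = at most one violation of MW ≤ 500, O–H/N–H
donors ≤ 5, N+O acceptors ≤ 10, logP ≤ 5; logP is Wildman–Crippen, as
recorded in `RULE_OF_FIVE_CONFIG`); (2) dock every survivor and keep
the top-N slice by best total energy (an absolute-threshold mode
exists; ties break by (energy, id) so library order never matters);
(3) keep molecules whose best pose forms at least one hydrogen bond
with the designated hinge residue's backbone amide — a ligand acceptor
within 3.5 Å of the backbone N, or a ligand donor heavy atom within
3.5 Å of the backbone O.  Every molecule is reported with stage flags;
summary counts are tallies of those flags.

De novo growth keeps a docked core frozen — literally: core heavy-atom
coordinates are copied, never re-optimized, so their RMSD to the input
pose is exactly 0 — and substitutes fragments at marked hydrogen
positions.  Substituents are placed at ideal bond length along the
replaced C–H vector, rigidly oriented, then rotated about the new bond
on a 15° grid (30° at large enumeration scale) to the lowest-energy
rotamer; fragment-internal geometry comes from an embedded conformer.
Enumeration is the full Cartesian product over sites, deduplicated by
canonical SMILES, with valence failures logged and dropped; the null
(all-H) substitution is always present and scores identically to the
core.  Candidate selection applies the Rule-of-Five filter and then
truncates to K.  Exhaustive enumeration is used up to ~10⁵ candidates,
the scale of interest here; a stochastic generator would be the next
step beyond that.

## Synthetic test systems

The `fixtures` module generates every input the tests need, with all
generators pure functions of their seed:

* **Toy pockets/complexes** — abstract atom arrangements, not
  proteins: a backbone-amide motif (registered as residue HNG A:1 so
  hinge logic runs unchanged) plus a carbon shell *molded* around a
  planted bidentate ligand at the C–C van der Waals equilibrium
  (+0.2 Å clearance).  The mold makes the planted pose the deepest
  basin by shape complementarity, which is what the redocking
  experiment requires.  Binder ligands anchor an acceptor to the
  backbone N and a donor to the backbone O (the classic kinase hinge
  chemotype); nonbinders are hydrocarbons; clash complexes plant an
  overlap at 1.3 Å.  Toy atoms carry no explicit hydrogens, so `E(t)`
  is exercised in unit tests with real molecules rather than in the
  toys.
* **Screening libraries** — small rigid scaffolds from SMILES
  (ketones/ethers/azines as binders, hydrocarbons as nonbinders, plus
  deliberate two-violation druggability failures), embedded in 3D,
  typed and Gasteiger-charged.
* **The oracle** — `brute_force_energy` re-derives the score as plain
  nested scalar loops, sharing only the parameter tables and the
  documented pair conventions with the production scorer.

What passing these tests shows: the scoring function computes its
stated form exactly; the search recovers a constructed optimum; the
filtration logic is watertight on ground-truth labels.  What it does
not show: performance on real kinase structures and real chemistry —
toy pockets have no flexibility, no waters, schematic charges, and
geometries chosen to be solvable at desk scale.

## Numerical choices and edge cases

* Charges: RDKit PEOE (Gasteiger–Marsilli), 8 iterations with the
  canonical halved damping; charge conservation is asserted to 1e-6.
* A ligand translated beyond the cutoff retains its torsion penalty
  and its ligand-only dehydration self-term (the formula's `j ≠ i`
  sum includes the ligand's own atoms); all receptor-pair terms are
  exactly zero there.
* Pose RMSD is heavy-atom and symmetry-aware (graph automorphisms via
  VF2 with element labels, capped at 2000 mappings).
* Cluster analysis is greedy in energy order with a 2.0 Å cutoff.
* Out-of-box ligand atoms reject a pose (+∞) rather than extrapolate.
* Problem sizes used by the bundled experiments: ~30-atom pockets,
  5-atom toy ligands, 100 oracle complexes, 10 × 20 docking runs, a
  200-molecule screening library, and a 625-candidate (4-site ×
  5-fragment) growth enumeration.

## Known limitations

Rigid receptor throughout; no tautomer/stereoisomer enumeration; no
pKa-based ligand protonation; His/termini chemistry is template-level;
the GA is single-threaded by design (runs are embarrassingly parallel
if a caller wants to distribute them); and all energy parameters are
surrogates pending a calibrated refit, as discussed above.
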