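# Methods

This note records the models, defaults and numerical choices behind
`mosads`, and what the synthetic-data tests do and do not demonstrate.

## Sheet model

A 2H-MoS₂ monolayer is generated in an orthorhombic supercell with in-plane
vectors `(a, 0)` and `(0, a√3)` containing 2 Mo and 4 S; x is the zigzag
direction. The Mo plane sits at z = 0 with sulfur planes at ±dz, giving each
Mo six sulfur neighbors (three up, three down) at the trigonal-prismatic
bond length `√(a²/3 + dz²)`. Rectangular cells were chosen because the
patches and simulation boxes used in adsorption studies are rectangular.

Defaults `a = 0.316 nm`, `dz = 0.1564 nm` are standard 2H-MoS₂
crystallographic values (bond length 0.2403 nm); both are configurable.
Requested target extents are met by the integer repeats minimizing
`|extent − target|` per axis — e.g. a 6.735 × 6.600 nm request yields a
21 × 12 patch of 6.636 × 6.568 nm, within one lattice spacing per axis.
Nonbonded parameters (per-species LJ σ, ε and partial charge) are pure
configuration: the shipped `data/mos2_params.yml` holds provisional
literature-style values for a neutral sheet (q_Mo = +0.6e, q_S = −0.3e,
net zero per cell) and is meant to be replaced by the force field actually
used. The `frozen` flag is metadata only (emitted as an index group for the
MD engine); no dynamics happen here.

## System setup

Placement translates the protein rigidly: xy-centroid to the sheet's xy
center, then along +z until the minimum distance from any protein heavy
atom to any sheet atom (S or Mo) equals the requested gap, solved by
bisection to 10⁻⁴ nm. The gap definition (heavy atom ↔ any sheet atom) is
logged, since "distance to the surface" is otherwise ambiguous. Formal
charge assumes standard protonation at pH 7 (Asp/Glu −1, Lys/Arg +1, His
neutral, zwitterionic termini net 0); for the HP35 sequence this gives +2e
and hence two chloride counterions. Water insertion and engine topologies
are deliberately out of scope — solvent counts depend on the solvation tool
and are not reproducible quantities.

## Observables

* **Contacts.** An atom of set A is in contact when any atom of set B lies
  within r_c (default 0.6 nm, minimum image when a box is present). The
  reported "contact number" counts contacting protein sidechain heavy
  atoms; a `pairs` flag switches to atom-pair counting, and outputs label
  the convention.
* **Native contacts / Q(t).** Residue pairs at sequence separation ≥ 3
  whose heavy-atom minimum distance is ≤ r_c in the reference structure;
  Q(t) is the fraction of those pairs still satisfying the criterion. All
  heavy atoms (backbone + sidechain) define the pair criterion by default;
  a `part="sidechain"` knob restricts it.
* **Helix ratio.** A residue is helical when (φ, ψ) fall within ±30° of
  (−57°, −47°) and belong to a run of ≥ 4 consecutive such residues; the
  ratio is over residues with both dihedrals defined (termini excluded).
  This dihedral-window assignment was chosen over a full secondary-structure
  algorithm: it is exactly invertible on the synthetic scaffold, and the
  window/run length are configurable. Note that runs are chain-wide: when
  two annotated helices are sequence-adjacent (the second ends at residue
  61, the third starts at 62), an intact boundary region counts as one
  helical stretch.
* **Hydrogen bonds.** Donor/acceptor = N and O heavy atoms in different
  residues; distance ≤ 0.35 nm, and X–H···Y angle ≥ 150° whenever covalent
  hydrogens (within 0.12 nm of a candidate) exist in the topology. Without
  hydrogens the distance-only criterion is used and logged. These are the
  common geometric thresholds; nothing downstream is sensitive to them.
* **Salt bridge / cation-π.** Minimum sidechain-N to carboxylate-O distance
  ≤ 0.4 nm; cation center (Arg CZ / Lys NZ) to aromatic ring centroid
  ≤ 0.5 nm.
* **Energetics.** 12-6 LJ plus *truncated* Coulomb at the same 1.0 nm
  cutoff, Lorentz–Berthelot by default. A lattice-sum treatment is
  deliberately not used: the package evaluates interaction energies on
  stored frames, not forces for dynamics, and the protein–sheet
  electrostatic term is small next to dispersion; an optional reaction-field
  correction (`reaction_field=True`, ε_rf = 78.5) is available where
  truncation bias matters. Energies are kcal/mol externally (kJ internally,
  conversion exactly 4.184); negative = attractive, with `abs_*` columns
  for magnitude readers. Per-residue maps assign each pair term to the
  protein atom's residue and therefore partition the totals exactly. Tail
  statistics are the mean over the trailing window (default 100 ns, clipped
  to the trajectory span) with a 5-block standard error; the estimator tag
  is recorded because "±" conventions vary.
* **Hydration / kinetics.** FSS = water oxygens within 0.45 nm of the
  residue's (sidechain by default) heavy atoms. The cutoff is a package
  default — absolute shell counts depend on it, so published shell sizes
  are treated as semantic anchors, not test targets. The dewetting count
  uses an axis-aligned bounding-box prism (residue xy box padded 0.3 nm,
  between the top sulfur plane and the residue's lowest heavy atom) rather
  than a convex hull, for determinism. Contact onsets require a positive
  count for ≥ k consecutive frames (default k = 5) so single-frame grazing
  contacts do not define anchoring; onset time is monotone non-decreasing
  in k. Helix anchoring order sorts helices by earliest member onset, ties
  broken by helix index, non-contacting helices last.

## Synthetic trajectories

The generator emulates the phenomenology of adsorption — rigid approach
along z following a gap(t) table, stepwise per-residue anchoring,
progressive helix melting, and fixed hydration shells — with exact
bookkeeping:

* The scaffold is built by internal-coordinate (NeRF) chain extension with
  ideal backbone geometry; (φ, ψ) = (−57°, −47°) inside the annotated
  helices and (−120°, +120°) in loops, so recomputed dihedrals match to
  machine precision. Sidechains are a Cβ plus a pseudo-atom cluster sized
  to the residue's true heavy-atom count — sufficient for contact, energy
  and hydration metrics, which only see heavy-atom positions and counts.
* Melting a residue rotates all downstream atoms about the N–Cα and Cα–C
  axes, changing only that residue's (φ, ψ); every other residue's internal
  geometry is untouched (verified to 10⁻⁹ nm).
* At its onset time a residue's sidechain is displaced to 0.45 nm above the
  nearest top-sulfur site, guaranteeing a contact under r_c = 0.6 while the
  gap schedule (validated to stay above r_c + 0.05 nm) guarantees no other
  residue touches the sheet. Onsets are therefore recovered exactly at
  persistence k = 1, with the caveat that programmed times are quantized to
  the frame grid.
* Shell waters are single-site oxygens rejection-sampled in a 0.28–0.43 nm
  shell around the target sidechain, excluded from a 0.25 nm core around
  every atom and from the FSS (plus 0.005 nm margin) of every *other
  hydrated* residue, so per-residue counts are unambiguous. Hydrated
  residues must be ≥ ~6 apart in sequence for the sampler to find room; the
  randomized-scenario helper enforces this. Placement is re-seeded per
  frame from a stable hash of (seed, frame index), so frame access order
  cannot change results, and identical seeds give byte-identical output.
* Ground-truth Q(t) is computed at generation time by an exhaustive
  residue-pair recount, independent of the metrics implementation.

What passing these tests shows: the analysis code measures exactly what it
claims on geometrically unambiguous inputs. What it does not show: anything
about force-field accuracy, real unfolding pathways, water dynamics, or the
magnitudes of production-scale interaction energies — the toy scaffold is
elongated rather than packed, its waters have no hydrogens, and its
dynamics are scripted, not integrated.

## Numerical choices

* Coordinates are nm internally (Å converted at PDB boundaries); frame
  times are ps in files, ns in analysis tables.
* Pairwise distances use vectorized NumPy with per-axis minimum image for
  orthorhombic boxes. At the system sizes this package targets (≤ ~10⁴
  atoms per frame) this is faster in practice than a cell list in Python;
  correctness is defined by exhaustive O(N²) recomputation, against which
  all pair metrics are tested (100 random systems per metric).
* Dihedral-setting rotations probe the rotation sense numerically instead
  of assuming a sign convention, and verify the target to 10⁻⁶ degrees.
* Problem sizes in tests and in the acceptance script (patches up to
  21 × 12 cells, trajectories of 30–120 frames, 10–20 random scenarios)
  were chosen as the smallest sizes at which every code path — periodic
  images, pinning near sheet edges, multi-residue shells — is exercised.

## Known limitations

* Single monolayer only: no multilayers, edges, vacancies, 1T polytype, or
  bonded sheet force-field terms.
* Truncated Coulomb differs from lattice-sum electrostatics; the optional
  reaction field narrows but does not close that gap.
* The helix assignment is a dihedral window, not DSSP; β/turn classes are
  not assigned.
* The default MoS₂ nonbonded parameters are provisional placeholders, and
  the generic per-element protein LJ set is for demonstrations on synthetic
  systems — production analyses should supply the force field's own values.
* The intrinsic hydrophobic proportion of the second helix depends on the
  span and classification convention; with the default table the span
  54–61 gives 50%, and no attempt is made to tune the table toward any
  particular published figure.
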