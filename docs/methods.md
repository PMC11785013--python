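# Methods

This note documents the model, the numerical choices, and what the synthetic
test systems do and do not establish.

## The structure-based potential

The force field is a single-basin all-atom structure-based ("Gō-like") model:
a chosen reference structure is, by construction, the global minimum of the
potential energy. Such models probe the low-energy fluctuations accessible
around an experimental conformation; they contain no electrostatics, no
solvent, and no hydrogens, and they cannot describe unfolding into states not
encoded in the reference.

Terms and parameters (internal units: length Å, energy ε, mass 1 per atom,
time √(m·Å²/ε), temperature in ε/k_B):

| term | form | weight | equilibrium |
|---|---|---|---|
| bond | ε_r/2 (r−r₀)² | ε_r = 100 ε/Å² | reference table, else measured |
| angle | ε_θ/2 (θ−θ₀)² | ε_θ = 80 ε/rad² | reference table, else measured |
| improper | ε_imp/2 (χ−χ₀)² | ε_imp = 10 ε/rad² | measured from input |
| planar | ε_planar [1−cos 2χ] | ε_planar = 40 ε | minima at 0°/180° |
| proper dihedral | ε_bb/ε_sc · F(φ−φ₀) | normalized (below) | measured from input |
| contact | ε_c [(σ/r)¹²−2(σ/r)⁶] | normalized (below) | σ = 0.96 × native distance |
| non-contact | ε_nc (σ_nc/r)¹² | ε_nc = 0.1 ε | σ_nc = 2.5 Å |
| restraint | k/2 (r−r_min)² | config (150 ε/nm² = 1.5 ε/Å²) | config (5 Å) |

with F(x) = [1−cos x] + ½[1−cos 3x]. The planar weight is quoted with rad²
units in some sources although the cosine term is dimensionless; it is
implemented as a pure energy weight of 40 ε.

**Normalization.** Dihedral and contact weights are set by three constraints,
applied exactly: total stabilizing energy Σε_c + Σε_dih = n_atoms·ε; the
contact:dihedral split is 2:1; within dihedrals the backbone:sidechain
per-term weight ratio is 2:1 with uniform weights inside each class. A
dihedral is "backbone" iff all four atoms carry backbone atom names
(protein N/CA/C/O; nucleic P/O5'/C5'/C4'/C3'/O3' and the phosphate oxygens).

**Shadow Contact Map.** A pair (i, j) is a native contact iff its reference
distance is ≤ 6 Å, the atoms belong to different residues and are not in a
1-2/1-3/1-4 bonded relationship, and no third atom of radius 1 Å occludes the
line of sight. The occlusion predicate is isolated in one function: atom k
shadows (i, j) if it projects onto the open segment i→j within 1 Å of the
line and lies within the cutoff sphere of i or j (the symmetric form). The
production implementation (KD-tree candidate pruning) is tested for exact
agreement against an independent O(N³) triple-loop oracle.

**Not an exact stationary point.** Because contact minima sit at 0.96 of the
native distance ("to avoid artificial expansion"), each contact pulls gently
inward at the reference coordinates; the true minimum of the full potential
is very slightly compressed. The exact, tested statement is the closed form
U(native) = Σε_c (0.96¹² − 2·0.96⁶) ≈ −0.9528 Σε_c, which holds whenever all
bonded terms are at their native values, planar groups are exactly planar,
and no non-contact pair is inside the repulsion cutoff — the synthetic
systems guarantee all three.

**Disorder.** Disordered regions (in the original system, two rRNA segments
near the binding site) keep their bonds, angles, impropers and planar terms —
chain connectivity and local stereochemistry survive — but lose their
stabilizing contacts and proper dihedrals. Removed contacts regain the
generic non-contact repulsion.

**Heteroatoms.** Single-atom ligand/target pseudo-residues are supported
through templates with no bonded terms; they are held by their contacts.
Unparameterized residues are a hard error naming the residue.

## Simulation

Langevin dynamics with the BAOAB splitting; friction γ = 1/τ (default 1.0),
timestep 0.002 reduced (conventional stable values for this potential class —
the bond frequency ω = √(2·100) ≈ 14 gives ωh ≈ 0.03). With γ = 0 the
integrator reduces exactly to velocity Verlet, which is how energy
conservation is verified. Initial velocities are Maxwell–Boltzmann at the run
temperature using the run seed; trajectories are bit-reproducible given
(seed, config, force field). All masses are 1.

The non-contact repulsion is truncated (not shifted) at 4.0 Å, where the
discarded tail is (2.5/4)¹²·0.1 ≈ 3.6×10⁻⁵ ε per pair; an unshifted cutoff
keeps the printed value ε_nc exact at r = σ_nc, and the tiny step
discontinuity is far below the 10⁻³ ε energy-conservation tolerance. Pairs
are enumerated with a Verlet list (0.5 Å skin, rebuilt when any atom moves
more than skin/2). Simulation lengths and replica counts are configuration
values; none are published quantities.

The run temperature is the reduced T = 0.5 used for all production arms.
Temperatures in the logs are instantaneous 2·KE/(3N) estimates.

## Rotation/tilt analysis

1. **Superposition** is the SVD (Kabsch) solution of the orthogonal
   Procrustes problem with the determinant correction; collinear selections
   are rejected.
2. **E-R axis.** The pre- and post-catalytic end states are aligned on the
   body (everything except the analyzed domain and its ligand); the relative
   rotation of the domain is expressed as an Euler–Rodrigues axis/angle with
   angle in [0°, 180°]. A relative rotation near 0° leaves the axis
   undefined and is flagged (axis = None).
3. **Per-frame decomposition.** Each frame is aligned to the reference on
   the body selection; the reference domain is fitted onto the frame's
   domain; the resulting rotation is decomposed in active Z-Y-Z Euler angles
   in the frame whose Z axis is the E-R axis. γ = φ + ψ (wrapped to
   (−180°, 180°]) measures rotation about the E-R axis; the polar angle
   θ ∈ [0°, 180°] is the orthogonal tilt. Both are invariant to the
   arbitrary choice of X/Y in the E-R frame and to global rigid motion
   applied to frame and references together.
   Numerically, sin θ is taken from the off-diagonal matrix entries rather
   than from arccos of R₃₃; when those entries are at round-off level the
   decomposition falls back to the exact θ = 0 (or 180°) branch where only
   γ (or φ−ψ) is defined — otherwise pure-γ rotations would pick up noise.
4. **a.s.d.** Per-residue average spatial deviation: each frame is aligned
   onto the reference over the fit selection (default: the domain's Cα
   atoms, i.e. intramolecular deformation), and the deviation of each
   residue's Cα is averaged over frames. All-atom selections are a
   parameter.
5. **Free energy vs tilt.** F(θ) = −T ln P(θ) from a histogram (1° bins by
   default), in k_BT, shifted so the minimum over populated bins is zero;
   empty bins are NaN (undefined), never zero. No sin θ Jacobian correction
   is applied by default — the profile then answers "how improbable is this
   tilt", matching how such plots are usually drawn; the correction is a
   flag (`jacobian=True`) because the convention is genuinely ambiguous.

## Synthetic systems

`make_toy_two_domain_system` builds a deterministic two-domain all-atom
polymer: a body strand, a backbone-only hinge linker turning 90° on a 6 Å
arc, a domain strand pointing away from the body, a single-atom
pseudo-cofactor held in the domain by contacts, and a single-atom target on
the body flank (native cofactor–target distance ≈ 11.1 Å, recorded in the
ground-truth metadata). `make_disordered_tail` appends a nucleic-like chain
lying against the body at contact distance, plus the matching disorder
specification. Toy residues (TPR/TLK/TNU) use a reduced alphabet that still
exercises every term type: bond, angle, improper, planar, backbone and
sidechain proper dihedrals, contacts.

Deliberate idealizations, and hence what a green test does not establish:

- Geometry is exactly planar where planar terms apply and all non-excluded
  pairs are ≥ 4.2 Å apart natively, so closed-form energy checks are exact;
  real structures have nonzero planar strain and close non-contacts.
- Sidechain bonds are longer than chemical bonds (2.2 Å) to satisfy the
  spacing contract; the toys test the mathematics of the pipeline, not
  chemical realism (no sequences, no rotamers, no base pairing).
- The generator is deterministic: the seed is recorded for provenance but
  does not perturb coordinates. Clash-freedom is validated, not sampled.
- The domain can tilt well beyond 15° without steric overlap, so
  free-energy profiles over a 7–12° window are reachable in short runs.

The constructed "pre-catalytic" state is a rigid 45° rotation of the domain
about the hinge; the analysis pipeline recovers that axis and angle to
numerical precision, which validates the geometry code but is not evidence
about any real pre/post pair.

## Pipeline and provenance

`run_pipeline` executes build → two simulation arms (restrained at
r_min = 5 Å, k = 150 ε/nm²; unrestrained) → analysis (distance filter at
7 Å, rotation/tilt, a.s.d. per arm, free energy vs tilt from the
unrestrained arm). The two arms share the force field; seeds are
(seed, seed + 1). Every artifact lands in one output directory with a JSON
manifest (config snapshot, seeds, force-field content hash, per-stage
outputs); a stage failure marks the manifest and skips downstream stages.
Topologies are exported as a documented plain-text GROMACS-dialect file that
round-trips losslessly.

## Known limitations

- Single-basin only: no dual-basin or multi-state force fields; transitions
  between distinct experimental conformations are outside the model.
- No electrostatics, solvent, or hydrogens; Fe–S clusters and exotic
  ligands need user-supplied templates.
- The restrained arm uses a plain harmonic (not flat-bottom) restraint.
- The a.s.d. and tilt statistics from toy-scale runs are qualitative; the
  toys are not scaled-down mitoribosomes.
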