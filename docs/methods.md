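# Methods

This note documents the model implemented by `kgsample`, the choices made
where the design was genuinely open, and what the synthetic test systems do
and do not demonstrate.

## Kinematic model

A molecule with fixed bond lengths, bond angles and peptide ω is a linkage
whose configuration is fully specified by its torsions. Atoms joined by
non-rotatable bonds are merged (union–find) into rigid bodies; the body
graph induced by rotatable bonds is spanned by a breadth-first directed
tree rooted, by default, at the body containing the first atom of the first
chain (the N-terminus). Each tree edge is a revolute joint: a right-handed
rotation about the tail→head bond vector, stored as an offset q_j (radians)
from the input structure, so q = 0 reproduces the input coordinates
bit-for-bit. Forward kinematics composes, along each root-to-leaf path,
rotations about the *input-frame* bond axes: the transform of a child body
is T_child = T_parent · Rot(p_tail⁰, u⁰, q_j). Composing in the reference
frame is exact (no drift accumulation beyond floating-point rotation error,
verified < 1e−8 Å on intra-body distances over 1,000 random q).

Rotatability rules (the open part of the model): single heavy-atom bonds
rotate, except the peptide C–N (ω), bonds inside rings (Pro, His, Phe, Tyr,
Trp; ring membership from residue templates), partial double bonds
(carbonyl/carboxylate C–O, amide C–N of Asn/Gln, the Arg guanidinium), any
bond to a terminal atom, and bonds to methyl carbons (a symmetric rotor
whose rotation is sterically and energetically irrelevant here). Torsions
that only move polar hydrogens (Ser/Thr/Tyr OH, Lys NH₃) *do* rotate, since
they position hydrogen-bond donors. Whether methyl and polar-H torsions are
degrees of freedom is a genuine modeling choice; these defaults keep donors
mobile while avoiding meaningless rotor states.

Disulfides found via CONECT are broken out of the covalent tree (the
spanning-tree model needs acyclic topology) and re-imposed as 6-row closure
constraints exactly like hydrogen bonds. This path is implemented but only
lightly exercised: no bundled fixture contains a disulfide.

## Closure constraints and the nullspace

Each hydrogen bond (donor heavy atom D, hydrogen h, acceptor A) closes a
cycle through the lowest common ancestor of the bodies holding h and A.
The constraint requires the positions of h and A to agree whether carried
through the left (h-side) or right (A-side) branch, giving two 3-vector
equations per bond. The analytic Jacobian entry of DoF j for constrained
atom position r is u_j × (r − r_Oj), positive on the h-side path, negative
on the A-side, zero off-path; this is validated against central finite
differences of the branch-difference endpoint maps (ε = 1e−6 rad, relative
error < 1e−5 — the finite-difference oracle is the arbiter of all sign and
frame conventions).

All six rows are always built, even though a single generic cycle has rank
5 (the spin of the bonded pair about the h···A axis changes nothing); the
deficiency is absorbed by the SVD rank tolerance τ = ε_machine · max(rows,
cols) · σ_max (LAPACK-style, overridable). This is more robust than
analytically deleting a row when geometry degenerates further (collinear
axes, coincident atoms). The nullspace basis N (right-singular vectors
below τ) is recomputed at every seed conformation, since J depends on
coordinates; bases are cached per pool member, never reused across
different conformations. A DoF is reported rigidified when ‖Nᵀe_j‖ < 1e−8
(configurable); with the default relative τ this classification is
invariant to root choice and constraint ordering.

The projector is first order, so a finite step drifts the constrained
distances by O(‖Δq‖²). Policy (an open design point): drift is *monitored*,
not corrected — a candidate whose H···A or D···A distance has moved more
than `drift_tolerance` (default 0.1 Å) from its initial value is rejected,
and no iterative closure refinement is attempted. At the default 0.29° step
cap the measured single-step drift is ~1e−4 Å and scales by ~4× when the
cap is halved, confirming the second-order behavior; in practice pooled
samples stay orders of magnitude inside the tolerance.

## Sterics

Non-bonded repulsion is a hard wall: a clash is any non-excluded pair
closer than `collision_factor` × (r_a + r_b), with conventional van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å) and the
default factor 0.75. Excluded are same-rigid-body pairs (constant
distances), pairs within three covalent bonds (1–4 distances are governed
by the torsion itself; standard practice), and the three atom pairs of each
declared hydrogen bond (which sit below van der Waals contact by
construction). Detection uses a uniform grid whose cell edge equals the
largest possible clash distance, searching 27 neighbor cells; it is exact
(set-identical to the all-pairs check, verified on random configurations).

## Sampling protocol

Parameters and defaults: 20 Å exploration radius (CA RMSD from the start),
0.2 Å shell width (100 shells), 0.29° maximum per-DoF rotation per step,
collision factor 0.75, drift tolerance 0.1 Å, and a single seeded RNG for
the whole run. Each iteration: draw a guide conformation with every DoF
uniform on [−π, π) (clashes deliberately ignored — it only steers), pick a
uniformly random occupied shell, seed from its member with the smallest
RMSD to the guide (ties to the lowest sample id), draw Δq ~ N(0, I) over
all DoFs, project, rescale so the largest component equals the cap, apply
forward kinematics, and accept unless clashing, drifting, or outside the
sphere. Two open conventions are resolved as follows: the step is rescaled
*after* projection, so the configured cap bounds the realized move rather
than the trial; and shell/seed RMSD is computed over CA atoms in the
root-anchored frame *without* superposition, since the kinematic root fixes
a common frame and alignment would add O(n²) cost for no benefit at this
scale. Runs are deterministic: identical inputs, configuration and seed
give byte-identical manifests.

## Analysis conventions

Superposition is least-squares (Kabsch, via scipy's rotation alignment)
with the RMSD recomputed from the fitted coordinates. The opening angle Θ
between a sample and a reference superposes the sample on the reference by
the stable-domain CAs and measures the angle between stable→mobile
center-of-mass vectors; zenith/azimuth first rotates the reference so its
inter-domain axis is +z, with azimuth right-handed in [0°, 360°), zero at
+x, and defined as 0 when the zenith is below 1e−6°. Landscapes are counts
on fixed-width grids (defaults 0.5° × 0.1 Å), reported as −log normalized
frequency with empty bins masked. Per-DoF fluctuations use circular
statistics: the RMSF is the root-mean-square of deviations from the
circular mean, wrapped to (−180°, 180°]. This is wrap-safe ((359°, 1°)
gives exactly 1°) and coincides with the linear standard deviation in the
small-angle limit; it is preferred over the √(−2 ln R̄) circular standard
deviation, which differs from the exact RMS at second order.

## Synthetic test systems

The fixtures generate everything the tests need; their role — and limits —
should be understood when reading test results:

* **Ideal helix** (polyalanine, φ = −57°, ψ = −47°, ideal bond geometry,
  explicit hydrogens, all i→i+4 bonds declared, H···O ≈ 2.1 Å): the test
  bed for rigidification. Its constraint network over-determines the
  backbone (nullity 0), the strongest form of the helix-rigidity claim.
* **Single-cycle chain** (n single-atom links on a jittered circle closed
  by one hydrogen bond, seeded and deterministic): the minimal generic
  system for the rank-5 property and drift scaling. Its out-of-plane
  jitter guarantees generic, non-coplanar axes.
* **Two-domain hinge** (two fully constrained 8-residue helices joined by
  a 6-residue extended, unconstrained linker): the end-to-end system. The
  linker length was chosen so the construction meets its contract — a
  hinge soft enough that a 2,000-sample run reorients the domains by more
  than 5° while every intra-domain bond holds; shorter linkers make the
  toy too stiff to exhibit the motion it exists to demonstrate.

What passing these tests shows: the projection, rigidity detection, steric
filter and search behave exactly as specified on molecules with known
structure. What they do not show: behavior on real, imperfect structures —
strained geometry, missing hydrogens, alternate conformations, tightly
packed cores where acceptance ratios drop, or the multi-day, 20,000-sample
regimes of full-size proteins. Test problem sizes (12–22 residues, 1,000–
2,000 samples) were chosen as the smallest systems that exhibit each
property robustly.

## Known limitations

* The nullspace projection is first order; long trajectories rely on the
  rejection policy rather than manifold re-projection.
* The SVD per seed is O(m·n²_cycle); no basis reuse or GPU path exists.
* Seed selection scans one shell per step; for very large pools a
  neighbor index would be preferable.
* Bond inference covers the 20 standard amino acids plus CONECT records;
  modified residues without CONECT are rejected rather than guessed.
* No energetics beyond hard spheres: ensembles are geometric, and
  individual members should be energy-minimized before detailed
  interpretation.
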