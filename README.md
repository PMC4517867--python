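# kgsample

Kino-geometric conformational sampling of proteins: explore dihedral space
while **exactly preserving a declared hydrogen-bond network**, by projecting
every trial move onto the nullspace of a closure-constraint Jacobian.

## The problem and the method

Proteins move by rotating about single covalent bonds (φ, ψ, χ torsions),
but their hydrogen-bond networks — the glue of secondary structure — must
survive those motions. `kgsample` treats a molecule as a kinematic linkage:
rigid bodies (maximal atom groups with no internal rotatable bond) are the
links, torsions are revolute joints, and the linkage is a rooted spanning
tree with *n* degrees of freedom **q**. Each hydrogen bond *h*···*A* closes
a kinematic cycle through the tree and contributes six holonomic closure
constraints

    f_h^L(q) − f_h^R(q) = 0,   f_A^L(q) − f_A^R(q) = 0,

where the L/R endpoint maps carry the two constrained atoms through the two
tree branches meeting at their common ancestor body. Differentiating gives a
6*m* × *n*_cycle Jacobian **J** with entries **u**_j × (**r** − **r**_{O_j})
(**u**_j: unit bond axis of DoF *j*; **r**_{O_j}: its tail atom; **r**: the
constrained atom). The right-singular vectors of **J** with zero singular
value form an orthonormal basis **N** of Ker(**J**); the projector **NN**ᵀ
maps any trial perturbation Δ**q** onto the tangent space of the constraint
manifold, so **q** + **NN**ᵀΔ**q** maintains every bond to first order. A
single generic cycle has rank 5 — the spin about the *h*–*A* axis is never
constrained — so the manifold has dimension *n*_cycle − 5*m*. Cycle DoFs
whose unit move projects to zero are *rigidified*: the constraint network
has immobilized them, with no combinatorial constraint counting required.

Conformation space is explored with a shell-stratified, RRT-like protocol:
the pool of accepted samples is stratified into 0.2 Å-wide RMSD shells
inside a 20 Å exploration sphere; each step seeds from a random occupied
shell (its member closest to a fully random guide conformation), applies a
projected random move capped at 0.29° per DoF, and rejects candidates with
hard-sphere clashes (van der Waals radii scaled by 0.75) or hydrogen-bond
drift. Analysis utilities measure what such ensembles are used for: domain
opening angles, zenith/azimuth landscapes, breathing angles, per-residue
mean displacement fields and wrap-safe per-DoF fluctuations.

## Worked example

Three narrative scripts live in `examples/`. The first builds an ideal
12-residue polyalanine helix with its eight i→i+4 hydrogen bonds and asks
what motion survives:

```sh
$ python examples/01_helix_rigidification.py
120 atoms, 25 rigid bodies, 24 torsional DoFs
8 hydrogen bonds -> Jacobian (48, 20), rank 20, nullity 0
cycle DoFs: 20, rigidified: 20
interior backbone phi/psi: 20, all rigidified: True
```

The helical hydrogen-bond network leaves a zero-dimensional nullspace: no
collective torsion motion can preserve all eight bonds, i.e. the helix core
is rigid. The second example shows the complementary case, a single generic
cycle (rank 5, nullity *n*_cycle − 5) where a projected 0.29° step disturbs
the bond by only ~1e−4 Å versus ~1e−2 Å unprojected. The third samples a
two-domain hinge (500 samples):

```sh
$ python examples/03_hinge_sampling.py
accepted 500 of 531 proposals (ratio 0.94); rejections: clash 31, drift 0
opening angle: max 4.87 deg, spread 4.87 deg
worst hydrogen-bond drift across the pool: 7.55e-15 Å
mean circular RMSF: free DoFs 0.452 deg, cycle DoFs 0.00e+00 deg
```

The free linker torsions reorient the domains by several degrees while the
rigidified helix torsions do not move and every hydrogen bond stays at its
initial length to machine precision.

A thin CLI wraps the same functions:

```sh
kgsample fixtures --kind hinge --out fix/
kgsample run --pdb fix/structure.pdb --constraints fix/constraints.txt \
             --samples 2000 --seed 1 --out run/
kgsample analyze angle --ensemble run/ --reference fix/structure.pdb \
             --stable 1-8 --mobile 15-22 --out angles.csv
```

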