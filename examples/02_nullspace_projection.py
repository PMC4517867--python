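"""One closure constraint removes five degrees of freedom, not six.

Builds a generic 20-DoF single-cycle chain closed by one hydrogen bond,
shows the 6-row Jacobian has numerical rank 5 (the spin about the
hydrogen-acceptor axis is unconstrained), and contrasts the hydrogen-bond
drift of a nullspace-projected step against an unprojected one.
"""

import numpy as np

from kgsample.fixtures import make_single_cycle_chain
from kgsample.kinematics import (build_rigid_bodies, build_tree,
                                 classify_dofs, forward_kinematics)
from kgsample.nullspace import (compute_jacobian, constraint_violation,
                                find_cycles, max_drift, nullspace_basis,
                                project)

topo, coords, constraints = make_single_cycle_chain(20)
tree = build_tree(build_rigid_bodies(topo), topo, coords0=coords)
n_cycle = classify_dofs(tree, constraints)
cycles = find_cycles(tree, constraints)
jac = compute_jacobian(tree, coords, cycles)
basis = nullspace_basis(jac, tree.n_dofs)

print(f"single-cycle chain: n_cycle = {n_cycle}, Jacobian {jac.matrix.shape}")
print(f"singular values: {np.round(basis.singular_values, 3)}")
print(f"rank {n_cycle - basis.nullity} -> nullity {basis.nullity} "
      f"(= n_cycle - 5m with m = 1)")

rng = np.random.default_rng(0)
cap = np.radians(0.29)  # default per-DoF step cap, in radians
trial = rng.standard_normal(tree.n_dofs)
projected = project(trial, basis)
projected *= cap / np.abs(projected).max()
raw = trial * (cap / np.abs(trial).max())

for label, step in (("projected", projected), ("unprojected", raw)):
    drift = max_drift(constraint_violation(
        forward_kinematics(tree, step), constraints))
    print(f"{label:>11s} step of max 0.29 deg -> H-bond drift {drift:.2e} Å")
# The projected move keeps the bond to within ~1e-4 Å (second-order error
# only); the unprojected move of identical size disturbs it nearly two
# orders of magnitude more.
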