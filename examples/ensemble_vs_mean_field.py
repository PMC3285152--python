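"""One mean-field run vs the exact hydrogen-bond ensemble on a toy network.

The 8-body backbone carries two fluctuating hydrogen bonds, so the integer
pebble game has an ensemble of four possible networks.  At occupancy 0.5 the
exact ensemble average is enumerated and compared with the single
virtual-pebble-game run: the Rand Measure scores the rigid-cluster
agreement per realization, and the Pearson correlation compares the
mechanical coupling maps (shared excess DOF per pair / 6).
"""

import numpy as np

from pebblegame import (
    aggregate,
    exact_ensemble,
    mcm_pearson,
    mechanical_coupling_map,
    rand_measure,
    run,
)
from pebblegame.fixtures import toy_two_hbond_network

topo = toy_two_hbond_network()
vertices = list(range(topo.n_vertices))
p = 0.5

vpg = run(aggregate(topo, p))
vpg_labels = vpg.rigid_cluster_decomposition().label
print(f"mean-field free DOF at p={p}: {vpg.free_dof():.4g}")

exact = exact_ensemble(topo, p, collect=("labels", "shared_dof"),
                       vertices=vertices)
print(f"ensemble size: {exact.n_realizations} networks "
      f"(weights {np.round(exact.weights, 3)})")

rms = [rand_measure(vpg_labels, lab) for lab in exact.labels_per_realization]
print("Rand Measure, mean-field vs each realization:",
      np.round(rms, 3), f"-> weighted mean {np.dot(exact.weights, rms):.3f}")

mcm_vpg = mechanical_coupling_map(vpg, vertices)
mcm_pg = mechanical_coupling_map(exact)
print(f"coupling-map Pearson correlation: "
      f"{mcm_pearson(mcm_vpg, mcm_pg):.4f}")
print("(1.0 would mean the single fractional run reproduces the ensemble "
      "mean coupling exactly; p=0.5 on a two-bond toy is the worst case —\n"
      " four wildly different networks carry equal weight.  On larger "
      "networks, and away from the transition, the agreement is far higher;\n"
      " at p=0 or p=1 the two descriptions coincide exactly.)")
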