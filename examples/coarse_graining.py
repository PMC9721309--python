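"""Inhibitory-in-degree coarse-graining of the membrane dynamics.

Groups RS neurons by their exact number of afferent inhibitory synapses
and summarizes each group by the mean membrane potential mu_V and the
Kuramoto order parameter R of the potentials mapped onto [0, pi].  In
the basal state the more-inhibited groups sit at lower mu_V; R near 1
within a group means its members' potentials are aligned.
"""

import numpy as np

from seizprop import (NetworkConfig, PerturbationParams, RecordSpec,
                      build_network, compute_group_profiles,
                      group_by_inhibitory_indegree, run_simulation)

cfg = NetworkConfig(connectivity_seed=1).desk_scaled(5)
net = build_network(cfg)
res = run_simulation(net, PerturbationParams(alpha=0.0), duration=1000.0,
                     dt=0.1, drive_seed=3,
                     record=RecordSpec(vm_populations=("RS",)))

groups = group_by_inhibitory_indegree(net, "RS")
profiles = compute_group_profiles(res, groups, "RS")
print(f"{len(profiles)} nonempty groups "
      f"(in-degrees {profiles[0].group_key}..{profiles[-1].group_key})")
sel = res.vm_times >= 500.0
print(" in-deg  members   mu_V (mV)     R")
for g in profiles[:: max(1, len(profiles) // 10)]:
    print(f"  {g.group_key:4d}   {g.members.size:5d}   "
          f"{g.mu_V[sel].mean():8.2f}   {g.R[sel].mean():.3f}")
print("Each row summarizes one in-degree group; the structural gradient in "
      "inhibition maps onto a gradient of time-averaged membrane potential.")
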