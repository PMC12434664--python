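"""Langevin dynamics of the toy hairpin at a cold and a hot temperature.

The surrogate's folding midpoint sits near T ~ 1.7 in reduced units (from
a temperature scan); T = 0.2 keeps the chain folded and T = 4.0 melts it.
Median Q over the second half of each run summarizes the regime.
"""

import numpy as np

from rnalandscape import SimConfig, build_topology, datasets, native_contacts, q_series, run_langevin

cg, _ = datasets.toy_hairpin()
nc = native_contacts(cg)

for temperature in (0.2, 4.0):
    cfg = SimConfig(temperature=temperature, n_steps=20_000, save_interval=100,
                    timestep=0.01, n_mg=3, seed=7)
    top = build_topology(cg, nc, cfg)
    traj = run_langevin(top, cfg, x0_rna=cg.xyz)
    q = q_series(traj.rna, nc)
    median_q = np.median(q[len(q) // 2:])
    print(f"T = {temperature}: median Q (2nd half) = {median_q:.3f}  "
          f"[{'folded' if median_q > 0.85 else 'unfolded' if median_q < 0.4 else 'intermediate'}]")
print("Q = 1 means every native contact formed; Q < 0.4 is the unfolded ensemble.")
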