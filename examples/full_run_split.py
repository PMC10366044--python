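"""Full three-stage run of the mobile/immobile split model (coarsened).

Runs the validated model variant — 23% of receptors immobile — over the
complete 7200 s schedule on a coarse 60-node mesh so the example finishes
in well under a minute, then prints the complex curve normalized at 1800 s
and the apical free-receptor residual.
"""

import numpy as np

import memrelo as mr

cfg = mr.SimulationConfig(
    model="split", n_nodes=60, plan=mr.StagePlan(substeps=(5, 5, 1)),
    output_every=600.0, store_fields=True,
)
traj = mr.run_simulation(cfg)

curve = mr.normalized_complex_curve(traj, t_norm=1800.0)
print("complex curve normalized at 1800 s:")
for t in (300.0, 600.0, 1800.0, 3600.0, 7200.0):
    print(f"  t = {t:6.0f} s : N_C/N_C(1800) = {curve.loc[t]:.3f}")

t, state, frame = traj.snapshots[-1]
c0 = cfg.N_total / traj.mesh.total_area
frac = mr.apical_free_fraction(state, frame, traj.mesh, c0)
print(f"\napical free-receptor residual at 7200 s: {100*frac:.1f}% of the initial density")
print("  (the immobile pool cannot drain toward the contact area, so a")
print("   fraction close to the 23% immobile share persists apically)")

imm = state.c_R_i + state.c_C_i
print(f"immobile nodal totals drift: {np.max(np.abs(imm - 0.23*c0)):.2e} (exactly conserved)")
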