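"""Simulate one refold + force-ramp cycle and look at its ground truth.

A dumbbell experiment holds an RNA aptamer between two trapped beads via
DNA handles.  During the low-load refolding period the tertiary state
(helix arms apart / weakly bound / docked) evolves as a Markov chain; the
ramp then unfolds whatever conformation was reached, in its characteristic
sequence of rips.
"""

import numpy as np

import forcefret as ff

cfg = ff.condition_sim_config("TPP", refold_duration=10.0)
mech = ff.MechanicalModel()
trace = ff.simulate_trace(cfg, mech, seed=1)

n_refold = trace.refold_end_index
print(f"frames: {len(trace)} total, {n_refold} refolding at "
      f"{trace.frame_period * 1e3:.0f} ms each")
states, counts = np.unique(trace.truth_tertiary[:n_refold], return_counts=True)
print("refold tertiary-state occupancy:",
      {s: int(c) for s, c in zip(states, counts)})
print(f"conformation held at ramp start: {trace.meta['ramp_conformation']}")
print("rip frames:", trace.meta["rip_frames"])
print("opening forces (pN):",
      [round(f, 1) for f in trace.meta["opening_forces_frame"]])
print(f"peak force reached: {trace.force.max():.1f} pN")

# The opening forces are the loads at which secondary-structure elements
# ruptured; an F-class (no bound ligand) trace shows three of them, a
# tightly bound F''-class trace a single one above 20 pN.
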