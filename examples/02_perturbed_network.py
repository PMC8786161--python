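"""Multi-stability of a randomly perturbed 16-oscillator network.

Reproduces the 7-epoch showcase: a new random perturbation is applied every
20000 steps and the coupled network settles into a different stable
collective oscillation each time.  Printed: per-epoch perturbation
magnitude, peak of the summed matrix observable M, and the stability flag.
"""
import socrcc

res = socrcc.run_experiment("fig1-perturbation-16", seed=1)
print("epoch  |sum eps|   max(M)  stable")
for s in res.summaries:
    print(f"{s.epoch:5d}  {s.eps_sum:9.5f}  {s.max_M:7.1f}  {s.stable}")
print("-> seven distinct stable orbits: the perturbation selects the "
      "collective state, it does not destabilise it.")
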