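"""Perturbation-response exponent and power-law tail estimation.

Runs a reduced 16-unit perturbation experiment (40 epochs), fits the power
curve max(M) = a * eps^b on log-log axes, and estimates the power-law tail
of the peak distribution by maximum likelihood with a KS-selected cutoff.
Also validates the estimator on a synthetic Pareto sample of known
exponent.
"""
import socrcc

res = socrcc.run_experiment("fig2-size-sweep-8-16-32", seed=1, n_units=16,
                            n_epochs=40)
pf, pl = res.power_fit, res.powerlaw
print(f"power fit:    max(M) = {pf.a:.2f} * eps^{pf.b:.3f}   (mse={pf.mse:.1f})")
print(f"tail MLE:     alpha={pl.alpha:.2f}, x_min={pl.x_min:.1f}, "
      f"KS={pl.ks_distance:.3f}, n_tail={pl.n_tail}")

x = socrcc.generate_fixture("pareto", seed=4, alpha=2.5, n=5000)
fit = socrcc.powerlaw_mle(x)
print(f"Pareto check: true alpha=2.50, estimated alpha={fit.alpha:.3f}")
print("-> the negative exponent b is the scale-free perturbation response; "
      "the Pareto recovery validates the estimator itself.")
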