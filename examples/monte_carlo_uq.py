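"""Monte-Carlo uncertainty of the additive-rate model at high stress.

Draws 250-sample ensembles with normal parameter perturbations of 10, 20
and 30% (one static draw per sample) at a constant 2 kPa and summarizes
the response.  The mean drifts away from the unperturbed prediction and
the distribution stretches upward — the nonlinear sensitivity that a
linearized analysis cannot capture, and the reason median/extremes are
reported alongside mean/variance.
"""

import plateletuq as pq

soares = pq.builtin_parameters("soares")
h = pq.generate_uniform_stress(2e4, 0.0, duration=1.0, dt=1e-3)  # 2 kPa

print(f"{'ampl':>5} {'mean':>8} {'median':>8} {'sd':>8} {'min':>8} {'max':>8}")
for amplitude in (0.1, 0.2, 0.3):
    ens = pq.run_mc(h, (soares, ("S", "F")),
                    pq.PerturbationSpec(amplitude, mode="per_sample",
                                        n_samples=250, seed=42))
    s = ens.summary()
    print(f"{amplitude:>5.1f} {s['mean']:>8.3f} {s['median']:>8.3f} "
          f"{s['variance'] ** 0.5:>8.3f} {s['min']:>8.4f} {s['max']:>8.3f}")

print(f"\nunperturbed PAS = {ens.unperturbed:.3f}")
print("The spread grows with amplitude and is strongly asymmetric: positive"
      "\nparameter perturbations push PAS much further up (towards full"
      "\nactivation) than equal negative ones push it down.")

sigma = ens.samples.std(ddof=1)
n = pq.required_sample_size(sigma, epsilon=0.01)
print(f"\nFor a standard error of 0.01 at 30% amplitude one needs "
      f"~{n} samples (σ = {sigma:.3f}).")
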