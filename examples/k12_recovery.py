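"""Recover k12 from a noisy synthetic recording.

Generates an agonist-evoked GIRK-bg4 trace with 5% additive Gaussian
noise, then fits k12 (and the signal scale) by bounded least squares
with a residual-bootstrap 95% interval — the desk-scale analogue of
inferring receptor-G protein coupling rates from current recordings.
"""

from girkflow import (
    GeometryParams,
    StimulusProtocol,
    default_parameters,
    fit_k12,
    generate_trace,
)

params = default_parameters("Gi-coupled")
geometry = GeometryParams()
protocol = StimulusProtocol.step(params.k12, t_end=10.0)

clean = generate_trace(params, geometry, protocol, noise_sd=0.0, seed=0)
noise_sd = 0.05 * float(clean.y.max())
trace = generate_trace(params, geometry, protocol, noise_sd=noise_sd, seed=7)

result = fit_k12(trace, params, geometry, n_boot=200, seed=8)

print(f"true k12      : {params.k12:.4f} um^2/s")
print(f"fitted k12    : {result.k12_hat:.4f} um^2/s "
      f"({100 * (result.k12_hat / params.k12 - 1):+.1f}% error)")
print(f"95% bootstrap : [{result.ci_low:.4f}, {result.ci_high:.4f}]")
print(f"converged     : {result.converged}   "
      f"flat loss profile: {result.flat_profile}")
print("\nThe interval covers the generating value; the flat-profile flag "
      "would warn if k12 sat in the saturated response plateau, where "
      "traces no longer constrain it.")
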