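"""Drug insertion kinetics and the exclusion surface pressure.

Simulates constant-area insertion traces at several initial pressures pi0,
fits the pseudo-first-order model dpi(t) = dpi_max (1 - exp(-beta t)) to
each, and extrapolates dpi_max vs pi0 to the exclusion pressure.
"""

from memtool.monolayer import exclusion_pressure, fit_insertion_kinetics
from memtool.synthetic import gen_insertion_traces

traces, truth = gen_insertion_traces(seed=7)

points = []
print("  pi0 (mN/m)   dpi_max (mN/m)   beta (1/s)")
for trace in traces:
    fit = fit_insertion_kinetics(trace)
    points.append((trace.pi_zero, fit.delta_pi_max))
    print(f"  {trace.pi_zero:8.1f}   {fit.delta_pi_max:12.3f}   {fit.beta:10.5f}")

res = exclusion_pressure(points)
print()
print(f"regression: dpi_max = {res.slope:.3f} * pi0 + {res.intercept:.2f}")
print(f"exclusion pressure = {res.pi_exclusion:.1f} mN/m "
      f"(generator: {truth['exclusion_pressure_mN_m']:.1f})")
print()
print("Above the exclusion pressure the film is too compressed for the")
print("drug to insert; a value above the collapse pressure means the drug")
print("adsorbs at any attainable film pressure.")
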