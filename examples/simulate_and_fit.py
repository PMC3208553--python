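"""Closed-loop recovery: simulate an assay, gate it, scan parameter space.

Simulates 100,000 macrophages at a known truth (m = 1.5, p = 0.48,
alpha = 1.6) together with a negative control, derives the quadrant gates
from the control (50% of it in Q1), counts the observed quadrant fractions,
and scans a 20x20x20 grid at the standard resolutions.  The local Rt minima
are printed: one of them should sit on the simulated truth with a residual
close to counting noise.
"""

from phagofit import ParamPoint
from phagofit.validation import fit_simulated_condition, grid_around

truth = ParamPoint(m=1.5, p=0.48, alpha=1.6)
grid = grid_around(truth)
observed, minima = fit_simulated_condition(truth, seed=11, grid=grid)

print(f"simulated truth: m={truth.m}, p={truth.p}, alpha={truth.alpha}")
print(f"observed fractions: Q1={observed.q1:.4f}, Q2+3={observed.q23:.4f}")
print(f"scan: {grid.size} grid points, {len(minima)} local Rt minima\n")
print(f"{'label':<6}{'m':>8}{'p':>7}{'alpha':>8}{'Rt':>10}")
for lm in minima:
    marker = "  <- truth" if (
        abs(lm.point.m - truth.m) <= 0.0625
        and abs(lm.point.p - truth.p) <= 0.04
        and abs(lm.point.alpha - truth.alpha) <= 0.15
    ) else ""
    print(f"{lm.label:<6}{lm.point.m:>8.4f}{lm.point.p:>7.2f}"
          f"{lm.point.alpha:>8.2f}{lm.rt:>10.4f}{marker}")
print("\nMultiple minima are expected: two observables constrain three")
print("parameters, so solutions lie on a ridge. The minimum at the truth")
print("has Rt at the level of Monte Carlo counting noise (~0.005).")
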