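"""Verify the finite-difference solver against the erf closed form.

Holds the skin at 10 degC from t = 0 (a step change) and compares the
Crank-Nicolson solution with the semi-infinite-solid analytic solution
Phi = Ts + (T0 - Ts) erf(x / 2 sqrt(alpha t)). Valid as an oracle
because 30 minutes of cooling penetrates ~1.5 cm, far from the 10-cm
deep boundary.
"""

from cryodepth import BoundaryCondition, analytic_semi_infinite, solve

ALPHA = 0.149e-6  # plain water, m^2/s

boundary = BoundaryCondition(times=[0.0, 1800.0], temps=[10.0, 10.0], deep_temp_T0=37.0)
field = solve(boundary, ALPHA)

print("depth   t (s)   CN (degC)   erf (degC)   |diff|")
worst = 0.0
for x_cm in (0.5, 1.0, 2.0, 3.0):
    trace = field.at_depth(x_cm * 1e-2)
    for t in (300, 900, 1800):
        cn = trace[t]
        exact = analytic_semi_infinite(10.0, 37.0, ALPHA, x_cm * 1e-2, float(t))
        worst = max(worst, abs(cn - exact))
        print(f"{x_cm:4.1f} cm {t:6d} {cn:10.4f} {exact:12.4f} {abs(cn - exact):9.2e}")
print(f"\nlargest deviation: {worst:.2e} degC (tolerance for acceptance: 0.05 degC)")
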