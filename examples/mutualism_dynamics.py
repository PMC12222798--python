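"""Simulate the cancer-fibroblast mutualism and map the extinction boundary.

Uses the inferred in-vitro parameter set (r_C = 1.1e-3, mu = 1e-3 per hour,
facilitation beta_C = 4.19e-4 per fibroblast) to show that (i) cancer alone
persists at low abundance, (ii) half-maximal drug without facilitation
drives it extinct, (iii) facilitation rescues it, and scans steady-state
cancer abundance over the (beta_C, X) plane.
"""

import numpy as np

from tmecrosstalk.mutualism import invitro_params, simulate, steady_state, stress_gradient_scan

p = invitro_params()  # carrying capacities = 100 x 10,000 seeded cells
print(f"net low-density growth without drug: r_C - mu = {p.r_C - p.mu:.1e} cells/cell/hour")

mono = steady_state(p.replace(beta_C=0.0, beta_F=0.0))
print(f"cancer alone, X=0:            C* = {mono.C_star:,.0f} cells "
      f"(= K_C (1 - mu/r_C) = {p.K_C * (1 - p.mu / p.r_C):,.0f})")

alone_drug = steady_state(p.replace(X=0.5, beta_C=0.0))
print(f"cancer alone, X=0.5:          C* = {alone_drug.C_star:,.0f} cells "
      "(division r_C/1.5 < mu: extinct)")

with_fib = steady_state(p.replace(X=0.5))
print(f"with fibroblast facilitation: C* = {with_fib.C_star:,.0f}, "
      f"F* = {with_fib.F_star:,.0f} cells")

traj = simulate(p.replace(X=0.5), C0=10_000, F0=10_000,
                times=np.linspace(24, 24 * 14, 14))
print(f"\n14-day coculture under X=0.5: C grows {traj['C'][-1] / 10_000:.1f}x "
      f"(10,000 -> {traj['C'][-1]:,.0f} cells)")

scan = stress_gradient_scan(p, beta_C_grid=np.linspace(0, p.beta_C, 9),
                            X_grid=np.linspace(0, 1, 5))
print("\nsteady-state cancer abundance C* (rows: drug effect X; cols: beta_C "
      "from 0 to the inferred value); 0 marks extinction:")
header = "  X \\ beta_C " + " ".join(f"{b:8.1e}" for b in scan["beta_C"])
print(header)
for Xv, row in zip(scan["X"], scan["C_star"]):
    print(f"  {Xv:10.2f} " + " ".join(f"{c:8.0f}" for c in row))
print("\nBlocking facilitation (moving left along a row) lowers C* and, at")
print("higher doses, crosses the extinction boundary - the model's case for")
print("combining endocrine therapy with ERBB inhibition.")
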