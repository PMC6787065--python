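"""Diazotroph growth and limitation terms.

Evaluates the temperature-dependent maximum growth rate and the three
nutrient limitation terms of the N2-fixer group over representative
surface conditions, and prints the window in which fixation escapes its
cold-water floor.
"""

import numpy as np

from nfixbox import (DiazotrophParams, SurfaceEnvironment,
                     diazotroph_growth_rate, diazotroph_limitations)

params = DiazotrophParams()

print("temperature response mu_D(T):")
for t in (10, 15, 20, 25, 26.8, 30, 35):
    print(f"  T={t:5.1f} C  mu_D={float(diazotroph_growth_rate(t)):.4f}")
print("  (the floor of 0.01 is active outside roughly 19.3-34.4 C;")
print("   the optimum sits near 26.8 C)")

print("\nlimitation terms in contrasting waters:")
cases = {
    "oligotrophic gyre  (PO4 0.2, NO3 0.1, Fe 0.5)": (0.2, 0.1, 0.5),
    "upwelling edge     (PO4 1.0, NO3 2.0, Fe 0.3)": (1.0, 2.0, 0.3),
    "HNLC, iron-starved (PO4 1.5, NO3 8.0, Fe 0.1)": (1.5, 8.0, 0.1),
}
for label, (po4, no3, fe) in cases.items():
    env = SurfaceEnvironment(temperature=26.0, po4=po4, no3=no3, fe=fe)
    p_lim, n_lim, f_lim = diazotroph_limitations(env, params)
    binding = min((float(p_lim), "PO4"), (float(n_lim), "NO3"),
                  (float(f_lim), "Fe"))
    print(f"  {label}: PO4_lim={float(p_lim):.3f} NO3_lim={float(n_lim):.3f} "
          f"Fe_lim={float(f_lim):.3f} -> {binding[1]} limits")

print("\nFixers thrive where NO3 is scarce (e^-NO3 near 1) and enough iron")
print("is present for tanh(2Fe - K_Fe) to open; ambient nitrate shuts the")
print("niche long before phosphate does.")
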