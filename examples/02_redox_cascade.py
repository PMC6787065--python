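"""The remineralisation redox cascade in one column.

Partitions a unit export flux through the sub-grid sediment fractions of
the eastern tropical Pacific column, and shows how the water-column
denitrification fraction and its NO3 limiter respond to oxygen and
nitrate.
"""

import numpy as np

from nfixbox import make_geometry, suboxic_fraction
from nfixbox.remin import (effective_wc_denit_fraction, sed_denit_factor,
                           sinking_flux_partition, wc_denit_fraction,
                           wc_denit_no3_limiter)

geom = make_geometry()
col = geom.columns[geom.index("trop_pac_east_surface")]
fractions = [geom.sediment_contact_fraction[b] for b, _, _ in col]
names = [geom.tags[b] for b, _, _ in col]

sed, wc, leaving = sinking_flux_partition(1.0, fractions)
print("unit export through the eastern Pacific column:")
for name, f, s in zip(names, fractions, sed):
    print(f"  {name:18s} contact={f:.2f}  sediment delivery={s:.3f}")
print(f"  (everything is intercepted by the bottom: leaving={leaving:.3f})")

print("\nwater-column denitrification fraction f_den(O2):")
for o2 in (0.0, 2.0, 3.75, 7.5, 15.0):
    print(f"  O2={o2:5.1f}  f_den={float(wc_denit_fraction(o2)):.5f}")
print("f_den is 1 in anoxia and negligible above ~15 mmol O2/m3.")

print("\nNO3 floor r_WCden (denitrification cannot strip NO3 below ~30):")
for no3 in (25.0, 30.0, 40.0, 50.0):
    print(f"  NO3={no3:5.1f}  r={float(wc_denit_no3_limiter(no3)):.5f}")
print("effective fraction at O2=2, NO3=32:",
      f"{float(effective_wc_denit_fraction(2.0, 32.0)):.4f}")

print("\nsediment denitrification per unit C rain:")
for o2, no3 in ((50, 50), (100, 10), (10, 35)):
    print(f"  O2={o2:4d} NO3={no3:3d}  dNO3/C="
          f"{float(sed_denit_factor(o2, no3)):.4f}")
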