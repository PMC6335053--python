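"""Steady-state GIRK response as a function of stimulus strength k12.

k12 — how fast an active receptor captures a G-protein trimer — is the
single parameter separating Gi-coupled receptors (which activate GIRK)
from Gs-coupled ones (tenfold smaller k12, no activation). The response
is steep right around the Gi-coupled reference value.
"""

import numpy as np

from girkflow import GeometryParams, default_parameters, sweep_k12

params = default_parameters("Gi-coupled")
geometry = GeometryParams()

grid = np.geomspace(params.k12 / 100.0, params.k12 * 10.0, 13)
table = sweep_k12(params, geometry, grid)

for _, row in table.iterrows():
    marker = "  <- Gi reference" if np.isclose(row.k12, params.k12) else ""
    if np.isclose(row.k12, params.k12 / 10.0):
        marker = "  <- Gs-like (k12/10)"
    print(f"k12 = {row.k12:9.5f} um^2/s   steady GIRK-bg4 = {row.girk4:.5f} um^-2{marker}")

gi = table.girk4.iloc[np.argmin(np.abs(grid - params.k12))]
gs = table.girk4.iloc[np.argmin(np.abs(grid - params.k12 / 10.0))]
print(f"\nGi/Gs response ratio across one decade of k12: {gi / gs:.1f}x")
print("A tenfold k12 difference maps onto a >5x difference in activated "
      "channels: rate, not wiring, sets the specificity.")
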