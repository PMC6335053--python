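"""Membrane Gbg concentration around a single receptor vs a hotspot.

Free Gbg diffuses (D = 0.2 um^2/s) and is re-sequestered (k = 1/s), so
its profile decays over lambda = sqrt(D/k) ~ 0.45 um. A lone receptor
cannot build an activating concentration; a 0.3 um disk of 50 receptors
per um^2 (~14 receptors) can.
"""

from girkflow import (
    GeometryParams,
    density_to_concentration,
    disk_source_profile_numeric,
    point_source_profile,
    receptors_in_disk,
)

geometry = GeometryParams()
print(f"characteristic length lambda = {geometry.characteristic_length:.3f} um\n")

point = point_source_profile(geometry, turnover=1.0)
print(f"single receptor, C(r0={geometry.inner_radius} um): "
      f"{point.C[0]:.2f} um^-2 "
      f"({density_to_concentration(point.C[0]) * 1e6:.2f} uM)")

disk = disk_source_profile_numeric(geometry, mesh_size=1200)
c0 = disk.C[0]
n_receptors = receptors_in_disk(geometry.receptor_density, geometry.hotspot_radius)
print(f"hotspot (R = {geometry.hotspot_radius} um, ~{n_receptors:.0f} receptors), "
      f"C(0): {c0:.2f} um^-2 ({density_to_concentration(c0) * 1e6:.2f} uM)")

for r in (0.0, 0.15, 0.3, 0.6, 1.0):
    print(f"  r = {r:4.2f} um   C = {disk.interpolate(r):6.3f} um^-2")

print("\nThe hotspot center reaches ~12.5 molecules/um^2 (~2.5 uM), about "
      "4x what a lone receptor achieves at its own perimeter — receptor "
      "clustering, not proximity to the channel, builds the Gbg signal.")
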