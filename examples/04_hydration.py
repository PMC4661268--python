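"""Pore hydration: density profile and wetting/dewetting classification.

Generates a synthetic pore-occupancy series whose hydrophobic segment is dry,
computes the water number-density profile in 1 A slices (cylinder volume at
the reference radius), converts to g/ml, and classifies wetted/dewetted
intervals along the pore axis.
"""
import numpy as np

from porepmf import OccupancySeriesSpec, PoreGeometry, classify_wetting, convert_density, density_profile, generate_occupancy_series
from porepmf.hydration import BULK_DENSITY

spec = OccupancySeriesSpec(
    z_range=(-14.0, 4.0),
    pore_radius_profile=5.0,
    mean_bulk_density=BULK_DENSITY,       # 0.03343 molecules/A^3 = 1.000 g/ml
    dewetting_zone=(-11.0, -9.0),         # dry hydrophobic segment
    flicker_rate=0.0,
    start_wetted=False,
    seed=4,
)
frames = generate_occupancy_series(spec, n_frames=400)
profile = density_profile(frames, PoreGeometry(reference_radius=5.0, z_range=(-14.0, 4.0)))

bulk = profile.density[(profile.z_centers < -11.5) | (profile.z_centers > -8.5)].mean()
print(f"recovered bulk density : {bulk:.5f} molecules/A^3 = {convert_density(bulk):.3f} g/ml")

for iv in classify_wetting(profile, bulk=BULK_DENSITY):
    print(f"  z in [{iv.z_lo:+6.1f}, {iv.z_hi:+6.1f}) A : {iv.state}")

print("\nSlices inside the hydrophobic zone drop below half the bulk density and")
print("classify as a dewetted interval — the vapor plug of a hydrophobic gate.")
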