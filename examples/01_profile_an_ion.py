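"""Histogram a synthetic ion surface into its σ-profile.

Generates a COSMO-like segment set, bins it on the standard σ grid
(−0.03 … 0.03 e/Å², 0.001-wide bins) and reports how the surface area
distributes over the hydrogen-bond donor, non-polar and acceptor regions.
"""

from iltox import SurfaceGenSpec, classify_sigma_region, compute_profile, \
    gen_surface, sigma_grid

spec = SurfaceGenSpec(n_segments=500, total_area=300.0, seed=11)
surface, truth = gen_surface(spec, ion_id="demo-cation")
profile = compute_profile(surface, sigma_grid())

print(f"ion {surface.ion_id}: {len(surface)} segments, "
      f"total area {surface.total_area:.2f} A^2")
print(f"binned area {profile.bin_areas.sum():.2f} A^2 "
      f"(spill {profile.spill_area:.2f} A^2 in {profile.spill_count} segments)")

region_area = {"HB_donor": 0.0, "non_polar": 0.0, "HB_acceptor": 0.0}
for center, area in zip(profile.bin_centers, profile.bin_areas):
    region_area[classify_sigma_region(center)] += area
for region, area in region_area.items():
    print(f"  {region:12s} {area:8.2f} A^2  ({100 * area / surface.total_area:5.1f}%)")

# Binned area equals the input surface area: nothing is silently dropped.
# The three regions partition the sigma axis at +/-0.0082 e/A^2; a mostly
# non-polar ion (like this synthetic one) concentrates its area in the middle.
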