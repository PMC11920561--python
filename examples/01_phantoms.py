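"""Build the two study phantoms and inspect their fills.

The homogeneous cylinder drives sensitivity, uniformity and noise; the NEMA
IEC body phantom (six hot spheres + cold lung) drives contrast recovery.
"""

import hospect as h

# A cylinder preset records the fill volume and activity; length follows
# from diameter and volume.
cyl = h.make_cylinder_spec(preset="UMCU")
print(f"cylinder: D={cyl.diameter_mm:.0f} mm, L={cyl.length_mm:.1f} mm, "
      f"{cyl.total_activity_mbq:.0f} MBq "
      f"({cyl.background_concentration_mbq_ml * 1000:.1f} kBq/mL)")

# NEMA presets record background and total-sphere fills; the nominal
# sphere-to-background ratio R is recomputed from the concentrations.
nema = h.make_nema_spec(preset="Radboudumc")
print(f"NEMA: R = {nema.fill_ratio:.2f} "
      f"(fill sheet: {nema.meta['fill_sheet_ratio']})")
for s in nema.spheres:
    print(f"  sphere {s.inner_diameter_mm:>4.0f} mm = "
          f"{h.sphere_analytic_volume(s.inner_diameter_mm):5.1f} mL "
          f"at (x,y) = ({s.center_mm[0]:6.1f}, {s.center_mm[1]:6.1f}) mm")

# Voxelize onto a 64³ grid of 4.8 mm voxels (desk scale).  Activity is
# conserved to the fill sheet within the voxelization error.
grid = h.VoxelGrid.centered(64, 4.8)
vol = h.voxelize_phantom(cyl, grid)
print(f"voxelized cylinder: {vol.total_activity_mbq:.1f} MBq on the grid "
      f"vs {cyl.total_activity_mbq:.1f} MBq filled")
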