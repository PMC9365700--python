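"""Ideal tetramer assemblies: composition, hinge geometry and unfolding.

Builds the three idealized assemblies of the 11.5 nm square tetramer unit —
the p442 flat sheet, the minimal closed cube of 6 units and the 10-unit
prism — then measures what the geometry implies: protomer counts and masses,
the bend angle across edge-sharing units, and the segment rotation implied
by unfolding the cube into a sheet.
"""

import numpy as np

from shell_lattice import (
    assembly_to_particle_table,
    build_cube,
    build_prism,
    build_sheet,
    linker_spans,
    neighbor_bend_angles,
    point_group_check,
    unfold_cube_to_sheet,
)

cube = build_cube()
prism = build_prism()
sheet = build_sheet(n=3, m=3)

print(f"cube : {len(cube)} tiles, {cube.n_protomers} protomers, {cube.mass_mda:.2f} MDa, "
      f"O-symmetric: {point_group_check(cube, 'O')}")
print(f"prism: {len(prism)} tiles, {prism.n_protomers} protomers, {prism.mass_mda:.2f} MDa, "
      f"D4-symmetric: {point_group_check(prism, 'D4')}")
env = prism.envelope() / 10.0
print(f"prism envelope: {env[0]:.0f} x {env[1]:.0f} x {env[2]:.1f} nm")
print(f"sheet: {len(sheet)} tiles, {sheet.mass_kda:.0f} kDa")
# The cube and prism masses follow directly from the 69.5 kDa protomer; the
# 24-protomer cube is the smallest assembly that closes into a compartment.

table = assembly_to_particle_table(cube)
edge = cube.unit.side / np.sqrt(2.0)
_, angles = neighbor_bend_angles(table, edge * 0.9, edge * 1.1)
print(f"\nedge-sharing cube tiles bend by {np.abs(angles).mean():.1f} degrees "
      f"({len(angles)} pairs)")
# 90 degrees is the maximum inter-tetramer bend the purified assemblies show.

net, report = unfold_cube_to_sheet(cube)
print(f"\nunfolded net: {report['n_tiles']} tiles, {report['n_hinges']} hinges of "
      f"{list(report['hinge_rotation_deg'].values())[0]:.0f} degrees each")
print(f"implied C-terminal segment rotation: {report['cts1_rotation_deg']:.1f} degrees")
# Unfolding maps the cube corner's 3-fold axis onto the sheet corner's 4-fold
# axis; the angle between the two axes (~55 degrees) is the rotation the
# corner-crossing segment must absorb.

spans = linker_spans(cube)
print(f"\nlinker spans (synthetic anchors): "
      f"linker1 {spans['linker1_span_A'].mean():.1f} A, "
      f"linker2 {spans['linker2_span_A'].mean():.1f} A "
      f"(bounds {spans.attrs['linker1_max_extension_A']:.0f} / "
      f"{spans.attrs['linker2_max_extension_A']:.0f} A)")
# Both disordered linkers stay well under their fully extended contour
# lengths, so the same connectivity works in sheet and cube geometry.
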