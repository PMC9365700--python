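"""Channel pore profiling against analytic fixtures.

Builds bead-lined channels with known free-radius profiles (a cylinder and
an hourglass) and measures radius profiles, restrictive diameters and pore
volumes, including probe-centre relaxation for an off-axis channel.
"""

import numpy as np

from shell_lattice import BeadModel, make_channel, pore_profile, pore_volume, restrictive_diameter

cyl = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=100.0)
prof = pore_profile(cyl.model, zrange=(-50, 50), dz=2.0)
print(f"cylinder: R(z) = {prof.radius.mean():.3f} A at every station, "
      f"restrictive diameter {restrictive_diameter(prof):.2f} nm")
# ring radius 8 A minus bead radius 1 A leaves a 7 A free radius = 1.4 nm
# restrictive diameter.

hour = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=100.0, waist=4.0)
ph = pore_profile(hour.model, zrange=(-50, 50), dz=2.0)
err = np.abs(ph.radius - hour.analytic_radius(ph.z)).max()
print(f"hourglass: restrictive diameter {restrictive_diameter(ph):.2f} nm at the waist, "
      f"max deviation from the analytic taper {err:.1e} A")

shifted = BeadModel(coords=cyl.model.coords + [3.0, 0.0, 0.0],
                    masses=cyl.model.masses, radii=cyl.model.radii)
fixed = pore_profile(shifted, zrange=(-50, 50), dz=2.0)
relaxed = pore_profile(shifted, zrange=(-50, 50), dz=2.0, relax=True)
print(f"off-axis channel: fixed-axis radius {fixed.radius.max():.2f} A, "
      f"relaxed {relaxed.radius.mean():.2f} A")
# Coordinate-ascent relaxation re-finds the true channel centre; pinning the
# probe to the nominal axis underestimates the clearance.

vol_ch = make_channel("cylinder", ring_radius=6.7, atom_radius=1.7, length=100.0)
vp = pore_profile(vol_ch.model, zrange=(-50, 50), dz=2.0)
print(f"\ncylinder R = 5 A over 10 nm: volume {pore_volume(vp):.3f} nm^3 "
      f"(closed form {np.pi * 0.25 * 10:.3f})")
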