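"""Cell geometry and buoyant density under nitrogen deprivation.

Median Coulter-counter diameters convert to spherical volumes; cells banding
between two sucrose layers take the midpoint density of the neighbouring
layers.
"""

from ndomics import (
    density_midpoint,
    density_reduction_pct,
    round_half_up,
    sphere_volume,
    volume_increase_pct,
)

d_nd, d_nr = 2.84, 2.45  # median diameters (um)
v_nd, v_nr = sphere_volume(d_nd), sphere_volume(d_nr)
print(f"median volume: ND {v_nd:.1f} um^3 vs NR {v_nr:.1f} um^3 "
      f"({volume_increase_pct(d_nd, d_nr):.1f}% larger under ND)")

rho_nr = density_midpoint(1.243, 1.278)
rho_nd = density_midpoint(1.102, 1.137)
print(f"buoyant density: NR {round_half_up(rho_nr, 3)} g/mL, "
      f"ND {round_half_up(rho_nd, 3)} g/mL "
      f"({density_reduction_pct(rho_nr, rho_nd):.1f}% lower under ND)")
print("Bigger, lighter cells: low-density lipid droplets accumulate while")
print("dense photosynthetic membranes are lost.")
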