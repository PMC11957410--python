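"""Locate and classify topological defect lines in a wave field.

A complex order parameter in three dimensions admits line singularities
(permissible defect dimension d - n = 3 - 2 = 1).  This example builds a
moderately disordered lamellar field, finds the phase-singular voxels by
the 8-neighbor winding loop, traces them into polylines, and prints the
screw/edge census: screw dislocations run along the layer normal, edge
dislocations perpendicular to it.
"""

import math

from leveledwaves import (WaveModelParams, WaveVectorDistribution,
                          build_plane_wave_field, defect_statistics,
                          find_defect_lines, permissible_defect_dimension,
                          waves_for)

print("permissible defect dimension for (d=3, n=2):",
      permissible_defect_dimension(3, 2), "(line defects)")

d = 40.0
for gamma, label in [(128.0, "lamellar (Gamma=128)"),
                     (2.0, "sponge-like (Gamma=2)")]:
    dist = WaveVectorDistribution(k0=2 * math.pi / d, sigma_k=0.1,
                                  gamma=gamma)
    params = WaveModelParams(dist=dist, alpha=0.3, n_waves=1000,
                             grid_n=64, seed=3)
    fld = build_plane_wave_field(params, waves_for(params))
    lines = find_defect_lines(fld, min_length=3)
    st = defect_statistics(lines, params.box_edge)
    print(f"{label}: {st.n_lines} lines "
          f"({st.count_screw} screw, {st.count_edge} edge), "
          f"line density {st.line_density:.2e} per A^2")
print("The more isotropic state carries a far denser defect network — "
      "the structural signature of the lamellar-to-sponge transition.")
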