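"""Check the voxel solver against the analytic layered-sphere series.

Two small disk electrodes are placed on a sphere; the voxel solution's
|E| on a mid-depth shell is compared with the Legendre-series oracle
(excluding 20-degree caps under the electrodes, where a point-electrode
oracle and a disk-electrode solver legitimately differ).  The homogeneous
sphere shows the discretization floor; the layered head shows the
staircase-interface error, which shrinks as the grid is refined.
"""

from fieldlab.sphere import SphereLayers, validate_solver

homog = SphereLayers((92.0,), (0.276,))
head = SphereLayers((58.0, 72.0, 76.0, 83.0, 92.0), (0.126, 0.276, 1.65, 0.01, 0.465))

m = validate_solver(homog, electrode_separation_deg=180.0, voxel_size_mm=4.0)
print(f"homogeneous, 4 mm: median |E| error {m['median_rel_error']:.1%} "
      f"(p90 {m['p90_rel_error']:.1%}, {m['n_points']} samples)")

for voxel in (4.0, 2.0):
    m = validate_solver(head, electrode_separation_deg=90.0, voxel_size_mm=voxel)
    print(f"5-layer head, {voxel:.0f} mm: median |E| error {m['median_rel_error']:.1%} "
          f"(p90 {m['p90_rel_error']:.1%})")
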