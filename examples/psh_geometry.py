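"""Build and export the porous polystyrene sphere geometry.

Starting from a solid 10 μm sphere, 200 small (0.4 μm) spheres centered on
the current surface are subtracted per iteration, 50 times; the resulting
porous model is voxelized and exported as a plain-text dipole list for
DDA-class electromagnetic solvers.
"""

from pclar import (PSHBuildSpec, build_psh_model, export_dda_geometry,
                   porosity, voxelize)

spec = PSHBuildSpec(seed=7)  # 10 um host, 0.4 um holes, 200/iter, 50 iters
model = build_psh_model(spec)
print(f"subtracted spheres: {len(model.subtracted_centers)}")

grid = voxelize(model, spacing_um=0.1)
print(f"voxels occupied at 0.1 um spacing: {grid.n_occupied}")
print(f"porosity: {porosity(model, grid=grid):.3f} "
      "(void fraction of the host sphere)")

export_dda_geometry(grid, "psh_geometry.txt")
print("geometry written to psh_geometry.txt (one 'ix iy iz' line per dipole)")
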