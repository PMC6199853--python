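"""Loft a predicted point cloud into a watertight bone surface (STL)."""

from pathlib import Path

from osteokit import (
    GeneratorConfig,
    PointCloudGrid,
    fit_full_model,
    generate_population,
    loft,
    predict_cloud,
)

cfg = GeneratorConfig(bone_family="tube", S=8, noise_sigma=0.0, seed=0)
population, _ = generate_population(cfg)
model = fit_full_model(population)

cloud = predict_cloud(model, population.parameters[0])
grid = PointCloudGrid.from_flat(cloud.points, cloud.grid)
mesh = loft(grid, samples_per_slice=64, cap_ends=True)
print(f"lofted surface: {len(mesh.vertices)} vertices, "
      f"{len(mesh.faces)} faces")
print(f"watertight: {mesh.is_watertight}, "
      f"Euler characteristic: {mesh.euler_characteristic}, "
      f"enclosed volume: {mesh.volume / 1000:.1f} cm^3")
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = mesh.save(out / "bone_surface.stl")
print(f"wrote {path}")
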