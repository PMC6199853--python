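"""Design a personalised fixation plate on a synthetic bone surface.

Reference line through three surgeon-selected landmarks, contact patch from
the surrounding bone points, 3 mm offset solid.  Screw holes need a patch
several points wide across the plate (the hole block must fit strictly
inside the grid); this bone's corridor is 3 points wide, so the plate is
exported without holes — see the test suite for a holed flat plate.
"""

from pathlib import Path

from osteokit import GeneratorConfig, PlateSpec, design_plate, export_plate
from osteokit.synthetic_data import landmark_points, specimen_cloud

cfg = GeneratorConfig(bone_family="tube", S=1, noise_sigma=0.0)
params = {"length": 370.0, "prox_width": 30.0,
          "mid_width": 30.0, "dist_width": 30.0}
bone = specimen_cloud(cfg, params)
landmarks = landmark_points(bone, cfg.plan(), cfg.M)

spec = PlateSpec(
    reference_point_ids=["plate_a", "plate_b", "plate_c"],
    corridor_half_width=8.0,       # mm each side of the reference line
    thickness=3.0,                 # mm, printed reconstructive plate value
    u_cluster_gap=10.0,            # slice spacing is ~34 mm
)
plate = design_plate(bone, landmarks, spec, bone_ref="synthetic-tube")
print(f"contact patch: {plate.patch.nu} x {plate.patch.nv} bone points "
      "(vertices are the bone's own points)")
print(f"solid: watertight={plate.solid.is_watertight}, "
      f"volume={plate.solid.volume:.0f} mm^3")
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = export_plate(plate, out / "plate.stl")
print(f"wrote {path} (+ manifest JSON alongside)")
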