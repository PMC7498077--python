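"""Build one complete plant and export its 3D mesh scene.

Starting from the built-in Zaodabai truth configuration, this script runs a
synthetic 50-plant field campaign, fits a parameter database from the
resulting measurement table, samples one plant from the fitted database, and
writes the plant tree (JSON) and a combined organ mesh scene (OBJ).
"""

import warnings
from pathlib import Path

from tuberoot import (
    build_database,
    build_plant,
    default_truth,
    generate_measurements,
    plant_scene,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

cfg = default_truth(1, n_plants=50, seed=0)        # variety 1 = Zaodabai
table = generate_measurements(cfg)
db = build_database(table, variety="Zaodabai")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    plant = build_plant(db, seed=7)

print(f"variety {plant.variety}, seed {plant.seed}: "
      f"{plant.node_count()} organ nodes")
for oc in ("seminal_root", "creeping_root", "creeping_stem", "tuber"):
    nodes = plant.by_class(oc)
    print(f"  {oc:15s} x{len(nodes)}")
depths = plant.depths_by_class("seminal_root")
print(f"seminal-root depths (mm): "
      f"{', '.join(f'{d:.0f}' for d in sorted(depths))}")
print("(depth is the deepest point of each simulated growth trajectory,")
print(" measured from the soil surface)")

plant.save(out / "plant.json")
scene = plant_scene(plant)
scene.export(out / "plant.obj")
print(f"wrote {out / 'plant.json'} and {out / 'plant.obj'} "
      f"({len(scene.geometry)} organ meshes)")
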