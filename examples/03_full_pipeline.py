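"""Run the whole pipeline: phantom dataset -> registered masked volume -> STL.

Writes a jittered sphere-phantom slice stack to disk, then runs
preparation -> registration -> segmentation (threshold window) -> volume
assembly with shape-based isotropic interpolation -> marching cubes ->
metrics, exactly as the `slicerecon run` command would.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

import slicerecon as sr

root = Path(tempfile.mkdtemp(prefix="slicerecon_demo_"))
grid = (96, 96, 26)
spacing = (0.33, 0.33, 1.0)
w = (grid[0] - 1) * spacing[0]
h = (grid[1] - 1) * spacing[1]
spec = sr.PhantomSpec(
    shape_kind="sphere",
    shape_params={"radius": 9.0, "center": (w / 2, h / 2, 12.5)},
    grid_shape=grid,
    spacing=spacing,
    fiducials=[(w / 2, 3.0, 1.2), (w - 3.0, h / 2, 1.2), (3.0, h - 3.0, 1.2)],
    jitter=sr.random_jitter(grid[2], seed=11, max_translation_px=3.0,
                            integer_translations=True,
                            image_shape=(grid[1], grid[0])),
    seed=3,
)
sr.write_phantom_dataset(spec, root / "dataset")

config = sr.PipelineConfig(
    input_dir=str(root / "dataset"),
    output_mesh=str(root / "sphere.stl"),
    registration_enabled=True,
    mask_mode="threshold",  # window [128, 255]: solid only, rods excluded
    isotropic=True,
    isovalue=127.5,
)
report = sr.run_pipeline(config)

metrics = report["metrics"]
true_volume = 4 / 3 * np.pi * 9.0**3
print(json.dumps(metrics, indent=1, sort_keys=True))
print(f"volume rel. err vs analytic sphere: "
      f"{metrics['enclosed_volume_mm3']/true_volume-1:+.4f}")
print(f"mesh written to {config.output_mesh}")
# The mesh is watertight with Euler characteristic 2 and encloses the
# analytic sphere volume to within ~1%, despite per-slice jitter.
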