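"""Recover per-slice acquisition jitter from three fiducial rods.

Renders a sphere phantom into a 96x96x20 slice stack (0.33 mm pixels, 1 mm
slices) with three fiducial disks, perturbs each slice by a random rigid
transform, then re-estimates the transforms from detected rod centroids and
compares them with the known ground truth.
"""

import numpy as np

import slicerecon as sr

grid = (96, 96, 20)
spacing = (0.33, 0.33, 1.0)
w = (grid[0] - 1) * spacing[0]
h = (grid[1] - 1) * spacing[1]
spec = sr.PhantomSpec(
    shape_kind="sphere",
    shape_params={"radius": 8.0, "center": (w / 2, h / 2, 9.5)},
    grid_shape=grid,
    spacing=spacing,
    # distinct y per rod keeps the (y, x) label order stable under jitter
    fiducials=[(w / 2, 3.0, 1.2), (w - 3.0, h / 2, 1.2), (3.0, h - 3.0, 1.2)],
    jitter=sr.random_jitter(grid[2], seed=5, max_translation_px=3.0,
                            max_rotation_deg=2.0, image_shape=(grid[1], grid[0])),
)

stack, truth = sr.generate_slice_stack(spec)
registered, transforms = sr.register_stack(stack, reference_index=0)

errors = [
    sr.transform_mean_displacement(t, j.inverse(), stack.shape)
    for t, j in zip(transforms, truth.transforms)
]
print(f"slices registered: {len(transforms)}")
print(f"mean displacement between recovered and true inverse transforms: "
      f"max {max(errors):.2e} px, mean {np.mean(errors):.2e} px")
# Values far below 0.1 px: three noiseless rods determine the affine almost
# exactly, so the registered stack is aligned to sub-pixel precision.
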