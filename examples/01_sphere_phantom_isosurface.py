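"""Reconstruct a sphere phantom's surface and compare with the closed form.

Samples the signed-distance field of a 10 mm sphere on a 32^3 grid at 1 mm
spacing, extracts the zero isosurface (inside rendered positive so normals
point outward), and checks volume and area against (4/3)*pi*r^3 and 4*pi*r^2.
"""

import numpy as np

import slicerecon as sr

spec = sr.PhantomSpec(
    shape_kind="sphere",
    shape_params={"radius": 10.0, "center": (15.35, 15.55, 15.45)},
    grid_shape=(32, 32, 32),
    spacing=(1.0, 1.0, 1.0),
)
field = sr.generate_field(spec)  # signed distance, negative inside
bright = sr.Volume(-field.data, field.spacing, field.origin)  # inside positive
mesh = sr.extract_isosurface(bright, isovalue=0.0)

report = sr.watertight_check(mesh)
volume = sr.enclosed_volume(mesh)
area = sr.surface_area(mesh)
r = spec.shape_params["radius"]

print(f"vertices={mesh.n_vertices} triangles={mesh.n_triangles}")
print(f"watertight={report.is_closed} euler={sr.euler_characteristic(mesh)}")
print(f"enclosed volume = {volume:.2f} mm^3 (analytic {4/3*np.pi*r**3:.2f}, "
      f"rel. err {volume/(4/3*np.pi*r**3)-1:+.4f})")
print(f"surface area    = {area:.2f} mm^2 (analytic {4*np.pi*r**2:.2f}, "
      f"rel. err {area/(4*np.pi*r**2)-1:+.4f})")
# A watertight Euler-2 mesh within ~1-2% of the analytic sphere shows the
# kernel places iso-points accurately at this resolution.
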