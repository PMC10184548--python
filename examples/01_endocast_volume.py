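"""Measure the enclosed volume of an endocast-like mesh.

Builds a synthetic ellipsoid "endocast" with an analytically known volume,
writes it to STL, reads it back and integrates the enclosed volume with the
signed-tetrahedron sum -- the same path a real segmented endocast surface
would take.
"""

import math
import tempfile
from pathlib import Path

from paleoneuro import load_mesh, make_ellipsoid_mesh, mesh_volume, save_stl

# Semi-axes loosely shaped like a large theropod cerebral endocast (mm).
result = make_ellipsoid_mesh(a=70.0, b=35.0, c=30.0, subdivisions=4)
true_cm3 = result.true_volume_mm3 / 1000.0

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "endocast.stl"
    save_stl(result.mesh, path)
    mesh = load_mesh(path)
    measured = mesh_volume(mesh)

print(f"analytic ellipsoid volume : {true_cm3:.3f} cm^3")
print(f"mesh-integrated volume    : {measured:.3f} cm^3")
print(f"relative error            : {abs(measured - true_cm3) / true_cm3:.4%}")
# The mesh is an inscribed polyhedron, so it slightly underestimates the
# smooth surface; at 4 subdivisions the deficit is ~0.2%, far below the
# uncertainty of any fossil segmentation.
assert abs(measured - true_cm3) / true_cm3 < 0.005
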