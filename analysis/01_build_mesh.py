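#!/usr/bin/env python
"""Build the 3-tooth tooth-mandible section at full and reduced resolution,
report element counts per tissue region, and export the meshes as VTK.

The full-resolution mesh (0.2 mm elements) reproduces the target scale of
~29,000 elements with ~9,000-10,500 of them trabecular; the reduced mesh
(0.6 mm) is the reference configuration used for the parametric studies.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from osteoadapt.geometry import GeometryParams, RegionLabel, build_geometry, generate_mesh
from osteoadapt.vtkio import write_vtk

OUT = Path(__file__).resolve().parent.parent / "results" / "mesh"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for tier, h in (("full", 0.2), ("reduced", 0.6)):
    params = GeometryParams(element_size=h)
    mesh = generate_mesh(build_geometry(params), params)
    labels, counts = np.unique(mesh.region, return_counts=True)
    row = {"tier": tier, "element_size_mm": h, "elements": mesh.n_elements,
           "nodes": mesh.n_nodes}
    row.update({RegionLabel(l).label: int(c) for l, c in zip(labels, counts)})
    rows.append(row)
    write_vtk(OUT / f"mesh_{tier}.vtk", mesh,
              cell_data={"region": mesh.region.astype(int)})
    print(f"{tier} (h={h} mm): {mesh.n_elements} elements, "
          f"{row['trabecular']} trabecular, {mesh.n_nodes} nodes")

table = pd.DataFrame(rows)
table.to_csv(OUT / "element_counts.csv", index=False)
print(f"\nwrote {OUT / 'element_counts.csv'}")
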