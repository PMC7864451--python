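"""Why contacts need Voronoi, not just distances.

Three collinear cells: the end pair is within each other's interaction
range, yet the middle cell sits between them, so they share no real
interface.  The bounded weighted-Voronoi construction recognizes this; a
plain distance cutoff does not.
"""

import numpy as np

import blastopack as bp

cells = [bp.Cell(id=i, position=np.array([0.9 * i, 0.0, 0.0]),
                 base_radius=1.0) for i in range(3)]
g = bp.voronoi_contacts(cells)
d02 = np.linalg.norm(cells[0].position - cells[2].position)
print(f"end-pair distance {d02:.2f} < cutoff 2.00, but contact edges are "
      f"{sorted(g.edges())}: the middle cell occludes the end pair")

# the same rule makes exact squares classify as squares even when the
# diagonal is within the distance cutoff
state = bp.make_fixture("square")
print(f"square fixture edges {sorted(state.graph.edges())} -> "
      f"label {state.label.value}")

for name in ("line", "t_shape", "diamond", "tetrahedron"):
    st = bp.make_fixture(name)
    print(f"{name:12s} -> {st.label.value:12s} "
          f"({st.graph.number_of_edges()} contacts)")
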