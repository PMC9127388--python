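"""Stress-free reference geometry and meshing of the vessel wall ring.

VH-IVUS frames are gated at the R-wave peak, i.e. end-diastole, so the imaged
geometry corresponds to the *minimum*-pressure state, not a stress-free one.
Two pre-deformations build the computational reference:

* axial shrinkage (default 5%): the solve applies a fixed axial stretch
  ``lambda_z = 1 / (1 - axial_shrinkage)``;
* circumferential shrinkage: a uniform in-plane scale ``s < 1`` about the
  lumen centroid, chosen so that inflating the scaled geometry to the
  minimum pressure recovers the imaged lumen area.  ``s`` is found by the
  fixed-point iteration ``s <- s * sqrt(A_target / A_computed)``, which is
  monotone because lumen area responds monotonically to the overall scale.

The wall ring is meshed with a structured grid of 6-node (quadratic)
triangles in polar parameter space about the lumen centroid; quadratic
elements avoid volumetric locking under the near-incompressibility penalty.
Contours are star-shaped by construction of the generator, which makes the
polar structured mesh well-posed; midside nodes are sampled on the true
contour so boundary edges follow its curvature.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field, replace

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon
from shapely.prepared import prep

from .cohort import VesselGeometry, radius_profile

__all__ = [
    "ReferenceGeometry",
    "Mesh",
    "ShrinkError",
    "build_mesh",
    "find_circumferential_shrink",
    "export_mesh_vtk",
]

DEFAULT_AXIAL_SHRINKAGE = 0.05
TISSUE_CODES = {"wall": 0, "lipid": 1, "calcium": 2}


def _scaled_geometry(geometry: VesselGeometry, s: float) -> VesselGeometry:
    """Uniform in-plane scaling of all contours about the lumen centroid."""
    c = geometry.lumen_centroid
    return replace(
        geometry,
        lumen_contour=c + s * (geometry.lumen_contour - c),
        eem_contour=c + s * (geometry.eem_contour - c),
        components=[(t, c + s * (p - c)) for t, p in geometry.components],
    )


@dataclass
class ReferenceGeometry:
    """Shrunken (stress-free) contours plus the axial stretch to apply."""

    geometry: VesselGeometry
    circumferential_shrink_factor: float = 1.0
    axial_shrinkage: float = DEFAULT_AXIAL_SHRINKAGE

    def __post_init__(self) -> None:
        if not 0.0 < self.circumferential_shrink_factor <= 1.0 + 1e-9:
            raise ValueError("shrink factor must lie in (0, 1]")
        if not 0.0 <= self.axial_shrinkage < 1.0:
            raise ValueError("axial shrinkage must lie in [0, 1)")

    @property
    def axial_stretch(self) -> float:
        return 1.0 / (1.0 - self.axial_shrinkage)

    @classmethod
    def from_imaged(
        cls,
        geometry: VesselGeometry,
        shrink_factor: float = 1.0,
        axial_shrinkage: float = DEFAULT_AXIAL_SHRINKAGE,
    ) -> "ReferenceGeometry":
        return cls(_scaled_geometry(geometry, shrink_factor), shrink_factor, axial_shrinkage)


@dataclass
class Mesh:
    """Quadratic-triangle mesh of the wall ring.

    Element connectivity is (corner0, corner1, corner2, mid01, mid12, mid20),
    counter-clockwise.  ``lumen_edges`` lists the boundary edges on the lumen
    loop as (start, end, mid) node triples ordered counter-clockwise, which
    is what the follower-pressure load integrates over.
    """

    nodes: np.ndarray  # (N, 2) mm
    elements: np.ndarray  # (E, 6) int
    tissue: np.ndarray  # (E,) str in {wall, lipid, calcium}
    lumen_nodes: np.ndarray  # ordered node ids on the lumen loop
    outer_nodes: np.ndarray
    lumen_edges: np.ndarray  # (n_edges, 3) int
    fibers: np.ndarray  # (E, 2) circumferential unit vectors
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def build_mesh(ref: ReferenceGeometry, target_edge_length: float = 0.08) -> Mesh:
    """Structured quadratic triangulation of the wall ring.

    Angular and radial resolution follow the target edge length; element
    tissue labels come from which component polygon (if any) contains the
    element centroid.
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    g = ref.geometry
    center = g.lumen_centroid

    probe = np.linspace(0.0, 2.0 * np.pi, 128, endpoint=False)
    try:
        r_l_probe = radius_profile(g.lumen_contour, center, probe)
        r_e_probe = radius_profile(g.eem_contour, center, probe)
    except ValueError as exc:  # degenerate contours
        raise ValueError(f"triangulation failed: {exc}") from exc
    if np.any(r_e_probe - r_l_probe <= 0):
        raise ValueError("triangulation failed: EEM inside lumen along some ray")

    circumference = 2.0 * np.pi * float(np.mean(r_l_probe))
    thickness = float(np.mean(r_e_probe - r_l_probe))
    n_theta = max(16, int(round(circumference / target_edge_length)))
    n_rad = max(2, int(round(thickness / target_edge_length)))

    # node grid at half-resolution steps so midside nodes lie on the contours
    nt2, nr2 = 2 * n_theta, 2 * n_rad
    thetas = np.linspace(0.0, 2.0 * np.pi, nt2, endpoint=False)
    r_l = radius_profile(g.lumen_contour, center, thetas)
    r_e = radius_profile(g.eem_contour, center, thetas)
    s = np.linspace(0.0, 1.0, nr2 + 1)
    rr = r_l[:, None] + s[None, :] * (r_e - r_l)[:, None]  # (nt2, nr2+1)
    xx = center[0] + rr * np.cos(thetas)[:, None]
    yy = center[1] + rr * np.sin(thetas)[:, None]

    def nid(i, j):
        return (np.asarray(i) % nt2) * (nr2 + 1) + np.asarray(j)

    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    elems = []
    for ii in range(n_theta):
        i0 = 2 * ii
        for jj in range(n_rad):
            j0 = 2 * jj
            a, b = nid(i0, j0), nid(i0 + 2, j0)
            c, d = nid(i0 + 2, j0 + 2), nid(i0, j0 + 2)
            m_ab, m_bc = nid(i0 + 1, j0), nid(i0 + 2, j0 + 1)
            m_diag = nid(i0 + 1, j0 + 1)
            m_cd, m_da = nid(i0 + 1, j0 + 2), nid(i0, j0 + 1)
            # corner order counter-clockwise in the plane (the (theta, r)
            # parameter map is orientation-reversing)
            elems.append([a, c, b, m_diag, m_bc, m_ab])
            elems.append([a, d, c, m_da, m_cd, m_diag])
    elements = np.asarray(elems, dtype=np.int64)

    centroids = nodes[elements[:, :3]].mean(axis=1)
    tissue = np.full(len(elements), "wall", dtype="<U7")
    for t, poly in g.components:
        inside = contains_xy(prep(Polygon(poly)).context, centroids[:, 0], centroids[:, 1])
        tissue[inside] = t

    rel = centroids - center
    rad = np.hypot(rel[:, 0], rel[:, 1])
    fibers = np.column_stack([-rel[:, 1], rel[:, 0]]) / rad[:, None]

    lumen_nodes = nid(np.arange(nt2), 0)
    outer_nodes = nid(np.arange(nt2), nr2)
    lumen_edges = np.column_stack(
        [nid(2 * np.arange(n_theta), 0), nid(2 * np.arange(n_theta) + 2, 0),
         nid(2 * np.arange(n_theta) + 1, 0)]
    )

    mesh = Mesh(nodes, elements, tissue, lumen_nodes, outer_nodes, lumen_edges,
                fibers, center)
    _check_element_areas(mesh)
    return mesh


def _check_element_areas(mesh: Mesh) -> None:
    tri = mesh.nodes[mesh.elements[:, :3]]
    v1 = tri[:, 1] - tri[:, 0]
    v2 = tri[:, 2] - tri[:, 0]
    areas = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    if np.any(areas <= 0):
        raise ValueError(
            f"triangulation failed: {int(np.sum(areas <= 0))} non-positive element areas"
        )


class ShrinkError(RuntimeError):
    """Circumferential-shrink iteration failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace  # list of (scale, computed lumen area)


def find_circumferential_shrink(
    geometry: VesselGeometry,
    material_map: dict | None = None,
    tolerance: float = 0.01,
    target_edge_length: float = 0.08,
    solver_config=None,
    max_iter: int = 20,
    axial_shrinkage: float = DEFAULT_AXIAL_SHRINKAGE,
) -> ReferenceGeometry:
    """Find the uniform scale whose inflation recovers the imaged lumen area.

    Inflates the candidate reference to ``geometry.pressure_min`` and
    iterates ``s <- s * sqrt(A_target / A_computed)`` until the relative
    lumen-area mismatch is within *tolerance*.  The scale is capped at 1
    (shrinkage only): a configuration that would need circumferential
    expansion to reach the imaged area (e.g. a near-rigid wall under axial
    stretch) fails with :class:`ShrinkError`.
    """
    from .fe import SolverConfig, solve_inflation  # local import: no cycle at module load
    from .material import material_table

    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    materials = material_map or material_table()
    config = solver_config or SolverConfig()
    a_target = geometry.lumen_area
    s = 1.0
    trace: list[tuple[float, float]] = []
    for _ in range(max_iter):
        ref = ReferenceGeometry.from_imaged(geometry, shrink_factor=min(s, 1.0),
                                            axial_shrinkage=axial_shrinkage)
        mesh = build_mesh(ref, target_edge_length)
        sol = solve_inflation(mesh, materials, geometry.pressure_min,
                              replace(config, axial_stretch=ref.axial_stretch))
        a_computed = sol.lumen_area
        trace.append((s, a_computed))
        if abs(a_computed - a_target) / a_target <= tolerance:
            return ref
        s = s * float(np.sqrt(a_target / a_computed))
    raise ShrinkError(
        f"shrink factor did not converge in {max_iter} iterations "
        f"(target {a_target:.4g} mm^2)",
        trace,
    )


def export_mesh_vtk(mesh: Mesh, path: str | pathlib.Path,
                    point_data: dict[str, np.ndarray] | None = None) -> pathlib.Path:
    """Write the mesh as legacy ASCII VTK with integer tissue tags.

    Cell type 22 is the VTK quadratic triangle, whose node ordering matches
    this package's (corners then midsides).
    """
    path = pathlib.Path(path)
    lines = ["# vtk DataFile Version 3.0", "vessel wall ring mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    lines += [f"{x:.9g} {y:.9g} 0" for x, y in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 7}")
    lines += ["6 " + " ".join(map(str, e)) for e in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["22"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(TISSUE_CODES[t]) for t in mesh.tissue]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in np.asarray(values)]
    path.write_text("\n".join(lines) + "\n")
    return path
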