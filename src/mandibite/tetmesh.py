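"""Tetrahedral meshes with named anatomical node sets.

The package works in a consistent mm-N-MPa unit system: node coordinates in
mm, areas in mm^2, volumes in mm^3, forces in N, stresses/moduli in MPa.

Volume meshes are built by Kuhn subdivision (6 tetrahedra per cube) of an
axis-aligned voxelization.  Because every cube face is split along the same
diagonal in neighbouring cubes, the resulting complex is conforming, every
tetrahedron has positive signed volume, and the external boundary is
watertight by construction; these properties are nevertheless re-checkable
via :func:`check_watertight` because meshes may also be loaded from disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np

from .errors import MeshQualityError, TopologyError

#: anatomical node sets every mandible mesh must carry
REGION_NAMES = (
    "articulation_dorsal",
    "articulation_ventral",
    "masticatory_margin",
    "apical_tooth",
    "apodeme_insertion",
)

# ---------------------------------------------------------------------------
# basic tet geometry


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra, mm^3 (positive for correct orientation)."""
    edges = nodes[tets[:, 1:]] - nodes[tets[:, :1]]  # (m, 3, 3)
    return np.linalg.det(edges) / 6.0


def _face_view(faces: np.ndarray) -> np.ndarray:
    """Canonical (sorted) faces viewable as single records for np.unique."""
    f = np.sort(faces, axis=1)
    return np.ascontiguousarray(f).view([("", f.dtype)] * 3).ravel()


def all_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 4m faces of m tets and the owning tet index of each."""
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([tets[:, c] for c in combos], axis=0)
    owners = np.tile(np.arange(len(tets)), 4)
    return faces, owners


def boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Faces belonging to exactly one tet, outward-oriented, with owners."""
    faces, owners = all_faces(tets)
    rec = _face_view(faces)
    _, first, counts = np.unique(rec, return_index=True, return_counts=True)
    sel = first[counts == 1]
    return faces[sel], owners[sel]


def orient_outward(nodes, tets, faces, owners) -> np.ndarray:
    """Flip boundary triangles so their normals point away from the owner tet."""
    faces = faces.copy()
    tri = nodes[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    # the tet node opposite the face
    opp = np.empty(len(faces), dtype=nodes.dtype)
    owner_nodes = tets[owners]
    for i in range(len(faces)):
        extra = np.setdiff1d(owner_nodes[i], faces[i], assume_unique=False)
        opp_i = nodes[extra[0]]
        if np.dot(normals[i], tri[i, 0] - opp_i) < 0:
            faces[i, [1, 2]] = faces[i, [2, 1]]
    return faces


def triangle_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = nodes[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


# ---------------------------------------------------------------------------
# the mesh container


@dataclass
class TaggedTetMesh:
    """Tetrahedral volume mesh with named anatomical node sets.

    Parameters
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) int array, positively oriented node indices
    region_tags : mapping of region name -> sorted int array of node indices
    apodeme_direction : (3,) unit vector, line of action of the mandible
        closer muscle at the apodeme insertion
    metadata : free-form provenance (morphotype, seed, voxel size, the
        strike load direction, apical capability flag, ...)
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_tags: dict[str, np.ndarray] = field(default_factory=dict)
    apodeme_direction: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region_tags = {
            k: np.unique(np.asarray(v, dtype=np.int64))
            for k, v in self.region_tags.items()
        }
        if self.apodeme_direction is not None:
            self.apodeme_direction = np.asarray(self.apodeme_direction, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        """Per-tet volumes (mm^3); raises on degenerate elements."""
        vols = tet_volumes(self.nodes, self.tets)
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise MeshQualityError(
                f"{bad.size} tetrahedra have non-positive volume "
                f"(first offenders: {bad[:10].tolist()})",
                element_ids=bad,
            )
        return vols

    def boundary(self) -> tuple[np.ndarray, np.ndarray]:
        """Outward-oriented boundary triangles and owning tet indices."""
        faces, owners = boundary_faces(self.tets)
        return orient_outward(self.nodes, self.tets, faces, owners), owners

    @property
    def surface_area(self) -> float:
        return surface_area(self)

    def validate(self) -> None:
        """Check every container invariant; raise on the first violation."""
        self.element_volumes()
        check_watertight(self)
        for name in REGION_NAMES:
            tag = self.region_tags.get(name)
            if tag is None or len(tag) == 0:
                raise TopologyError(f"region tag '{name}' is missing or empty")
            if tag.min() < 0 or tag.max() >= self.n_nodes:
                raise TopologyError(f"region tag '{name}' references invalid nodes")
        art = np.union1d(
            self.region_tags["articulation_dorsal"],
            self.region_tags["articulation_ventral"],
        )
        margin = self.region_tags["masticatory_margin"]
        apical = self.region_tags["apical_tooth"]
        if np.intersect1d(art, np.union1d(margin, apical)).size:
            raise TopologyError(
                "articulation tags overlap the masticatory margin / apical tooth"
            )
        if not np.isin(apical, margin).all():
            raise TopologyError("apical_tooth is not a subset of masticatory_margin")
        if self.apodeme_direction is None or not np.isclose(
            np.linalg.norm(self.apodeme_direction), 1.0, atol=1e-9
        ):
            raise TopologyError("apodeme_direction missing or not unit length")


def check_watertight(mesh: TaggedTetMesh) -> None:
    """Raise TopologyError unless the external surface is closed.

    Every facet must belong to one tet (boundary) or two (interior), and
    every boundary edge must be shared by an even number of boundary
    triangles (two on a manifold surface; four at a pinch, which voxel
    shells may legitimately contain).
    """
    faces, _ = all_faces(mesh.tets)
    rec = _face_view(faces)
    _, counts = np.unique(rec, return_counts=True)
    if (counts > 2).any():
        raise TopologyError("a facet is shared by more than two tetrahedra")
    bfaces, _ = boundary_faces(mesh.tets)
    if len(bfaces) == 0:
        raise TopologyError("mesh has no boundary faces")
    edges = np.concatenate(
        [bfaces[:, [0, 1]], bfaces[:, [1, 2]], bfaces[:, [0, 2]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    erec = np.ascontiguousarray(edges).view([("", edges.dtype)] * 2).ravel()
    _, ecounts = np.unique(erec, return_counts=True)
    if (ecounts % 2 != 0).any():
        raise TopologyError(
            "boundary surface is not closed: an edge is shared by an odd "
            "number of boundary triangles"
        )


def surface_area(mesh: TaggedTetMesh) -> float:
    """Total external surface area (mm^2) of a watertight mesh."""
    check_watertight(mesh)
    faces, _ = boundary_faces(mesh.tets)
    return float(triangle_areas(mesh.nodes, faces).sum())


def mesh_volume(mesh: TaggedTetMesh) -> float:
    """Total enclosed volume (mm^3) as the sum of element volumes."""
    return float(mesh.element_volumes().sum())


# ---------------------------------------------------------------------------
# Kuhn voxel tetrahedralization

# the six tetrahedra of the unit cube around the (0,0,0)-(1,1,1) diagonal,
# expressed as corner offsets; even permutations are positively oriented,
# odd ones need a swap
_KUHN_TETS = []
for perm in permutations(range(3)):
    p0 = np.zeros(3, dtype=np.int64)
    p1 = p0.copy()
    p1[perm[0]] = 1
    p2 = p1.copy()
    p2[perm[1]] = 1
    p3 = np.ones(3, dtype=np.int64)
    tet = [p0, p1, p2, p3]
    # parity of the permutation
    inv = sum(
        1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j]
    )
    if inv % 2 == 1:
        tet[2], tet[3] = tet[3], tet[2]
    _KUHN_TETS.append(np.stack(tet))
_KUHN_TETS = np.stack(_KUHN_TETS)  # (6, 4, 3)


def voxels_to_tets(
    voxels: np.ndarray, origin: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Turn integer voxel coordinates into a conforming tet mesh.

    Parameters
    ----------
    voxels : (v, 3) int array of voxel (i, j, k) indices
    origin : world coordinates of the grid corner (0, 0, 0)
    spacing : voxel edge length, mm

    Returns
    -------
    nodes : (n, 3) float, tets : (6v, 4) int
    """
    voxels = np.asarray(voxels, dtype=np.int64)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
        raise MeshQualityError("voxel list must be a non-empty (v, 3) int array")
    # global corner coordinates per tet node: (v, 6, 4, 3)
    corners = voxels[:, None, None, :] + _KUHN_TETS[None, :, :, :]
    corners = corners.reshape(-1, 3)
    # hash corner ijk -> node id
    uniq, inverse = np.unique(corners, axis=0, return_inverse=True)
    tets = inverse.reshape(-1, 4)
    nodes = np.asarray(origin, dtype=float)[None, :] + spacing * uniq
    return nodes, tets


def structured_box_mesh(
    divisions: tuple[int, int, int],
    lengths: tuple[float, float, float],
    origin=(0.0, 0.0, 0.0),
) -> TaggedTetMesh:
    """Uniform tet mesh of an axis-aligned box (handy for solver tests).

    ``divisions`` counts cubes per axis; the cube edge must be identical on
    every axis (lengths[i] / divisions[i] constant) so Kuhn subdivision stays
    uniform.
    """
    divisions = tuple(int(d) for d in divisions)
    h = lengths[0] / divisions[0]
    for L, d in zip(lengths, divisions):
        if not np.isclose(L / d, h):
            raise MeshQualityError("box divisions must give cubic voxels")
    grid = np.stack(
        np.meshgrid(*[np.arange(d) for d in divisions], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    nodes, tets = voxels_to_tets(grid, np.asarray(origin, dtype=float), h)
    return TaggedTetMesh(nodes=nodes, tets=tets, metadata={"spacing": h})


# ---------------------------------------------------------------------------
# I/O: VTK legacy (volume), STL (surface), JSON sidecar (region tags)


def write_vtk(
    mesh: TaggedTetMesh, path, cell_data: dict[str, np.ndarray] | None = None
) -> None:
    """Write the tet mesh as a legacy-ASCII VTK unstructured grid."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("mandibite tet mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        cells = np.column_stack(
            [np.full(mesh.n_tets, 4, dtype=np.int64), mesh.tets]
        )
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10, dtype=np.int64), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_tets}\n")
            for name, values in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.17g")


def read_vtk(path) -> tuple[TaggedTetMesh, dict[str, np.ndarray]]:
    """Read back a legacy-ASCII VTK unstructured tet grid (our own subset)."""
    tokens = Path(path).read_text().split()
    cell_data: dict[str, np.ndarray] = {}
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = tokens.index("CELLS")
    m = int(tokens[i + 1])
    raw = np.array(tokens[i + 3 : i + 3 + 5 * m], dtype=np.int64).reshape(m, 5)
    if (raw[:, 0] != 4).any():
        raise TopologyError("VTK file contains non-tetrahedral cells")
    tets = raw[:, 1:]
    j = 0
    toks = tokens
    while "SCALARS" in toks[j:]:
        j = toks.index("SCALARS", j)
        name = toks[j + 1]
        start = toks.index("default", j) + 1
        cell_data[name] = np.array(toks[start : start + m], dtype=float)
        j = start + m
    return TaggedTetMesh(nodes=pts, tets=tets), cell_data


def write_stl(mesh: TaggedTetMesh, path, ascii_format: bool = False) -> None:
    """Export the external surface as STL via trimesh."""
    import trimesh

    faces, _ = mesh.boundary()
    surf = trimesh.Trimesh(vertices=mesh.nodes, faces=faces, process=False)
    file_type = "stl_ascii" if ascii_format else "stl"
    Path(path).write_bytes(surf.export(file_type=file_type).encode()
                           if ascii_format else surf.export(file_type=file_type))


def write_region_sidecar(mesh: TaggedTetMesh, path) -> None:
    """JSON sidecar mapping region names to node indices (+ metadata)."""
    payload = {
        "region_tags": {k: v.tolist() for k, v in mesh.region_tags.items()},
        "apodeme_direction": (
            None
            if mesh.apodeme_direction is None
            else mesh.apodeme_direction.tolist()
        ),
        "metadata": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in mesh.metadata.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_region_sidecar(mesh: TaggedTetMesh, path) -> TaggedTetMesh:
    """Attach region tags / metadata from a JSON sidecar to a bare mesh."""
    payload = json.loads(Path(path).read_text())
    mesh.region_tags = {
        k: np.asarray(v, dtype=np.int64)
        for k, v in payload["region_tags"].items()
    }
    if payload.get("apodeme_direction") is not None:
        mesh.apodeme_direction = np.asarray(payload["apodeme_direction"], float)
    mesh.metadata.update(payload.get("metadata", {}))
    return mesh
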