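"""Linear-elastic finite-element solver on tetrahedral meshes.

Static small-strain elasticity with a homogeneous isotropic material and
4-node constant-strain tetrahedra (tet4).  The solver returns nodal
displacements, reaction forces at the constrained nodes, and the
per-element von Mises stress / volume table that the Intervals Method
consumes.  Voigt order is (xx, yy, zz, xy, yz, zx) with engineering shear
strains.

Defaults follow published measurements for ant mandible cuticle:
E = 2750 MPa, nu = 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ConstraintError,
    DegenerateFieldError,
    MeshQualityError,
    ParameterError,
)
from .tetmesh import TaggedTetMesh, boundary_faces, triangle_areas


@dataclass(frozen=True)
class MaterialModel:
    """Homogeneous isotropic elastic constants (MPa / dimensionless)."""

    youngs_modulus: float = 2750.0
    poisson_ratio: float = 0.3

    def __post_init__(self):
        if not self.youngs_modulus > 0:
            raise ParameterError("youngs_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ParameterError("poisson_ratio must be in [0, 0.5)")

    @property
    def d_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix in Voigt notation (MPa)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass
class ElementStressField:
    """Per-element von Mises stress (MPa) and volume (mm^3)."""

    element_id: np.ndarray
    von_mises: np.ndarray
    volume: np.ndarray
    #: True once the stress column holds ln(MPa) (log-transformed fields
    #: may be negative)
    is_log: bool = False

    def __post_init__(self):
        self.element_id = np.asarray(self.element_id, dtype=np.int64)
        self.von_mises = np.asarray(self.von_mises, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if not (
            len(self.element_id) == len(self.von_mises) == len(self.volume)
        ):
            raise ParameterError("element_id/von_mises/volume length mismatch")
        if len(self.volume) and self.volume.min() <= 0:
            raise MeshQualityError("element volumes must be positive")
        if not self.is_log and len(self.von_mises) and self.von_mises.min() < 0:
            raise DegenerateFieldError("von Mises stress cannot be negative")

    def __len__(self) -> int:
        return len(self.element_id)

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": self.element_id,
                "von_mises_MPa": self.von_mises,
                "volume_mm3": self.volume,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElementStressField":
        return cls(
            element_id=df["element_id"].to_numpy(),
            von_mises=df["von_mises_MPa"].to_numpy(),
            volume=df["volume_mm3"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "ElementStressField":
        # round_trip parsing keeps write -> read -> write byte-stable
        return cls.from_frame(
            pd.read_csv(Path(path), float_precision="round_trip")
        )


@dataclass
class SolveResult:
    """Solution of one load case."""

    displacements: np.ndarray          # (n_nodes, 3), mm
    stress_field: ElementStressField
    reaction_forces: np.ndarray        # (n_fixed, 3), N
    fixed_nodes: np.ndarray
    stress_tensors: np.ndarray = field(repr=False, default=None)  # (m, 6) MPa

    @property
    def equilibrium_residual(self) -> float:
        """|sum reactions + sum applied loads| / |sum applied loads|."""
        return self._residual

    _residual: float = field(default=np.nan, repr=False)


def von_mises(stress_tensor: np.ndarray) -> float | np.ndarray:
    """Von Mises equivalent stress of symmetric 3x3 tensor(s).

    sigma_vm = sqrt(0.5[(s11-s22)^2 + (s22-s33)^2 + (s33-s11)^2]
                    + 3(s12^2 + s23^2 + s31^2))
    """
    t = np.asarray(stress_tensor, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ParameterError("stress tensor must be 3x3")
    if not np.allclose(t, np.swapaxes(t, -1, -2), rtol=1e-8, atol=1e-10):
        raise ParameterError("stress tensor must be symmetric")
    s11, s22, s33 = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
    s12, s23, s31 = t[..., 0, 1], t[..., 1, 2], t[..., 2, 0]
    out = np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )
    return float(out) if out.ndim == 0 else out


def _von_mises_voigt(sig: np.ndarray) -> np.ndarray:
    s11, s22, s33, s12, s23, s31 = sig.T
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )


def element_matrices(
    nodes: np.ndarray, tets: np.ndarray, material: MaterialModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized tet4 B matrices, volumes and stiffness matrices.

    Returns (B, V, K) with shapes (m, 6, 12), (m,), (m, 12, 12).
    """
    edges = nodes[tets[:, 1:]] - nodes[tets[:, :1]]  # (m, 3, 3) rows=edges
    detJ = np.linalg.det(edges)
    V = detJ / 6.0
    if (V <= 0).any():
        raise MeshQualityError(
            "non-positive element volumes",
            element_ids=np.flatnonzero(V <= 0),
        )
    invJ = np.linalg.inv(edges)  # (m, 3, 3)
    m = len(tets)
    # shape-function gradients: rows of invJ^T give grad N_1..N_3;
    # grad N_0 = -(grad N_1 + grad N_2 + grad N_3)
    g = np.empty((m, 4, 3))
    g[:, 1:, :] = np.swapaxes(invJ, 1, 2)
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    D = material.d_matrix
    DB = np.einsum("ij,mjk->mik", D, B)
    K = np.einsum("mji,mjk,m->mik", B, DB, V)
    return B, V, K


def assemble_stiffness(
    mesh: TaggedTetMesh, material: MaterialModel
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Global sparse stiffness matrix plus element B matrices and volumes."""
    B, V, Ke = element_matrices(mesh.nodes, mesh.tets, material)
    m = mesh.n_tets
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        m, 12
    )
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()
    return K, B, V


def nodal_loads(
    mesh: TaggedTetMesh,
    node_set: np.ndarray,
    direction: np.ndarray,
    magnitude: float,
) -> np.ndarray:
    """Distribute a total force over a surface node set.

    Nodal weights are tributary areas of the loaded surface patch (one third
    of each boundary triangle whose three corners all lie in the set) —
    consistent loads for a uniform traction.  If the set spans no complete
    boundary triangle the load is split equally between its nodes.
    """
    node_set = np.asarray(node_set, dtype=np.int64)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    faces, _ = boundary_faces(mesh.tets)
    inset = np.isin(faces, node_set).all(axis=1)
    weights = np.zeros(mesh.n_nodes)
    if inset.any():
        areas = triangle_areas(mesh.nodes, faces[inset])
        np.add.at(weights, faces[inset].ravel(), np.repeat(areas / 3.0, 3))
    else:
        weights[node_set] = 1.0
    weights = weights / weights.sum()
    f = np.zeros((mesh.n_nodes, 3))
    f += weights[:, None] * direction[None, :] * magnitude
    return f


def assemble_and_solve(
    mesh: TaggedTetMesh,
    material: MaterialModel,
    scenario,
) -> SolveResult:
    """Solve one biting load case (static linear elasticity).

    ``scenario`` is a :class:`mandibite.scenarios.BCScenario` or anything
    exposing ``fixed_nodes(mesh)`` and ``load_vector(mesh)``.
    """
    fixed_nodes = np.unique(np.asarray(scenario.fixed_nodes(mesh), np.int64))
    if fixed_nodes.size and (
        fixed_nodes.min() < 0 or fixed_nodes.max() >= mesh.n_nodes
    ):
        raise ConstraintError("fixed node set references invalid mesh nodes")
    f = scenario.load_vector(mesh)
    return solve_displacement(mesh, material, fixed_nodes, f)


def solve_displacement(
    mesh: TaggedTetMesh,
    material: MaterialModel,
    fixed_nodes: np.ndarray,
    loads: np.ndarray,
    fixed_components: np.ndarray | None = None,
) -> SolveResult:
    """Core solve with zero-displacement constraints.

    ``fixed_components`` optionally restricts which of the 3 displacement
    components are constrained per fixed node (defaults to all three).
    """
    K, B, V = assemble_stiffness(mesh, material)
    n_dof = 3 * mesh.n_nodes
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
    if fixed_components is None:
        fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    else:
        fixed_dofs = np.asarray(fixed_components, dtype=np.int64)
    free = np.setdiff1d(np.arange(n_dof), fixed_dofs)
    if free.size == n_dof:
        raise ConstraintError("no constraints: rigid-body modes present")
    fvec = np.asarray(loads, dtype=float).ravel()

    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as exc:  # pragma: no cover - scipy raises on singular
        raise ConstraintError(
            f"singular stiffness system (insufficient constraints?): {exc}"
        ) from exc
    u = np.zeros(n_dof)
    u[free] = lu.solve(fvec[free])
    if not np.all(np.isfinite(u)):
        raise ConstraintError("singular stiffness system: non-finite solution")
    # residual on the free equations flags near-singular factorizations
    res = np.linalg.norm(Kff @ u[free] - fvec[free])
    scale = np.linalg.norm(fvec[free])
    if scale > 0 and res / scale > 1e-6:
        raise ConstraintError(
            "stiffness system nearly singular: relative residual "
            f"{res / scale:.2e} (insufficient constraints?)"
        )

    # element stresses (constant per element)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(len(mesh.tets), 12)
    strains = np.einsum("mij,mj->mi", B, ue)
    sig = strains @ material.d_matrix.T
    svm = _von_mises_voigt(sig)

    reactions_full = (K @ u - fvec).reshape(-1, 3)
    reactions = reactions_full[fixed_nodes]
    total_load = fvec.reshape(-1, 3).sum(axis=0)
    resid = np.linalg.norm(reactions.sum(axis=0) + total_load)
    denom = np.linalg.norm(total_load)
    field = ElementStressField(
        element_id=np.arange(len(mesh.tets)), von_mises=svm, volume=V
    )
    out = SolveResult(
        displacements=u.reshape(-1, 3),
        stress_field=field,
        reaction_forces=reactions,
        fixed_nodes=fixed_nodes,
        stress_tensors=sig,
    )
    out._residual = float(resid / denom) if denom > 0 else float(resid)
    return out
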