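"""Mesh-density convergence checks.

Mirrors the standard practice of probing von Mises stress at a handful of
anatomical regions over a refinement ladder and accepting the coarsest
density whose probe stresses change by less than a tolerance (default 5%)
relative to the next-finer density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import NonConvergenceError, ParameterError
from .fem import MaterialModel, assemble_and_solve
from .morphology import MorphotypeParams, generate_mandible
from .scenarios import build_scenario
from .tetmesh import TaggedTetMesh

DEFAULT_PROBES = (
    "masticatory_margin",
    "apical_tooth",
    "apodeme_insertion",
    "articulation_dorsal",
)


@dataclass
class ConvergenceReport:
    """Outcome of a refinement-ladder study."""

    ladder: list[float]                 # densities, coarse -> fine
    probe_names: list[str]
    probe_stresses: np.ndarray          # (levels, probes), MPa
    relative_errors: np.ndarray         # (levels-1, probes) vs next finer
    tolerance: float
    chosen_density: float | None = None
    converged: bool = False
    extras: dict = field(default_factory=dict)


def probe_stress(
    mesh: TaggedTetMesh, field_values: np.ndarray, region: str,
    n_elements: int = 6,
) -> float:
    """Mean von Mises stress of up to ``n_elements`` elements nearest the
    centroid of an anatomical region (elements must touch the region)."""
    if region not in mesh.region_tags:
        raise ParameterError(f"mesh lacks region tag {region!r}")
    nodes = mesh.region_tags[region]
    touching = np.flatnonzero(np.isin(mesh.tets, nodes).any(axis=1))
    if touching.size == 0:
        raise ParameterError(f"no elements touch region {region!r}")
    target = mesh.nodes[nodes].mean(axis=0)
    cent = mesh.nodes[mesh.tets[touching]].mean(axis=1)
    order = np.argsort(np.linalg.norm(cent - target, axis=1))
    pick = touching[order[:n_elements]]
    return float(field_values[pick].mean())


def ladder_convergence(
    solve_at: Callable[[float], tuple[TaggedTetMesh, np.ndarray]],
    ladder: Sequence[float],
    probes: Sequence[str],
    tolerance: float = 0.05,
) -> ConvergenceReport:
    """Generic ladder driver: returns the coarsest converged density.

    ``solve_at(density)`` must return (mesh, per-element von Mises array).
    Densities must be ordered coarse to fine.  Raises
    :class:`NonConvergenceError` (with the full per-probe trace attached)
    when no level converges.
    """
    if len(ladder) < 2:
        raise ParameterError("refinement ladder needs at least 2 levels")
    if not (3 <= len(probes) <= 6):
        raise ParameterError("use between 3 and 6 probe regions")
    stresses = []
    for dens in ladder:
        mesh, svm = solve_at(dens)
        stresses.append([probe_stress(mesh, svm, r) for r in probes])
    stresses = np.asarray(stresses)
    finer = stresses[1:]
    # relative to the next-finer probe value; probes that are identically
    # zero on both levels (elements fully inside a fixed region) count as
    # converged rather than 0/0
    scale = np.maximum(np.abs(finer), 1e-12 * max(np.abs(stresses).max(), 1e-300))
    errors = np.abs(stresses[:-1] - finer) / scale
    report = ConvergenceReport(
        ladder=list(ladder),
        probe_names=list(probes),
        probe_stresses=stresses,
        relative_errors=errors,
        tolerance=tolerance,
    )
    for i in range(len(ladder) - 1):
        if np.all(errors[i] < tolerance):
            report.chosen_density = ladder[i]
            report.converged = True
            return report
    raise NonConvergenceError(
        f"no density in the ladder {list(ladder)} converged below "
        f"tolerance {tolerance}",
        trace=report,
    )


def mesh_convergence_check(
    generator_params: MorphotypeParams,
    scenario: str,
    probes: Sequence[str] = DEFAULT_PROBES,
    tolerance: float = 0.05,
    ladder: Sequence[float] | None = None,
    material: MaterialModel | None = None,
    load_magnitude: float = 1.0,
) -> ConvergenceReport:
    """Pick a mesh density for one morphotype under one biting scenario.

    ``ladder`` lists voxel sizes from coarse to fine (default: 1.6x, 1.25x
    and 1.0x the generator's default voxel size).  The emulated simulation
    setup uses the same boundary conditions as the full study.
    """
    material = material or MaterialModel()
    if ladder is None:
        from .morphology import _default_voxel_size

        h0 = generator_params.voxel_size or _default_voxel_size(
            generator_params
        )
        ladder = [1.6 * h0, 1.25 * h0, h0]
    else:
        if any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise ParameterError(
                "ladder voxel sizes must strictly decrease (coarse to fine)"
            )

    from dataclasses import replace

    def solve_at(voxel_size: float):
        params = replace(generator_params, voxel_size=voxel_size)
        mesh = generate_mandible(params)
        bc = build_scenario(mesh, scenario, load_magnitude)
        res = assemble_and_solve(mesh, material, bc)
        return mesh, res.stress_field.von_mises

    return ladder_convergence(solve_at, list(ladder), list(probes), tolerance)
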