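"""End-to-end comparative study orchestration.

``run_study`` takes a :class:`RunConfig` (usually loaded from YAML),
generates or loads the specimen meshes, normalizes loads by surface area,
solves every requested biting scenario, applies the Intervals Method per
scenario, and writes meshes, stress tables, normalized fields, interval
tables, PCA outputs, a convergence report, plots and a run log to the
output directory.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import ConfigurationError, ScenarioExclusionError
from .fem import ElementStressField, MaterialModel, assemble_and_solve
from .intervals import (
    ConvergenceResult,
    IntervalConfig,
    pca_profiles,
    scenario_profiles,
    select_interval_count,
)
from .morphology import MORPHOTYPES, MorphotypeParams, generate_mandible
from .scenarios import (
    SCENARIOS,
    build_scenario,
    normalize_loads,
    normalize_stress_field,
    write_specimen_table,
)
from .tetmesh import (
    TaggedTetMesh,
    mesh_volume,
    read_region_sidecar,
    read_vtk,
    surface_area,
    write_region_sidecar,
    write_stl,
    write_vtk,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration schema (YAML-friendly pydantic models)


class SpecimenSpec(BaseModel):
    """One specimen: either generated from a morphotype or loaded from disk."""

    specimen_id: str
    morphotype: str | None = None
    mesh_path: str | None = None
    scale: float = 1.0
    voxel_size: float | None = None
    apical_capable: bool | None = None
    overrides: dict = Field(default_factory=dict)

    @field_validator("morphotype")
    @classmethod
    def _known_morphotype(cls, v):
        if v is not None and v not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {v!r}")
        return v

    def model_post_init(self, _ctx):
        if (self.morphotype is None) == (self.mesh_path is None):
            raise ValueError(
                "specimen needs exactly one of morphotype or mesh_path"
            )


class MaterialSpec(BaseModel):
    youngs_modulus_MPa: float = 2750.0
    poisson_ratio: float = 0.3


class IntervalSpec(BaseModel):
    trim_fraction: float = 0.02
    tail_fraction: float = 0.15
    n_intervals: int = 15
    candidate_counts: list[int] = [5, 10, 15, 25, 50]
    log_transform: bool = True
    convergence_epsilon: float = 0.01

    def to_config(self) -> IntervalConfig:
        return IntervalConfig(
            trim_fraction=self.trim_fraction,
            tail_fraction=self.tail_fraction,
            n_intervals=self.n_intervals,
            candidate_counts=tuple(self.candidate_counts),
            log_transform=self.log_transform,
            convergence_epsilon=self.convergence_epsilon,
        )


class RunConfig(BaseModel):
    """Validated study configuration."""

    specimens: list[SpecimenSpec]
    material: MaterialSpec = MaterialSpec()
    scenarios: list[str] = list(SCENARIOS)
    intervals: IntervalSpec = IntervalSpec()
    reference_specimen: str | None = None
    strike_direction_mode: str = "global"
    seed: int = 0
    output_dir: str = "mandibite_out"
    select_intervals: bool = True
    write_plots: bool = True

    @field_validator("specimens")
    @classmethod
    def _nonempty_specimens(cls, v):
        if not v:
            raise ValueError("at least one specimen is required")
        return v

    @field_validator("scenarios")
    @classmethod
    def _known_scenarios(cls, v):
        if not v:
            raise ValueError("at least one scenario is required")
        for s in v:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _specimen_seed(base_seed: int, index: int) -> int:
    return (base_seed * 10007 + 31 * index + 1) % (2**31)


def build_specimen(spec: SpecimenSpec, base_seed: int, index: int) -> TaggedTetMesh:
    """Generate (or load) one specimen mesh according to its spec."""
    if spec.mesh_path is not None:
        mesh, _ = read_vtk(spec.mesh_path)
        sidecar = Path(spec.mesh_path).with_suffix(".regions.json")
        if sidecar.exists():
            read_region_sidecar(mesh, sidecar)
        mesh.validate()
    else:
        params = MorphotypeParams.preset(
            spec.morphotype,
            seed=_specimen_seed(base_seed, index),
            scale=spec.scale,
            **(
                {"voxel_size": spec.voxel_size} if spec.voxel_size else {}
            ),
            **spec.overrides,
        )
        mesh = generate_mandible(params)
    if spec.apical_capable is not None:
        mesh.metadata["apical_capable"] = spec.apical_capable
    mesh.metadata["specimen_id"] = spec.specimen_id
    return mesh


# ---------------------------------------------------------------------------
# plots


def plot_pca(pca_result, path, scenario: str = "") -> None:
    """PC1/PC2 biplot: specimen scores plus interval-loading arrows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = pca_result.scores
    ax.scatter(sc["PC1"], sc["PC2"], s=30, zorder=3)
    for sid, row in sc.iterrows():
        ax.annotate(str(sid), (row["PC1"], row["PC2"]), fontsize=7)
    scale = 0.8 * max(sc["PC1"].abs().max(), sc["PC2"].abs().max())
    for name, row in pca_result.loadings.iterrows():
        ax.arrow(0, 0, scale * row["PC1"], scale * row["PC2"],
                 color="tab:red", alpha=0.4, head_width=0.02 * scale)
        ax.annotate(name.replace("interval_", ""),
                    (scale * row["PC1"], scale * row["PC2"]),
                    color="tab:red", fontsize=6)
    ve = pca_result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)" if len(ve) > 1 else "PC2")
    ax.set_title(scenario)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_colormap(mesh: TaggedTetMesh, values: np.ndarray, path,
                  title: str = "") -> None:
    """Poor-man's color map: element centroids colored by normalized stress."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cent = mesh.nodes[mesh.tets].mean(axis=1)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    p = ax.scatter(cent[:, 0], cent[:, 1], cent[:, 2], c=values, s=4,
                   cmap="turbo")
    fig.colorbar(p, ax=ax, label="normalized von Mises stress")
    ax.set_title(title)
    ax.set_box_aspect(np.ptp(cent, axis=0) + 1e-9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# the study driver


def run_study(config: RunConfig) -> pd.DataFrame:
    """Run the full comparative pipeline; returns the study table."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mandibite")
    root.addHandler(handler)
    old_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        logger.info(
            "mandibite %s | seed=%d | config=%s",
            __version__, config.seed, config.digest(),
        )
        (out / "config.yaml").write_text(config.to_yaml())
        return _run_study_inner(config, out, t0)
    finally:
        root.setLevel(old_level)
        root.removeHandler(handler)
        handler.close()


def _run_study_inner(config: RunConfig, out: Path, t0: float) -> pd.DataFrame:
    material = MaterialModel(
        youngs_modulus=config.material.youngs_modulus_MPa,
        poisson_ratio=config.material.poisson_ratio,
    )
    iconf = config.intervals.to_config()

    meshdir = out / "meshes"
    meshdir.mkdir(exist_ok=True)
    meshes: dict[str, TaggedTetMesh] = {}
    for i, spec in enumerate(config.specimens):
        mesh = build_specimen(spec, config.seed, i)
        meshes[spec.specimen_id] = mesh
        write_vtk(mesh, meshdir / f"{spec.specimen_id}.vtk")
        write_region_sidecar(mesh, meshdir / f"{spec.specimen_id}.regions.json")
        write_stl(mesh, meshdir / f"{spec.specimen_id}.stl")
        logger.info("specimen %s: %d tets", spec.specimen_id, mesh.n_tets)

    records = normalize_loads(
        [(sid, surface_area(m)) for sid, m in meshes.items()]
    )
    loads = {r.specimen_id: r.applied_load for r in records}
    write_specimen_table(records, out / "specimen_table.csv")
    reference = config.reference_specimen or max(
        records, key=lambda r: r.surface_area
    ).specimen_id
    if reference not in meshes:
        raise ConfigurationError(
            f"reference specimen {reference!r} is not in the study"
        )

    fields: dict[str, dict[str, ElementStressField]] = {}
    rows = []
    stressdir = out / "stress"
    stressdir.mkdir(exist_ok=True)
    for scen in config.scenarios:
        fields[scen] = {}
        for sid, mesh in meshes.items():
            try:
                bc = build_scenario(
                    mesh, scen, loads[sid], config.strike_direction_mode
                )
            except ScenarioExclusionError:
                logger.info("skipping %s/%s (apical-incapable)", sid, scen)
                continue
            result = assemble_and_solve(mesh, material, bc)
            field = result.stress_field
            fields[scen][sid] = field
            field.to_csv(stressdir / f"{sid}__{scen}.csv")
            rows.append(
                {
                    "specimen_id": sid,
                    "scenario": scen,
                    "applied_load_N": loads[sid],
                    "n_elements": len(field),
                    "total_volume_mm3": field.total_volume,
                    "max_von_mises_MPa": float(field.von_mises.max()),
                    "mean_von_mises_MPa": float(
                        np.average(field.von_mises, weights=field.volume)
                    ),
                    "equilibrium_residual": result.equilibrium_residual,
                }
            )
            logger.info(
                "solved %s/%s: residual %.2e", sid, scen,
                result.equilibrium_residual,
            )

    # normalized color-map fields relative to the reference model
    normdir = out / "normalized"
    normdir.mkdir(exist_ok=True)
    for scen, per_spec in fields.items():
        ref_field = per_spec.get(reference)
        if ref_field is None:
            logger.warning(
                "reference %s missing in %s; skipping normalization",
                reference, scen,
            )
            continue
        for sid, f in per_spec.items():
            normalized = normalize_stress_field(f, ref_field)
            pd.DataFrame(
                {"element_id": f.element_id, "normalized_stress": normalized}
            ).to_csv(normdir / f"{sid}__{scen}.csv", index=False)
            write_vtk(
                meshes[sid],
                normdir / f"{sid}__{scen}.vtk",
                cell_data={"normalized_von_mises": normalized},
            )
        if config.write_plots:
            ref_norm = normalize_stress_field(ref_field, ref_field)
            plot_colormap(
                meshes[reference], ref_norm,
                normdir / f"reference_{reference}__{scen}.png",
                title=f"{reference} / {scen}",
            )

    # intervals method per scenario
    intdir = out / "intervals"
    intdir.mkdir(exist_ok=True)
    table_rows = []
    convergences: dict[str, ConvergenceResult] = {}
    for scen, per_spec in fields.items():
        if not per_spec:
            continue
        profiles, layout = scenario_profiles(per_spec, iconf, scen)
        profiles.to_csv(intdir / f"intervals_{scen}.csv")
        (intdir / f"layout_{scen}.json").write_text(json.dumps(layout, indent=1))
        for row in rows:
            if row["scenario"] == scen:
                fr = profiles.loc[row["specimen_id"]]
                row.update({c: float(fr[c]) for c in profiles.columns})
        if len(per_spec) >= 3:
            pca = pca_profiles(profiles)
            pca.scores.to_csv(intdir / f"pca_scores_{scen}.csv")
            pca.loadings.to_csv(intdir / f"pca_loadings_{scen}.csv")
            pd.DataFrame(
                {
                    "component": [
                        f"PC{i + 1}"
                        for i in range(len(pca.variance_explained))
                    ],
                    "variance_explained_pct": pca.variance_explained,
                }
            ).to_csv(intdir / f"pca_variance_{scen}.csv", index=False)
            if config.write_plots:
                plot_pca(pca, intdir / f"pca_{scen}.png", scen)
            if config.select_intervals:
                conv = select_interval_count(per_spec, iconf, scen)
                convergences[scen] = conv
                logger.info(
                    "%s: chosen interval count %d (converged=%s)",
                    scen, conv.chosen_k, conv.converged,
                )
        else:
            logger.warning(
                "%s: only %d specimens solved; skipping PCA", scen,
                len(per_spec),
            )
    if convergences:
        (intdir / "convergence.json").write_text(
            json.dumps(
                {s: json.loads(c.to_json()) for s, c in convergences.items()},
                indent=1,
            )
        )

    table = pd.DataFrame(rows)
    table.to_csv(out / "study_table.csv", index=False)
    logger.info("study finished in %.1f s (%d rows)", time.time() - t0, len(table))
    return table


# ---------------------------------------------------------------------------
# fixtures


def fixture_study_config(seed: int = 0, output_dir: str = "fixture_out",
                         **kwargs) -> RunConfig:
    """The packaged small study: 3 morphotypes × 2 sizes, all scenarios.

    Meshes stay under ~5k tets each so the full pipeline runs in minutes on
    one CPU; trap-jaw specimens are flagged apical-incapable, mirroring how
    specialized strikers cannot engage the apical tooth alone.
    """
    specimens = []
    for morph, vox in (("shovel", None), ("robust_major", None),
                       ("trapjaw", 0.034)):
        for scale, tag in ((1.0, "large"), (0.75, "small")):
            specimens.append(
                SpecimenSpec(
                    specimen_id=f"{morph}_{tag}",
                    morphotype=morph,
                    scale=scale,
                    voxel_size=None if vox is None else vox * scale,
                )
            )
    return RunConfig(
        specimens=specimens,
        scenarios=list(SCENARIOS),
        seed=seed,
        output_dir=output_dir,
        **kwargs,
    )


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Small packaged meshes + toy stress tables for tests and demos.

    One specimen per morphotype (≤ 5k elements each), written as
    VTK + STL + region sidecar, plus a solved strike stress table for the
    shovel specimen and a 10-element toy stress CSV.  Runs in well under a
    minute on one CPU.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = {}
    vox = {"trapjaw": 0.034, "falcate": 0.028}
    for i, morph in enumerate(MORPHOTYPES):
        params = MorphotypeParams.preset(
            morph, seed=_specimen_seed(seed, i), voxel_size=vox.get(morph)
        )
        mesh = generate_mandible(params)
        mesh.validate()
        write_vtk(mesh, out / f"{morph}.vtk")
        write_region_sidecar(mesh, out / f"{morph}.regions.json")
        write_stl(mesh, out / f"{morph}.stl")
        made[morph] = mesh
    shovel = made["shovel"]
    bc = build_scenario(shovel, "strike_margin", 1.0)
    res = assemble_and_solve(shovel, MaterialModel(), bc)
    res.stress_field.to_csv(out / "shovel__strike_margin.csv")
    rng = np.random.default_rng(seed)
    toy = ElementStressField(
        element_id=np.arange(10),
        von_mises=rng.lognormal(0.0, 1.0, 10),
        volume=rng.uniform(0.5, 1.5, 10),
    )
    toy.to_csv(out / "toy_stress.csv")
    return made
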