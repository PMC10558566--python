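"""Biting load cases, load normalization, and comparative stress scaling.

Four bite scenarios are modelled, combining the two bite phases with the
part of the masticatory margin engaged:

* ``strike_margin`` / ``strike_apical`` — first bite phase: the mandible
  hits an object.  The bite contact (full margin or apical tooth only)
  carries the load; the two head articulations are fixed in all
  directions.
* ``pressure_margin`` / ``pressure_apical`` — second bite phase: crushing
  or gripping.  The closer-muscle load enters at the apodeme insertion
  along the muscle's line of action; the articulations *and* the bite
  contact are fixed.

Comparative loading follows the surface-area rule: the largest specimen
receives the 1 N reference load and every other specimen receives
``SA_i / SA_max`` N, so stress levels are comparable across sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFieldError,
    ParameterError,
    ScenarioExclusionError,
)
from .fem import ElementStressField, nodal_loads
from .intervals import weighted_quantile
from .tetmesh import TaggedTetMesh, boundary_faces, triangle_areas

SCENARIOS = (
    "strike_margin",
    "pressure_margin",
    "strike_apical",
    "pressure_apical",
)

_CONTACT = {
    "strike_margin": "masticatory_margin",
    "pressure_margin": "masticatory_margin",
    "strike_apical": "apical_tooth",
    "pressure_apical": "apical_tooth",
}

REFERENCE_LOAD_N = 1.0


@dataclass(frozen=True)
class BCScenario:
    """One biting boundary-condition case on a tagged mesh."""

    scenario: str
    fixed_sets: tuple[str, ...]
    loaded_set: str
    load_direction: tuple[float, float, float]
    load_magnitude: float

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.load_magnitude <= 0:
            raise ParameterError("load_magnitude must be positive")
        arts = {"articulation_dorsal", "articulation_ventral"}
        if self.scenario.startswith("strike"):
            if set(self.fixed_sets) != arts:
                raise ParameterError(
                    "strike scenarios fix exactly the two articulations"
                )
        else:
            if set(self.fixed_sets) != arts | {_CONTACT[self.scenario]}:
                raise ParameterError(
                    "pressure scenarios fix the articulations plus the "
                    "bite contact"
                )
        if self.loaded_set in self.fixed_sets:
            raise ParameterError("loaded_set must be disjoint from fixed_sets")
        n = np.linalg.norm(self.load_direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ParameterError("load_direction must be a unit vector")

    # -- hooks used by the FE solver -------------------------------------
    def fixed_nodes(self, mesh: TaggedTetMesh) -> np.ndarray:
        sets = []
        for name in self.fixed_sets:
            if name not in mesh.region_tags:
                raise ConfigurationError(f"mesh lacks region tag {name!r}")
            sets.append(mesh.region_tags[name])
        return np.unique(np.concatenate(sets))

    def load_vector(self, mesh: TaggedTetMesh) -> np.ndarray:
        if self.loaded_set not in mesh.region_tags:
            raise ConfigurationError(f"mesh lacks region tag {self.loaded_set!r}")
        return nodal_loads(
            mesh,
            mesh.region_tags[self.loaded_set],
            np.asarray(self.load_direction),
            self.load_magnitude,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "fixed_sets": list(self.fixed_sets),
                "loaded_set": self.loaded_set,
                "load_direction": list(self.load_direction),
                "load_magnitude": self.load_magnitude,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BCScenario":
        d = json.loads(text)
        return cls(
            scenario=d["scenario"],
            fixed_sets=tuple(d["fixed_sets"]),
            loaded_set=d["loaded_set"],
            load_direction=tuple(d["load_direction"]),
            load_magnitude=d["load_magnitude"],
        )


def _patch_mean_inward_normal(mesh: TaggedTetMesh, node_set) -> np.ndarray:
    faces, _ = mesh.boundary()
    inset = np.isin(faces, node_set).all(axis=1)
    if not inset.any():
        raise ConfigurationError(
            "loaded patch spans no complete boundary triangle; cannot derive "
            "a surface normal"
        )
    tri = mesh.nodes[faces[inset]]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).sum(axis=0)
    return -n / np.linalg.norm(n)


def build_scenario(
    mesh: TaggedTetMesh,
    scenario: str,
    load_magnitude: float,
    strike_direction_mode: str = "global",
) -> BCScenario:
    """Construct the boundary conditions of one bite scenario for a mesh.

    ``strike_direction_mode`` selects how the strike load direction is set:
    ``"global"`` uses the mesh's bite-closure direction (perpendicular to
    the articulation axis, stored by the generator), ``"surface_normal"``
    uses the mean inward normal of the bite-contact patch.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}")
    contact = _CONTACT[scenario]
    if scenario.endswith("apical") and not mesh.metadata.get(
        "apical_capable", True
    ):
        raise ScenarioExclusionError(
            "apical-tooth scenarios are excluded for this specimen "
            "(flagged apical-incapable: independent use of the apical tooth "
            "is improbable for this morphology)"
        )
    for name in ("articulation_dorsal", "articulation_ventral", contact):
        if name not in mesh.region_tags or len(mesh.region_tags[name]) == 0:
            raise ConfigurationError(f"mesh lacks region tag {name!r}")
    arts = ("articulation_dorsal", "articulation_ventral")
    if scenario.startswith("strike"):
        if strike_direction_mode == "global":
            direction = np.asarray(
                mesh.metadata.get("strike_direction", (0.0, -1.0, 0.0)), float
            )
        elif strike_direction_mode == "surface_normal":
            direction = _patch_mean_inward_normal(
                mesh, mesh.region_tags[contact]
            )
        else:
            raise ParameterError(
                "strike_direction_mode must be 'global' or 'surface_normal'"
            )
        return BCScenario(
            scenario=scenario,
            fixed_sets=arts,
            loaded_set=contact,
            load_direction=tuple(direction / np.linalg.norm(direction)),
            load_magnitude=load_magnitude,
        )
    if "apodeme_insertion" not in mesh.region_tags:
        raise ConfigurationError("mesh lacks region tag 'apodeme_insertion'")
    direction = np.asarray(mesh.apodeme_direction, dtype=float)
    return BCScenario(
        scenario=scenario,
        fixed_sets=arts + (contact,),
        loaded_set="apodeme_insertion",
        load_direction=tuple(direction / np.linalg.norm(direction)),
        load_magnitude=load_magnitude,
    )


# ---------------------------------------------------------------------------
# load normalization by surface area


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen row of the comparative study table."""

    specimen_id: str
    surface_area: float       # mm^2
    applied_load: float       # N, full precision
    feeding_habit: str = ""
    worker_type: str = ""

    @property
    def applied_load_rounded(self) -> float:
        """Load rounded half-up to 4 decimals, as reported in print."""
        return float(
            Decimal(repr(self.applied_load)).quantize(
                Decimal("0.0001"), rounding=ROUND_HALF_UP
            )
        )


def normalize_loads(surface_areas) -> list[SpecimenRecord]:
    """Surface-area load normalization.

    The specimen with the largest surface area receives the 1 N reference
    load; every other specimen i receives ``SA_i / SA_max`` N.  Accepts an
    iterable of ``(specimen_id, surface_area)`` pairs or a DataFrame with
    ``species``/``specimen_id`` and ``surface_area_mm2`` columns.
    """
    if isinstance(surface_areas, pd.DataFrame):
        df = surface_areas
        idcol = "specimen_id" if "specimen_id" in df else "species"
        wt = df["worker_type"] if "worker_type" in df else [""] * len(df)
        fh = df["feeding_habit"] if "feeding_habit" in df else [""] * len(df)
        items = list(
            zip(df[idcol], df["surface_area_mm2"], wt, fh)
        )
    else:
        items = [(sid, sa, "", "") for sid, sa in surface_areas]
    if not items:
        raise ParameterError("surface_areas must be non-empty")
    areas = np.array([it[1] for it in items], dtype=float)
    if not np.all(np.isfinite(areas)) or areas.min() <= 0:
        raise ParameterError("surface_area values must be positive and finite")
    sa_max = areas.max()
    return [
        SpecimenRecord(
            specimen_id=str(sid),
            surface_area=float(sa),
            applied_load=float(sa / sa_max) * REFERENCE_LOAD_N,
            worker_type=str(wt),
            feeding_habit=str(fh),
        )
        for (sid, sa, wt, fh) in items
    ]


def _clean_decimal(x) -> float:
    """Normalize printed European/typo-laden decimals ('2,13', "2'.1324")."""
    if isinstance(x, (int, float)):
        return float(x)
    s = "".join(ch for ch in str(x) if ch.isdigit() or ch in ".,-")
    if "," in s and "." not in s:
        s = s.replace(",", ".")
    else:
        s = s.replace(",", "")
    return float(s)


def read_specimen_table(path=None) -> pd.DataFrame:
    """Read a specimen table CSV (defaults to the packaged ant table).

    The packaged table lists the 28 mandibles (25 ant species; three species
    contribute a second worker type) with the printed surface areas and
    applied loads of the source study.
    """
    if path is None:
        with resources.files("mandibite").joinpath(
            "data/ant_specimens.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(Path(path))
    for col in ("surface_area_mm2", "applied_load_N"):
        if col in df:
            df[col] = df[col].map(_clean_decimal)
    if "apical_capable" in df:
        df["apical_capable"] = df["apical_capable"].astype(bool)
    return df


def write_specimen_table(records: list[SpecimenRecord], path) -> None:
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "worker_type": [r.worker_type for r in records],
            "surface_area_mm2": [r.surface_area for r in records],
            "applied_load_N": [r.applied_load_rounded for r in records],
            "feeding_habit": [r.feeding_habit for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reference-model stress normalization (comparative color maps)


def normalize_stress_field(
    field: ElementStressField,
    reference: ElementStressField,
    statistic: str | float = 0.98,
) -> np.ndarray:
    """Per-element dimensionless stress relative to a reference model.

    ``statistic`` picks the reference scale: a quantile in (0, 1] of the
    reference model's volume-weighted von Mises distribution (default the
    robust 98th percentile, insensitive to artifact peaks), or ``"max"``.
    With ``"max"`` a model normalized against itself peaks at exactly 1.
    """
    if len(reference) == 0:
        raise DegenerateFieldError("reference stress field is empty")
    if statistic == "max":
        scale = float(reference.von_mises.max())
    else:
        q = float(statistic)
        if not (0 < q <= 1):
            raise ParameterError("quantile statistic must be in (0, 1]")
        scale = float(
            weighted_quantile(reference.von_mises, reference.volume, q)
        )
    if scale <= 0:
        raise DegenerateFieldError("reference scale statistic is zero")
    return field.von_mises / scale
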