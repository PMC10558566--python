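"""Bite scenarios, load normalization, and reference-model stress scaling."""

import numpy as np
import pytest

from conftest import tagged_bar_mesh
from mandibite.errors import (
    ConfigurationError,
    DegenerateFieldError,
    ParameterError,
    ScenarioExclusionError,
)
from mandibite.fem import ElementStressField
from mandibite.morphology import MorphotypeParams, generate_mandible
from mandibite.scenarios import (
    BCScenario,
    build_scenario,
    normalize_loads,
    normalize_stress_field,
    read_specimen_table,
)


class TestNormalizeLoads:
    def test_printed_pair(self):
        # largest vs leaf-cutter specimen of the reference table
        recs = normalize_loads([("major", 3.382100), ("leafcutter", 0.777902)])
        assert recs[0].applied_load_rounded == 1.0000
        assert recs[1].applied_load_rounded == 0.2300

    def test_single_specimen_gets_reference_load(self):
        (rec,) = normalize_loads([("only", 0.123)])
        assert rec.applied_load == 1.0

    def test_linear_ratio(self):
        recs = normalize_loads([("a", 2.0), ("b", 1.0), ("c", 0.5)])
        assert [r.applied_load for r in recs] == [1.0, 0.5, 0.25]

    def test_validation(self):
        with pytest.raises(ParameterError):
            normalize_loads([])
        with pytest.raises(ParameterError):
            normalize_loads([("a", -1.0)])

    def test_monotone_in_surface_area(self):
        rng = np.random.default_rng(1)
        areas = np.sort(rng.uniform(0.01, 4.0, 30))
        recs = normalize_loads([(str(i), a) for i, a in enumerate(areas)])
        loads = np.array([r.applied_load for r in recs])
        assert (np.diff(loads) > 0).all()
        assert loads.max() == 1.0

    def test_packaged_table_roundtrip(self):
        df = read_specimen_table()
        assert len(df) == 28
        assert df["surface_area_mm2"].max() == pytest.approx(3.3821)

    def test_european_decimal_ingest(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "species,surface_area_mm2\nA,\"2,1324\"\nB,'3.382100\n"
        )
        df = read_specimen_table(p)
        assert df["surface_area_mm2"].tolist() == [2.1324, 3.3821]


class TestBuildScenario:
    def test_strike_margin_sets(self, shovel_mesh):
        bc = build_scenario(shovel_mesh, "strike_margin", 0.5)
        assert set(bc.fixed_sets) == {
            "articulation_dorsal", "articulation_ventral"
        }
        assert bc.loaded_set == "masticatory_margin"
        assert np.linalg.norm(bc.load_direction) == pytest.approx(1.0)

    def test_pressure_apical_sets(self, shovel_mesh):
        bc = build_scenario(shovel_mesh, "pressure_apical", 0.5)
        assert set(bc.fixed_sets) == {
            "articulation_dorsal", "articulation_ventral", "apical_tooth"
        }
        assert bc.loaded_set == "apodeme_insertion"
        assert np.allclose(bc.load_direction, shovel_mesh.apodeme_direction)

    def test_apical_excluded_for_trapjaw(self):
        mesh = generate_mandible(
            MorphotypeParams.preset("trapjaw", seed=1, voxel_size=0.045)
        )
        with pytest.raises(ScenarioExclusionError):
            build_scenario(mesh, "strike_apical", 0.5)
        # margin scenarios remain available
        build_scenario(mesh, "strike_margin", 0.5)

    def test_missing_region_tag(self, shovel_mesh):
        bare = shovel_mesh.__class__(
            nodes=shovel_mesh.nodes, tets=shovel_mesh.tets
        )
        with pytest.raises(ConfigurationError):
            build_scenario(bare, "strike_margin", 0.5)

    def test_deterministic_and_idempotent(self, shovel_mesh):
        a = build_scenario(shovel_mesh, "pressure_margin", 0.3)
        b = build_scenario(shovel_mesh, "pressure_margin", 0.3)
        assert a == b

    def test_surface_normal_mode(self, shovel_mesh):
        bc = build_scenario(
            shovel_mesh, "strike_margin", 0.5,
            strike_direction_mode="surface_normal",
        )
        assert np.linalg.norm(bc.load_direction) == pytest.approx(1.0)

    def test_json_roundtrip(self, shovel_mesh):
        bc = build_scenario(shovel_mesh, "strike_margin", 0.5)
        assert BCScenario.from_json(bc.to_json()) == bc

    def test_invariant_violations_rejected(self):
        with pytest.raises(ParameterError):
            BCScenario(
                scenario="strike_margin",
                fixed_sets=("articulation_dorsal",),  # missing ventral
                loaded_set="masticatory_margin",
                load_direction=(0.0, -1.0, 0.0),
                load_magnitude=1.0,
            )
        with pytest.raises(ParameterError):
            BCScenario(
                scenario="pressure_margin",
                fixed_sets=(
                    "articulation_dorsal",
                    "articulation_ventral",
                    "masticatory_margin",
                ),
                loaded_set="masticatory_margin",  # loaded inside fixed
                load_direction=(0.0, -1.0, 0.0),
                load_magnitude=1.0,
            )
        with pytest.raises(ParameterError):
            BCScenario(
                scenario="strike_margin",
                fixed_sets=("articulation_dorsal", "articulation_ventral"),
                loaded_set="masticatory_margin",
                load_direction=(0.0, -2.0, 0.0),  # not unit
                load_magnitude=1.0,
            )

    def test_works_on_synthetic_tagged_bar(self, material):
        from mandibite.fem import assemble_and_solve

        mesh = tagged_bar_mesh((8, 2, 2), (4.0, 1.0, 1.0))
        bc = build_scenario(mesh, "strike_margin", 1.0)
        res = assemble_and_solve(mesh, material, bc)
        assert res.equilibrium_residual < 1e-8


class TestNormalizeStressField:
    def _field(self, values, volumes=None):
        values = np.asarray(values, dtype=float)
        volumes = (
            np.ones_like(values) if volumes is None else np.asarray(volumes)
        )
        return ElementStressField(np.arange(len(values)), values, volumes)

    def test_self_normalization_peaks_at_one(self):
        f = self._field([1.0, 3.0, 7.0])
        out = normalize_stress_field(f, f, statistic="max")
        assert out.max() == pytest.approx(1.0)

    def test_linearity(self):
        ref = self._field(np.linspace(1, 10, 50))
        f = self._field(np.linspace(0.5, 5, 50))
        a = normalize_stress_field(f, ref)
        doubled = self._field(2 * f.von_mises)
        b = normalize_stress_field(doubled, ref)
        assert np.allclose(b, 2 * a)

    def test_toy_division(self):
        f = self._field([2.0, 4.0])
        ref = self._field([4.0])
        out = normalize_stress_field(f, ref, statistic="max")
        assert np.allclose(out, [0.5, 1.0])

    def test_zero_reference_scale(self):
        f = self._field([1.0])
        ref = self._field([0.0])
        with pytest.raises(DegenerateFieldError):
            normalize_stress_field(f, ref, statistic="max")

    def test_default_quantile_is_robust_to_peak(self):
        # one artificial spike barely moves the default p98 scale
        base = np.linspace(1, 10, 1000)
        ref = self._field(base)
        spiky = self._field(np.append(base, 1e6), np.ones(1001))
        a = normalize_stress_field(ref, ref)
        b = normalize_stress_field(ref, spiky)
        assert np.allclose(a, b, rtol=0.01)
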