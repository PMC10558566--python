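import numpy as np
import pytest

from mandibite.fem import MaterialModel
from mandibite.morphology import MorphotypeParams, generate_mandible
from mandibite.pipeline import fixture_study_config, run_study
from mandibite.tetmesh import TaggedTetMesh, structured_box_mesh

STUDY_SEED = 1  # seed of the packaged small comparative study


@pytest.fixture(scope="session")
def material():
    return MaterialModel()


@pytest.fixture(scope="session")
def shovel_mesh():
    mesh = generate_mandible(MorphotypeParams.preset("shovel", seed=1))
    mesh.validate()
    return mesh


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One full comparative study (3 morphotypes x 2 sizes, 4 scenarios)."""
    out = tmp_path_factory.mktemp("study")
    config = fixture_study_config(seed=STUDY_SEED, output_dir=str(out))
    table = run_study(config)
    return config, table, out


def tagged_bar_mesh(divisions, lengths, nu_direction="x") -> TaggedTetMesh:
    """A box mesh with synthetic anatomical tags for solver-level tests.

    The left face plays the two articulations (split dorsally/ventrally),
    the right face the masticatory margin (its top half the apical tooth),
    and the bottom face near the left end the apodeme insertion.
    """
    mesh = structured_box_mesh(divisions, lengths)
    X = mesh.nodes
    lx, ly, lz = lengths
    left = np.flatnonzero(np.isclose(X[:, 0], 0.0))
    right = np.flatnonzero(np.isclose(X[:, 0], lx))
    zmid = lz / 2
    margin = right
    apical = right[X[right, 2] > zmid]
    bottom = np.flatnonzero(
        np.isclose(X[:, 2], 0.0) & (X[:, 0] < 0.3 * lx) & (X[:, 0] > 0)
    )
    mesh.region_tags = {
        "articulation_dorsal": left[X[left, 2] > zmid],
        "articulation_ventral": left[X[left, 2] <= zmid],
        "masticatory_margin": margin,
        "apical_tooth": apical,
        "apodeme_insertion": bottom,
    }
    mesh.apodeme_direction = np.array([0.0, 0.0, -1.0])
    mesh.metadata["strike_direction"] = [-1.0, 0.0, 0.0]
    return mesh
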