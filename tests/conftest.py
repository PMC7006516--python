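"""Shared fixtures: canonical solids, synthetic populations, and one
session-scoped end-to-end study run reused by the expensive checks."""

import numpy as np
import pytest
import trimesh

from footshape.geometry import PointCloud, TriangleMesh
from footshape.registration import CorrespondedSet
from footshape.synthetic import PopulationSpec, make_template, sample_population

STUDY_SEED = 7  # fixed seed for the end-to-end validation study


@pytest.fixture(scope="session")
def unit_cube():
    """Axis-aligned 10 mm cube with min corner at the origin."""
    box = trimesh.creation.box(extents=[10.0, 10.0, 10.0])
    box.apply_translation([5.0, 5.0, 5.0])
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def sphere5():
    """Radius-5 mm icosphere (watertight, ~1280 faces)."""
    s = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def bone_template():
    """Metatarsal-like template mesh plus its landmark vertex indices."""
    return make_template("metatarsal", 642)


@pytest.fixture(scope="session")
def clean_population(bone_template):
    """15 noiseless, unposed subjects with known mode weights; the
    correspondence is the generator's (faces shared with the template)."""
    tpl, lmk = bone_template
    spec = PopulationSpec(seed=2, n_subjects=15, noise_sd=0.0,
                          rotation_range_deg=0.0, translation_range_mm=0.0,
                          left_fraction=0.0)
    meshes, truth = sample_population(tpl, spec, landmark_indices=lmk)
    shapes = np.stack([m.vertices for m in meshes])
    corr = CorrespondedSet(template=tpl.as_cloud(), shapes=shapes,
                           fit_rmse=np.zeros(len(shapes)), faces=tpl.faces,
                           subject_ids=truth.subject_ids)
    return corr, truth, lmk


@pytest.fixture(scope="session")
def study_result():
    """One full pipeline run (simulate -> register -> SSM -> LOO full +
    sparse) at the study's default conditions, shared across tests."""
    from footshape.workflow import run_study

    return run_study(PopulationSpec(seed=STUDY_SEED))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_cloud(rng):
    def make(n=50, scale=10.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return PointCloud(r.normal(scale=scale, size=(n, 3)))

    return make
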