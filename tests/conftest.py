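import numpy as np
import pytest

from kvqa.core import DoseMap
from kvqa.pipeline import make_fixtures
from kvqa.synthetic import BeamGroundTruth, FilmResponseModel, generate_dose_map

FILM_PITCH = 25.4 / 75.0  # mm per pixel at the 75 dpi scan convention


@pytest.fixture(scope="session")
def film_pitch() -> float:
    return FILM_PITCH


@pytest.fixture
def beam_10mm() -> BeamGroundTruth:
    return BeamGroundTruth(shape="circular", nominal_size=10.0, edge_sigma=0.4)


@pytest.fixture
def map_10mm(beam_10mm) -> DoseMap:
    return generate_dose_map(beam_10mm, 20.0, FILM_PITCH)


@pytest.fixture
def noiseless_model() -> FilmResponseModel:
    return FilmResponseModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def minimal_bundle(tmp_path_factory):
    """A small deterministic fixture bundle shared by pipeline/CLI tests."""
    root = tmp_path_factory.mktemp("bundle") / "minimal"
    make_fixtures(root, seed=7, scenario="minimal", n_flex_angles=24)
    return root
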