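import numpy as np
import pytest

from meriquant.synth import (
    Synth4DConfig,
    SynthGeometryConfig,
    SynthMeshConfig,
    SynthTrackConfig,
    generate_geometry_table,
    generate_mesh,
    generate_pairs_4d,
    generate_tracks,
)


@pytest.fixture(scope="session")
def geometry_table():
    """Moderate default geometry table shared by read-only tests."""
    cfg = SynthGeometryConfig(cells_per_root_per_tissue=60, seed=11)
    return generate_geometry_table(cfg)


@pytest.fixture(scope="session")
def tracks_table():
    return generate_tracks(SynthTrackConfig(seed=5))


@pytest.fixture(scope="session")
def pairs_table():
    return generate_pairs_4d(Synth4DConfig(seed=7))


@pytest.fixture(scope="session")
def default_mesh():
    return generate_mesh(SynthMeshConfig())


@pytest.fixture(scope="session")
def small_mesh():
    """~38-cell template for simulator tests."""
    return generate_mesh(
        SynthMeshConfig(
            n_epidermis=12, n_cortex=6, n_endodermis=6, n_pericycle=8, n_stele=6
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
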