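import numpy as np
import pytest

from fnirs_macorr import ArtifactSpec, BlockDesign, build_layout, simulate_recording


@pytest.fixture(scope="session")
def layout5():
    return build_layout(5, 5)


@pytest.fixture(scope="session")
def design3():
    """Three 20/20/20 blocks at 10 Hz: 1800 samples."""
    return BlockDesign(n_blocks=3)


@pytest.fixture(scope="session")
def jump_recording(layout5, design3):
    """Recording with a baseline jump at optode T3 (contaminates CH4, CH9)."""
    return simulate_recording(
        layout5,
        design3,
        artifacts=[ArtifactSpec("T3", "baseline_jump", 0.1, 70.0)],
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_recording(layout5, design3):
    return simulate_recording(layout5, design3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
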