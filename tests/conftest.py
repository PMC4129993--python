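import numpy as np
import pytest

import hierbg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def suite_scenes():
    """All standard-suite scenes, rendered once per session."""
    return {name: hierbg.generate_scene(cfg) for name, cfg in hierbg.standard_suite().items()}


@pytest.fixture(scope="session")
def suite_detections(suite_scenes):
    """Hierarchical-detector results on every suite scene (default config)."""
    return {
        name: hierbg.detect_sequence(scene.frames)
        for name, scene in suite_scenes.items()
    }
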