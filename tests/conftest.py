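import numpy as np
import pytest

from hipnav import (PelvicLandmarks, SceneConfig, build_app_frame,
                    generate_pelvis, simulate_case)


@pytest.fixture(scope="session")
def canonical_landmarks():
    """Symmetric canonical pelvis: ASIS on the x-axis, pubis inferior."""
    return PelvicLandmarks(
        asis_left=[120.0, 0.0, 0.0], asis_right=[-120.0, 0.0, 0.0],
        pubic_left=[25.0, 0.0, -95.0], pubic_right=[-25.0, 0.0, -95.0],
    )


@pytest.fixture(scope="session")
def canonical_frame(canonical_landmarks):
    return build_app_frame(canonical_landmarks)


@pytest.fixture(scope="session")
def pelvis():
    return generate_pelvis(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def default_case():
    return simulate_case(SceneConfig(seed=11))
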